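"""Deterministic synthetic-data generators.

These generators produce group-structured reference panels with planted
diagnostic markers, melt-curve plates with noise and instrument baselines,
and labeled "market survey" sample sets — everything the rest of the
toolkit needs to build and test without downloading reference data.

Divergence structure: an ancestral sequence is drawn uniformly; group
consensus sequences receive seeded random substitutions at the
between-group rate; members receive substitutions at the within-group rate.
Marker windows are exempt from both mutation processes — inside a marker,
the only between-group differences are the planted diagnostic bases and
indels, mirroring how real diagnostic fragments are selected for being
identical within groups and controlled between them.  Diagnostic bases form
an A·T→G·C ladder so that group melting temperatures are ordered and
separated by a controlled ΔTm.

All randomness flows through one ``numpy.random.default_rng(seed)``; the
same seed reproduces output bit for bit.  Substitutions are uniform over
the off-diagonal base changes unless a transition bias is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GroupSpec
from .seqio import Alignment, NucleotideSequence
from .thermo import DEFAULT_GRID, MeltCurve, melt_grid, simulate_melt_curve

__all__ = ["MarkerSpec", "PanelSpec", "SyntheticPanel",
           "simulate_reference_panel", "simulate_melt_curve_set",
           "simulate_market_survey"]

_BASES = np.array(list("ACGT"))


@dataclass
class MarkerSpec:
    """A planted diagnostic window.

    ``diag_step`` A·T→G·C flips separate consecutive groups (group *g* gets
    ``g·diag_step`` flips), giving an ordered Tm ladder.  ``indel_groups``
    lack the base at ``indel_pos`` (a gap column in the alignment).
    """

    start: int
    end: int
    flank_len: int = 18
    diag_step: int = 2
    indel_groups: tuple[int, ...] = ()
    indel_pos: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PanelSpec:
    """Conditions for one synthetic reference panel."""

    n_groups: int = 6
    members_per_group: int = 2
    seq_len: int = 1200
    inter_group_divergence: float = 0.02   # substitutions/site between groups
    intra_group_divergence: float = 0.005  # substitutions/site within groups
    markers: list[MarkerSpec] = field(
        default_factory=lambda: [MarkerSpec(start=500, end=613)]  # 113 bp window
    )
    transition_bias: float = 1.0           # >1 favours transitions
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.inter_group_divergence > self.intra_group_divergence >= 0):
            raise ValueError("need inter > intra >= 0")
        if max(self.inter_group_divergence, self.intra_group_divergence) > 0.5:
            raise ValueError("divergence rates above 0.5 are not meaningful")
        last_end = 0
        for m in sorted(self.markers, key=lambda m: m.start):
            if m.start < last_end:
                raise ValueError("marker windows must not overlap")
            if not (0 <= m.start < m.end <= self.seq_len):
                raise ValueError("marker window outside sequence bounds")
            if m.length < 2 * m.flank_len + 1:
                raise ValueError("marker window too short for its flanks")
            last_end = m.end


@dataclass
class SyntheticPanel:
    """Sequences, their alignment, and the group structure of one panel."""

    spec: PanelSpec
    sequences: list[NucleotideSequence]
    alignment: Alignment
    groups: GroupSpec

    def group_of(self, seq_id: str) -> str:
        for g, members in self.groups.groups.items():
            if seq_id in members:
                return g
        raise KeyError(seq_id)

    def marker_amplicon(self, seq_id: str, marker_index: int = 0) -> str:
        """Gap-stripped sequence of one marker window for one member."""
        m = self.spec.markers[marker_index]
        return self.alignment.row(seq_id)[m.start:m.end].replace("-", "")


def _mutate(row: np.ndarray, positions: np.ndarray, rng: np.random.Generator,
            transition_bias: float) -> None:
    """Substitute bases in place at the given positions."""
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for p in positions:
        old = row[p]
        others = [b for b in "ACGT" if b != old]
        if transition_bias == 1.0:
            row[p] = rng.choice(others)
        else:
            w = np.array([transition_bias if b == transitions[old] else 1.0 for b in others])
            row[p] = rng.choice(others, p=w / w.sum())


def simulate_reference_panel(spec: PanelSpec) -> SyntheticPanel:
    """Generate one panel: ancestor → group consensi → members.

    Marker windows carry only the planted diagnostics; background columns
    carry the Poisson-like substitution processes.  Diagnostic positions are
    evenly spaced over each marker interior and forced to A/T in the
    ancestor so each flip is an A·T→G·C change.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(_BASES, size=spec.seq_len)
    # marker windows are redrawn at ~40% GC (typical of mtDNA fragments) so
    # that even the most GC-shifted group's amplicon finishes melting well
    # inside the 65-95 degC dissociation ramp
    for m in spec.markers:
        ancestor[m.start:m.end] = rng.choice(
            _BASES, size=m.length, p=[0.30, 0.20, 0.20, 0.30])

    protected = np.zeros(spec.seq_len, dtype=bool)
    diag_positions: dict[int, list[int]] = {}
    for mi, m in enumerate(spec.markers):
        protected[m.start:m.end] = True
        interior = np.arange(m.start + m.flank_len, m.end - m.flank_len)
        if m.indel_pos is not None:
            if not (m.start + m.flank_len <= m.indel_pos < m.end - m.flank_len):
                raise ValueError("indel position must lie in the marker interior")
            interior = interior[interior != m.indel_pos]
        n_diag = max((spec.n_groups - 1) * m.diag_step, 1)
        if n_diag > len(interior):
            raise ValueError("marker interior too short for the diagnostic ladder")
        pick = np.linspace(0, len(interior) - 1, n_diag).round().astype(int)
        positions = sorted(interior[pick].tolist())
        diag_positions[mi] = positions
        ancestor[positions] = rng.choice(np.array(list("AT")), size=len(positions))

    background = np.nonzero(~protected)[0]

    sequences: list[NucleotideSequence] = []
    aligned_rows: list[tuple[str, str]] = []
    groups: dict[str, list[str]] = {}
    for g in range(spec.n_groups):
        gname = f"G{g}"
        consensus = ancestor.copy()
        n_inter = rng.binomial(len(background), spec.inter_group_divergence)
        hit = rng.choice(background, size=n_inter, replace=False)
        _mutate(consensus, hit, rng, spec.transition_bias)
        for mi, m in enumerate(spec.markers):
            for p in diag_positions[mi][: g * m.diag_step]:
                consensus[p] = "G" if consensus[p] == "A" else "C"
        gap_cols = {
            m.indel_pos for m in spec.markers
            if m.indel_pos is not None and g in m.indel_groups
        }
        members = []
        for k in range(spec.members_per_group):
            row = consensus.copy()
            n_intra = rng.binomial(len(background), spec.intra_group_divergence)
            hit = rng.choice(background, size=n_intra, replace=False)
            _mutate(row, hit, rng, spec.transition_bias)
            sid = f"{gname}_m{k}"
            aligned = "".join("-" if i in gap_cols else row[i] for i in range(spec.seq_len))
            aligned_rows.append((sid, aligned))
            sequences.append(NucleotideSequence(
                id=sid, bases=aligned.replace("-", ""),
                species_label=gname, group_label=gname,
            ))
            members.append(sid)
        groups[gname] = members

    return SyntheticPanel(
        spec=spec,
        sequences=sequences,
        alignment=Alignment(rows=aligned_rows),
        groups=GroupSpec(groups=groups),
    )


def simulate_melt_curve_set(
    panel: SyntheticPanel,
    replicates: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    marker_index: int = 0,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    baseline_slope_range: tuple[float, float] = (-0.10, -0.02),
    baseline_offset_range: tuple[float, float] = (8.0, 12.0),
) -> list[MeltCurve]:
    """Simulate a melt-curve plate for every member of a panel.

    Each curve is the two-state melt of the member's planted-marker amplicon
    scaled to 90 fluorescence units, plus a per-curve random linear baseline
    (slope and offset drawn from the stated ranges, emulating instrument
    drift) and i.i.d. Gaussian noise — enough structure to exercise
    baseline normalization.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    temps = melt_grid(grid)
    curves = []
    for seq in panel.sequences:
        amplicon = panel.marker_amplicon(seq.id, marker_index)
        base = simulate_melt_curve(amplicon, grid=grid, sample_id=seq.id)
        theta = base.fluorescence / 100.0
        for rep in range(replicates):
            slope = rng.uniform(*baseline_slope_range)
            offset = rng.uniform(*baseline_offset_range)
            raw = 90.0 * theta + offset + slope * (temps - temps[0])
            raw = raw + rng.normal(0.0, noise_sd, size=len(temps))
            curves.append(MeltCurve(
                sample_id=f"{seq.id}_r{rep}",
                temperatures=temps,
                fluorescence=np.clip(raw, 0.0, None),
                group_label=seq.group_label,
            ))
    return curves


def simulate_market_survey(
    panel: SyntheticPanel,
    n_samples: int = 20,
    mislabel_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """Draw labeled survey samples, a seeded fraction deliberately mislabeled.

    Returns the sample sequences (declared label in ``species_label``) and a
    truth table recording both the declared and the true group per sample.
    """
    if not (0 <= mislabel_rate <= 1):
        raise ValueError("mislabel_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = panel.groups.names
    by_id = {s.id: s for s in panel.sequences}
    samples = []
    rows = []
    for i in range(n_samples):
        true = names[rng.integers(len(names))]
        member = panel.groups.groups[true][rng.integers(len(panel.groups.groups[true]))]
        mislabel = bool(rng.random() < mislabel_rate)
        declared = true
        if mislabel:
            declared = names[(names.index(true) + 1 + rng.integers(len(names) - 1)) % len(names)]
        sid = f"S{i:03d}"
        samples.append(NucleotideSequence(
            id=sid, bases=by_id[member].bases, species_label=declared,
        ))
        rows.append({"sample_id": sid, "true_group": true,
                     "declared_group": declared, "mislabeled": mislabel,
                     "source_member": member})
    return samples, pd.DataFrame(rows)
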