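"""End-to-end identification workflow and survey-panel bookkeeping.

``build_reference`` turns labeled reference sequences into a reusable
:class:`ReferenceAssay` — in-silico amplicons of the chosen HRM marker,
simulated replicate melt curves, their clustering, and (optionally) RFLP
and multiplex keys.  ``identify_sample`` then classifies an unknown
sequence or melt curve against it, flagging mislabeling when a declared
label disagrees with the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hrm as _hrm
from . import pcr as _pcr
from . import rflp as _rflp
from .hrm import HRMConfig, NormalizedCurve, SpeciesCall, UNASSIGNED
from .seqio import NucleotideSequence, Primer, SamplePanel
from .thermo import MeltCurve, melt_grid, simulate_melt_curve

__all__ = ["ReferenceAssay", "build_reference", "identify_sample",
           "summarize_panel", "SpeciesCall"]

NO_PRODUCT = "no product"


@dataclass
class ReferenceAssay:
    """A fitted reference: curves, clustering and optional banding keys."""

    fwd: Primer
    rev: Primer
    config: HRMConfig
    curves: list[NormalizedCurve]
    clustering: _hrm.ClusterResult
    enzyme: _rflp.RestrictionEnzyme | None = None
    rflp_pair: tuple[Primer, Primer] | None = None
    rflp_patterns: dict[str, _rflp.DigestPattern] = field(default_factory=dict)
    multiplex_pairs: list[tuple[Primer, Primer]] = field(default_factory=list)
    multiplex_patterns: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return sorted({g for g in self.clustering.cluster_labels.values() if g})


def _replicate_curves(
    amplicon_seq: str, sample_id: str, group: str | None, config: HRMConfig,
    replicates: int, noise_sd: float, rng: np.random.Generator,
) -> list[NormalizedCurve]:
    base = simulate_melt_curve(amplicon_seq, grid=config.grid, sample_id=sample_id)
    temps = base.temperatures
    out = []
    for rep in range(replicates):
        raw = 0.9 * base.fluorescence + 10.0
        if noise_sd > 0:
            raw = raw + rng.normal(0.0, noise_sd, size=len(temps))
        mc = MeltCurve(sample_id=f"{sample_id}_r{rep}", temperatures=temps,
                       fluorescence=np.clip(raw, 0.0, None), group_label=group)
        out.append(_hrm.normalize_curve(mc, config))
    return out


def build_reference(
    references: list[NucleotideSequence],
    fwd: Primer,
    rev: Primer,
    config: HRMConfig | None = None,
    replicates: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    enzyme: _rflp.RestrictionEnzyme | None = None,
    rflp_pair: tuple[Primer, Primer] | None = None,
    multiplex_pairs: list[tuple[Primer, Primer]] | None = None,
    max_mismatches: int = _pcr.DEFAULT_MAX_MISMATCHES,
    clamp_len: int = _pcr.DEFAULT_CLAMP_LEN,
) -> ReferenceAssay:
    """Build a reference assay from labeled sequences.

    Every reference sequence must carry a ``group_label``.  The HRM marker
    is amplified in silico per reference; ``replicates`` noisy melt curves
    per reference are simulated, normalized and clustered with the labels.
    References whose marker fails to amplify are rejected.
    """
    config = config or HRMConfig()
    rng = np.random.default_rng(seed)
    curves: list[NormalizedCurve] = []
    labels: dict[str, str] = {}
    for ref in references:
        if not ref.group_label:
            raise ValueError(f"reference {ref.id} has no group label")
        amps = _pcr.amplify(ref, fwd, rev, max_mismatches, clamp_len)
        if not amps:
            raise ValueError(f"marker fails to amplify on reference {ref.id}")
        for nc in _replicate_curves(amps[0].sequence, ref.id, ref.group_label,
                                    config, replicates, noise_sd, rng):
            curves.append(nc)
            labels[nc.sample_id] = ref.group_label
    clustering = _hrm.cluster_curves(curves, config, reference_labels=labels)

    assay = ReferenceAssay(fwd=fwd, rev=rev, config=config,
                           curves=curves, clustering=clustering)
    if enzyme is not None and rflp_pair is not None:
        assay.enzyme = enzyme
        assay.rflp_pair = rflp_pair
        for ref in references:
            amps = _pcr.amplify(ref, *rflp_pair, max_mismatches, clamp_len)
            if amps and ref.group_label not in assay.rflp_patterns:
                assay.rflp_patterns[ref.group_label] = _rflp.digest(
                    amps[0].sequence, enzyme)
    if multiplex_pairs:
        assay.multiplex_pairs = list(multiplex_pairs)
        for ref in references:
            if ref.group_label in assay.multiplex_patterns:
                continue
            pat = _pcr.multiplex_predict(ref, multiplex_pairs,
                                         max_mismatches, clamp_len)
            assay.multiplex_patterns[ref.group_label] = pat.pattern_key
    return assay


def _match_lengths(observed: list[int], predicted: list[int], rel_tol: float) -> float:
    """Greedy one-to-one band-length matching score in [0, 1]."""
    if not observed and not predicted:
        return 1.0
    remaining = list(observed)
    matched = 0
    for pred in sorted(predicted, reverse=True):
        hits = [o for o in remaining if abs(o - pred) <= rel_tol * pred]
        if hits:
            remaining.remove(min(hits, key=lambda o: abs(o - pred)))
            matched += 1
    return matched / max(len(observed), len(predicted), 1)


def _classify_by_pattern(
    observed: list[int], patterns: dict[str, list[int]], rel_tol: float
) -> tuple[str, float, dict]:
    scores = {g: _match_lengths(observed, list(p), rel_tol)
              for g, p in patterns.items()}
    best = max(scores.values(), default=0.0)
    winners = sorted(g for g, s in scores.items() if s == best)
    call = winners[0] if len(winners) == 1 and best == 1.0 else UNASSIGNED
    return call, best, {"scores": scores, "observed": observed, "tied": winners}


def identify_sample(
    sample: NucleotideSequence | MeltCurve,
    reference: ReferenceAssay,
    declared_label: str | None = None,
    method: str = "hrm",
    rel_tol: float = _rflp.DEFAULT_REL_TOL,
    max_mismatches: int = _pcr.DEFAULT_MAX_MISMATCHES,
    clamp_len: int = _pcr.DEFAULT_CLAMP_LEN,
) -> SpeciesCall:
    """Classify one sample (sequence or melt curve) against a reference.

    Sequence input is amplified in silico with the assay's marker primers;
    a template on which the marker yields no product returns an explicit
    "no product" call rather than an error.  ``method`` selects the HRM
    view, the RFLP view, the multiplex view, or ``combined`` (HRM + RFLP
    with an agreement check).  The mislabel flag is set only when a
    declared label exists and disagrees with a definite call.
    """
    if len({g for g in reference.clustering.cluster_labels.values() if g}) < 2:
        raise ValueError("reference assay needs at least two labeled groups")
    if method not in ("hrm", "rflp", "multiplex", "combined"):
        raise ValueError(f"unknown method {method!r}")

    if isinstance(sample, MeltCurve):
        if method != "hrm":
            raise ValueError("curve input supports the hrm method only")
        nc = _hrm.normalize_curve(sample, reference.config)
        call = _hrm.assign_unknown(nc, reference.curves,
                                   reference.clustering, reference.config)
        return _flag(call, declared_label)

    calls: dict[str, SpeciesCall] = {}
    if method in ("hrm", "combined"):
        amps = _pcr.amplify(sample, reference.fwd, reference.rev,
                            max_mismatches, clamp_len)
        if not amps:
            return SpeciesCall(sample_id=sample.id, method=method,
                               call=NO_PRODUCT, confidence=0.0,
                               evidence={"marker": (reference.fwd.name,
                                                    reference.rev.name)})
        curve = simulate_melt_curve(amps[0].sequence, grid=reference.config.grid,
                                    sample_id=sample.id)
        nc = _hrm.normalize_curve(curve, reference.config)
        calls["hrm"] = _hrm.assign_unknown(nc, reference.curves,
                                           reference.clustering, reference.config)
    if method in ("rflp", "combined"):
        if reference.enzyme is None or not reference.rflp_patterns:
            raise ValueError("reference assay carries no RFLP key")
        amps = _pcr.amplify(sample, *reference.rflp_pair, max_mismatches, clamp_len)
        if not amps:
            return SpeciesCall(sample_id=sample.id, method=method,
                               call=NO_PRODUCT, confidence=0.0,
                               evidence={"rflp_pair": tuple(
                                   p.name for p in reference.rflp_pair)})
        pattern = _rflp.digest(amps[0].sequence, reference.enzyme)
        call, score, ev = _classify_by_pattern(
            list(pattern.fragments),
            {g: list(p.fragments) for g, p in reference.rflp_patterns.items()},
            rel_tol)
        calls["rflp"] = SpeciesCall(sample_id=sample.id, method="rflp",
                                    call=call, confidence=score, evidence=ev)
    if method == "multiplex":
        if not reference.multiplex_patterns:
            raise ValueError("reference assay carries no multiplex key")
        pat = _pcr.multiplex_predict(sample, reference.multiplex_pairs,
                                     max_mismatches, clamp_len)
        call, score, ev = _classify_by_pattern(
            list(pat.pattern_key),
            {g: list(k) for g, k in reference.multiplex_patterns.items()},
            rel_tol)
        return _flag(SpeciesCall(sample_id=sample.id, method="multiplex",
                                 call=call, confidence=score, evidence=ev),
                     declared_label)

    if method == "combined":
        h, r = calls["hrm"], calls["rflp"]
        agree = h.call == r.call
        out = SpeciesCall(
            sample_id=sample.id, method="combined", call=h.call,
            confidence=h.confidence,
            evidence={"hrm": h.evidence | {"call": h.call},
                      "rflp": r.evidence | {"call": r.call},
                      "views_agree": agree},
        )
        return _flag(out, declared_label)

    out = calls[method]
    out.method = method
    return _flag(out, declared_label)


def _flag(call: SpeciesCall, declared: str | None) -> SpeciesCall:
    if declared is not None and call.call not in (UNASSIGNED, NO_PRODUCT):
        call.mislabel_flag = call.call != declared
        call.evidence["declared_label"] = declared
    return call


_COUNT_COLUMNS = ["n_total", "n_fc", "n_fm_sm", "n_re", "n_frozen", "n_cooked"]


def summarize_panel(
    panel: SamplePanel,
    where: dict | None = None,
    by: list[str] | None = None,
):
    """Totals and sub-totals of a survey panel.

    ``where`` maps column names to a value, a set of values, or a predicate;
    ``by`` optionally groups the summary.  Count arithmetic conserves row
    sums exactly.
    """
    df = panel.table
    if where:
        mask = pd.Series(True, index=df.index)
        for col, crit in where.items():
            if col not in df.columns:
                raise KeyError(f"unknown column {col!r}")
            if callable(crit):
                mask &= df[col].map(crit)
            elif isinstance(crit, (set, frozenset, list, tuple)):
                mask &= df[col].isin(list(crit))
            else:
                mask &= df[col] == crit
        df = df[mask]
    if by:
        for col in by:
            if col not in df.columns:
                raise KeyError(f"unknown column {col!r}")
        return df.groupby(by, sort=True)[_COUNT_COLUMNS].sum().reset_index()
    totals = {c: int(df[c].sum()) for c in _COUNT_COLUMNS}
    totals["n_rows"] = int(len(df))
    return totals
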