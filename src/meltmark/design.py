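"""Diagnostic-window discovery and HRM primer proposal on alignments.

A useful short HRM marker is a window of a multi-species alignment that is
(a) identical within each group, (b) different between every pair of groups
that must be told apart, at at least one interior column, and (c) flanked by
near-conserved stretches from which universal primers can be read off.
``scan_diagnostic_windows`` enumerates every window satisfying all three
constraints; results are ranked by diagnostic-column count, ties broken by
shorter window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio import IUPAC_SETS, Alignment, Primer, reverse_complement
from .thermo import duplex_params, simulate_melt_curve

__all__ = ["GroupSpec", "MarkerCandidate", "ScanResult", "DesignError",
           "scan_diagnostic_windows", "propose_primer_pairs",
           "predict_assay_separation"]

_CODE_FOR_SET = {frozenset(v): k for k, v in IUPAC_SETS.items()}


class DesignError(ValueError):
    """Raised when a candidate cannot yield usable primers."""


@dataclass
class GroupSpec:
    """Disjoint groups of alignment row ids."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"sequences {sorted(overlap)} appear in more than one group")
            seen.update(members)

    @property
    def names(self) -> list[str]:
        return list(self.groups)


@dataclass
class MarkerCandidate:
    """One alignment window usable as a short diagnostic marker."""

    window: tuple[int, int]                 # 0-based half-open columns
    amplicon_len: dict[str, int]            # per group, gaps removed
    diagnostic_columns: list[int]
    intra_group_identical: dict[str, bool]
    has_indel: bool
    flank_variable_columns: tuple[int, int]  # variable columns in (left, right) flank

    @property
    def aligned_length(self) -> int:
        return self.window[1] - self.window[0]


@dataclass
class ScanResult:
    """Ranked candidates plus, when empty, per-constraint failure tallies."""

    candidates: list[MarkerCandidate]
    failure_tallies: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]


def _alignment_matrix(aln: Alignment) -> tuple[np.ndarray, dict[str, int]]:
    mat = np.array([list(bases) for _, bases in aln.rows])
    index = {rid: i for i, (rid, _) in enumerate(aln.rows)}
    return mat, index


def scan_diagnostic_windows(
    aln: Alignment,
    groups: GroupSpec,
    min_len: int = 100,
    max_len: int = 160,
    flank_len: int = 18,
    max_flank_mismatch: int = 2,
    must_discriminate: list[tuple[str, str]] | None = None,
) -> ScanResult:
    """Enumerate alignment windows usable as group-diagnostic markers.

    Window lengths are aligned-column lengths in [min_len, max_len].  The
    two ``flank_len`` flanks are part of the window; "interior" means the
    columns between them.  By default every pair of groups must be
    discriminated.  Prefix-sum bookkeeping makes the scan linear in
    (columns × window lengths).
    """
    if min_len < 2 * flank_len + 1:
        raise ValueError("min_len must be >= 2*flank_len + 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    mat, index = _alignment_matrix(aln)
    n_cols = mat.shape[1]
    for name, members in groups.groups.items():
        missing = [m for m in members if m not in index]
        if missing:
            raise KeyError(f"group {name!r} members not in alignment: {missing}")

    names = groups.names
    pairs = must_discriminate or list(itertools.combinations(names, 2))
    for a, b in pairs:
        if a not in groups.groups or b not in groups.groups:
            raise KeyError(f"must-discriminate pair ({a}, {b}) names an unknown group")

    rows_of = {g: [index[m] for m in members] for g, members in groups.groups.items()}

    # per-column facts
    intra_ok = {}          # group -> bool per column: members identical
    consensus = {}         # group -> column char (valid where intra_ok)
    for g, rows in rows_of.items():
        sub = mat[rows]
        same = (sub == sub[0]).all(axis=0)
        intra_ok[g] = same
        consensus[g] = sub[0]
    all_intra = np.logical_and.reduce([intra_ok[g] for g in names])
    variable = ~(mat == mat[0]).all(axis=0)                      # across ALL rows
    pair_diff = {
        (a, b): all_intra & (consensus[a] != consensus[b]) for a, b in pairs
    }
    diag_any = np.zeros(n_cols, dtype=bool)
    for d in pair_diff.values():
        diag_any |= d
    gap_col = (mat == "-").any(axis=0)

    def prefix(x):
        return np.concatenate([[0], np.cumsum(x.astype(int))])

    p_intra = prefix(~all_intra)     # count of columns violating intra-identity
    p_var = prefix(variable)
    p_diag = prefix(diag_any)
    p_gap = prefix(gap_col)
    p_pair = {k: prefix(v) for k, v in pair_diff.items()}

    tallies = {"intra_identity": 0, "pair_discrimination": 0, "flank_conservation": 0}
    found: list[MarkerCandidate] = []
    for length in range(min_len, max_len + 1):
        for s in range(0, n_cols - length + 1):
            e = s + length
            if p_intra[e] - p_intra[s] > 0:
                tallies["intra_identity"] += 1
                continue
            lf_var = int(p_var[s + flank_len] - p_var[s])
            rf_var = int(p_var[e] - p_var[e - flank_len])
            if lf_var > max_flank_mismatch or rf_var > max_flank_mismatch:
                tallies["flank_conservation"] += 1
                continue
            i0, i1 = s + flank_len, e - flank_len
            if any(p_pair[k][i1] - p_pair[k][i0] == 0 for k in pair_diff):
                tallies["pair_discrimination"] += 1
                continue
            diag_cols = [c for c in range(s, e) if diag_any[c]]
            found.append(MarkerCandidate(
                window=(s, e),
                amplicon_len={
                    g: int(length - sum(consensus[g][s:e] == "-")) for g in names
                },
                diagnostic_columns=diag_cols,
                intra_group_identical={g: True for g in names},
                has_indel=bool(p_gap[e] - p_gap[s] > 0),
                flank_variable_columns=(lf_var, rf_var),
            ))
    found.sort(key=lambda c: (-len(c.diagnostic_columns), c.aligned_length, c.window))
    return ScanResult(candidates=found, failure_tallies=tallies if not found else {})


def _flank_consensus(mat: np.ndarray, cols: range) -> str:
    """IUPAC consensus of alignment columns across all rows; gaps are dropped
    from the resulting primer sequence."""
    out = []
    for c in cols:
        bases = frozenset(mat[:, c]) - {"-"}
        if not bases:
            continue
        out.append(_CODE_FOR_SET[frozenset().union(*(IUPAC_SETS[b] for b in bases))])
    return "".join(out)


def propose_primer_pairs(
    candidate: MarkerCandidate,
    aln: Alignment,
    flank_len: int = 18,
    min_primer_len: int = 18,
    max_primer_len: int = 26,
    tm_range: tuple[float, float] = (50.0, 65.0),
    max_pair_dtm: float = 3.0,
    max_degenerate: int = 3,
) -> list[tuple[Primer, Primer]]:
    """Read primers off the candidate's flank consensi.

    The forward primer is the left flank consensus (top strand 5'->3'); the
    reverse primer is the reverse complement of the right flank consensus.
    Variable flank columns become IUPAC codes; more than ``max_degenerate``
    of them rejects the candidate.  Pairs failing the length, Tm-range or
    pairwise ΔTm constraints are dropped (an empty list is allowed).
    """
    mat, _ = _alignment_matrix(aln)
    s, e = candidate.window
    flank = candidate.flank_variable_columns
    fwd_seq = _flank_consensus(mat, range(s, s + flank_len))
    rev_seq = reverse_complement(_flank_consensus(mat, range(e - flank_len, e)))

    for seq, side, n_var in ((fwd_seq, "left", flank[0]), (rev_seq, "right", flank[1])):
        degenerate = sum(1 for c in seq if c not in "ACGT")
        if degenerate > max_degenerate:
            raise DesignError(
                f"{side} flank needs {degenerate} degenerate positions (> {max_degenerate})"
            )

    fwd = Primer(name=f"marker_{s}_{e}_F", sequence=fwd_seq)
    rev = Primer(name=f"marker_{s}_{e}_R", sequence=rev_seq)
    pairs = []
    lens_ok = all(min_primer_len <= len(p) <= max_primer_len for p in (fwd, rev))
    if lens_ok:
        tm_f = duplex_params(fwd.sequence).tm
        tm_r = duplex_params(rev.sequence).tm
        if (tm_range[0] <= tm_f <= tm_range[1] and tm_range[0] <= tm_r <= tm_range[1]
                and abs(tm_f - tm_r) <= max_pair_dtm):
            pairs.append((Primer(fwd.name, fwd.sequence, round(tm_f, 1)),
                          Primer(rev.name, rev.sequence, round(tm_r, 1))))
    return pairs


def predict_assay_separation(
    candidate: MarkerCandidate,
    aln: Alignment,
    groups: GroupSpec,
    tm_diff_threshold: float = 0.2,
    shape_rms_cut: float = 1.0,
    max_ambiguous_frac: float = 0.10,
    grid: tuple[float, float, float] = (65.0, 95.0, 0.2),
) -> dict[tuple[str, str], dict]:
    """Per-group-pair window identity and predicted melt separation.

    Identity counts gaps as differences.  ΔTm is the 50%-crossing difference
    between simulated two-state melts of the per-group consensus amplicons
    (gaps stripped).  A pair is flagged HRM-separable when |ΔTm| reaches
    ``tm_diff_threshold`` or the RMS distance between the simulated curves
    reaches ``shape_rms_cut`` (percent units).
    """
    mat, index = _alignment_matrix(aln)
    s, e = candidate.window
    names = groups.names
    window_rows = {}
    for g, members in groups.groups.items():
        sub = mat[[index[m] for m in members], s:e]
        ambiguous = (~(sub == sub[0]).all(axis=0)).sum()
        if ambiguous > max_ambiguous_frac * (e - s):
            raise DesignError(
                f"group {g!r} consensus ambiguous at {ambiguous} of {e - s} columns"
            )
        window_rows[g] = "".join(sub[0])

    curves = {}
    tms = {}
    for g, row in window_rows.items():
        seq = row.replace("-", "")
        curve = simulate_melt_curve(seq, grid=grid, model="two_state", sample_id=g)
        curves[g] = curve.fluorescence
        half = np.nonzero(curve.fluorescence <= 50.0)[0]
        if len(half) and half[0] > 0:
            i = half[0]
            f0, f1 = curve.fluorescence[i - 1], curve.fluorescence[i]
            t0, t1 = curve.temperatures[i - 1], curve.temperatures[i]
            tms[g] = float(t0 + (f0 - 50.0) / (f0 - f1) * (t1 - t0))
        else:
            tms[g] = float("nan")

    out = {}
    for a, b in itertools.combinations(names, 2):
        ra, rb = window_rows[a], window_rows[b]
        ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-") / len(ra)
        dtm = abs(tms[a] - tms[b])
        rms = float(np.sqrt(np.mean((curves[a] - curves[b]) ** 2)))
        indel = ("-" in ra) != ("-" in rb) or ra.count("-") != rb.count("-")
        out[(a, b)] = {
            "identity_pct": 100.0 * ident,
            "delta_tm": dtm,
            "rms_distance": rms,
            "separable": bool(dtm >= tm_diff_threshold or rms >= shape_rms_cut),
            "indel": indel,
        }
    return out
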