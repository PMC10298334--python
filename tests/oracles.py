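"""Independent brute-force oracles used to cross-check the implementation.

These re-derive results by direct enumeration, sharing no code path with the
package internals beyond the IUPAC alphabet definition.
"""

from __future__ import annotations

import itertools

import numpy as np

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
        "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def brute_sites(template: str, circular: bool, primer: str,
                max_mm: int, clamp: int) -> set[tuple[int, str]]:
    """All (start, strand) binding sites by direct enumeration on the
    doubled sequence."""
    n = len(template)
    space = template + template if circular else template
    max_start = n - 1 if circular else n - len(primer)
    hits = set()
    for strand in "+-":
        q = primer if strand == "+" else rc(primer)
        clamp_idx = (set(range(len(q) - clamp, len(q))) if strand == "+"
                     else set(range(clamp)))
        for s in range(max_start + 1):
            if s + len(q) > len(space):
                continue
            mm = [i for i in range(len(q))
                  if not (space[s + i] in IUPAC[q[i]]
                          if space[s + i] in "ACGT"
                          else IUPAC[space[s + i]] <= IUPAC[q[i]])]
            if len(mm) <= max_mm and not any(i in clamp_idx for i in mm):
                hits.add((s, strand))
    return hits


def brute_scan(aln_rows: list[tuple[str, str]], groups: dict[str, list[str]],
               min_len: int, max_len: int, flank_len: int,
               max_flank_mismatch: int) -> set[tuple[int, int]]:
    """All diagnostic windows by per-window direct re-checking.

    Returns the set of (start, end) windows satisfying: intra-group
    identity; at least one interior column differing for every group pair;
    both flanks with at most ``max_flank_mismatch`` variable columns across
    all rows.
    """
    mat = np.array([list(b) for _, b in aln_rows])
    idx = {rid: i for i, (rid, _) in enumerate(aln_rows)}
    n_cols = mat.shape[1]
    names = list(groups)
    ok: set[tuple[int, int]] = set()
    for length in range(min_len, max_len + 1):
        for s in range(n_cols - length + 1):
            e = s + length
            win = mat[:, s:e]
            good = True
            cons = {}
            for g, members in groups.items():
                sub = win[[idx[m] for m in members]]
                if not (sub == sub[0]).all():
                    good = False
                    break
                cons[g] = sub[0]
            if not good:
                continue
            lf = win[:, :flank_len]
            rf = win[:, length - flank_len:]
            if (~(lf == lf[0]).all(axis=0)).sum() > max_flank_mismatch:
                continue
            if (~(rf == rf[0]).all(axis=0)).sum() > max_flank_mismatch:
                continue
            interior = slice(flank_len, length - flank_len)
            for a, b in itertools.combinations(names, 2):
                if not (cons[a][interior] != cons[b][interior]).any():
                    good = False
                    break
            if good:
                ok.add((s, e))
    return ok
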