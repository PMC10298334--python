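"""Restriction-digest fragment prediction and gel-pattern matching.

Only palindromic enzymes are accepted, so scanning the top strand for the
recognition sequence finds every cut site.  Fragment sizes on agarose gels
are read off against a ladder with roughly ±10% error, hence the default
relative tolerance of 0.12 when matching observed bands to predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import NucleotideSequence, is_concrete, reverse_complement

__all__ = ["RestrictionEnzyme", "DigestPattern", "BUILTIN_ENZYMES", "get_enzyme",
           "digest", "rflp_key", "match_bands", "GEL_RESOLUTION_FLOOR_BP",
           "DEFAULT_REL_TOL"]

DEFAULT_REL_TOL = 0.12

#: Fragments below this size are kept but flagged: a 50 bp ladder is the
#: practical floor for resolving bands on a standard agarose gel.
GEL_RESOLUTION_FLOOR_BP = 40


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A palindromic type-II enzyme: recognition site and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        object.__setattr__(self, "recognition", site)
        if not is_concrete(site):
            raise ValueError(f"{self.name}: recognition site must be concrete DNA")
        if site != reverse_complement(site):
            raise ValueError(
                f"{self.name}: non-palindromic recognition site {site!r} is not supported"
            )
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(f"{self.name}: cut_offset {self.cut_offset} outside site")


BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),   # A^AGCTT
    "Sau3AI": RestrictionEnzyme("Sau3AI", "GATC", 0),       # ^GATC
    "XbaI": RestrictionEnzyme("XbaI", "TCTAGA", 1),         # T^CTAGA
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; built-ins: {sorted(BUILTIN_ENZYMES)}")


@dataclass(frozen=True)
class DigestPattern:
    """Ordered (descending) fragment lengths of one enzyme on one linear input."""

    enzyme: str
    input_length: int
    fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.fragments) != self.input_length:
            raise ValueError("fragments must sum to the input length")
        if any(f < 1 for f in self.fragments):
            raise ValueError("all fragments must be >= 1 bp")

    @property
    def sub_resolution_fragments(self) -> tuple[int, ...]:
        """Fragments that may not resolve on a standard gel."""
        return tuple(f for f in self.fragments if f < GEL_RESOLUTION_FLOOR_BP)

    def __str__(self) -> str:
        return "/".join(str(f) for f in self.fragments)


def digest(seq: str | NucleotideSequence, enzyme: RestrictionEnzyme) -> DigestPattern:
    """Digest a linear concrete sequence; zero sites yield one full-length fragment."""
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq.upper()
    if not is_concrete(bases):
        raise ValueError("digest operates on concrete sequences (no ambiguity codes)")
    site = enzyme.recognition
    cuts = set()
    start = bases.find(site)
    while start != -1:
        pos = start + enzyme.cut_offset
        if 0 < pos < len(bases):
            cuts.add(pos)
        start = bases.find(site, start + 1)  # overlapping occurrences included
    bounds = [0, *sorted(cuts), len(bases)]
    fragments = tuple(sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True))
    return DigestPattern(enzyme=enzyme.name, input_length=len(bases), fragments=fragments)


def match_bands(
    observed: list[int | float],
    predicted: DigestPattern,
    rel_tol: float = DEFAULT_REL_TOL,
) -> float:
    """Score agreement between gel-estimated band sizes and a prediction.

    Greedy one-to-one pairing, largest predicted fragment first, each paired
    with the closest unused observed band within ``rel_tol`` of the
    predicted size.  Score is matched pairs / max(#observed, #predicted);
    1.0 means pattern-identical at this tolerance.
    """
    if not observed:
        raise ValueError("observed band list must be non-empty")
    if not (0 < rel_tol < 1):
        raise ValueError("rel_tol must be in (0, 1)")
    remaining = list(observed)
    matched = 0
    for pred in sorted(predicted.fragments, reverse=True):
        candidates = [o for o in remaining if abs(o - pred) <= rel_tol * pred]
        if candidates:
            best = min(candidates, key=lambda o: abs(o - pred))
            remaining.remove(best)
            matched += 1
    return matched / max(len(observed), len(predicted.fragments))


@dataclass
class RflpKey:
    """Per-group digest patterns plus a discriminability verdict."""

    enzyme: str
    patterns: dict[str, DigestPattern]
    indistinguishable_pairs: list[tuple[str, str]]

    @property
    def fully_discriminating(self) -> bool:
        return not self.indistinguishable_pairs


def rflp_key(
    amplicons: list[NucleotideSequence],
    enzyme: RestrictionEnzyme,
    rel_tol: float = DEFAULT_REL_TOL,
) -> RflpKey:
    """Digest one amplicon panel and report which group pairs the enzyme
    cannot tell apart at gel tolerance.

    Each input sequence must carry a ``group_label``; the first member of a
    group defines its pattern.  A group pair is flagged indistinguishable
    when their patterns band-match with score 1.0.
    """
    groups: dict[str, DigestPattern] = {}
    for amp in amplicons:
        if not amp.group_label:
            raise ValueError(f"amplicon {amp.id} has no group label")
        groups.setdefault(amp.group_label, digest(amp, enzyme))
    if len(groups) < 2:
        raise ValueError("rflp_key needs at least two groups")
    names = sorted(groups)
    clashes = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa, pb = groups[a], groups[b]
            if (match_bands(list(pa.fragments), pb, rel_tol) == 1.0
                    and match_bands(list(pb.fragments), pa, rel_tol) == 1.0):
                clashes.append((a, b))
    return RflpKey(enzyme=enzyme.name, patterns=groups, indistinguishable_pairs=clashes)
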