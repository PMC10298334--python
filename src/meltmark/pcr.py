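"""In-silico PCR: degenerate-primer binding sites and product prediction.

Site finding is pure mismatch counting under IUPAC degeneracy — no
thermodynamic binding model.  A site is reported when the primer aligns
ungapped with at most ``max_mismatches`` mismatches and with zero mismatches
in the 3'-terminal ``clamp_len`` bases, the positions that the polymerase
must extend from.  Circular templates (complete mtDNA) are searched across
the origin by doubling the sequence and deduplicating modulo length.

Coordinates are 0-based half-open internally; user-facing reports add 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import IUPAC_SETS, NucleotideSequence, Primer, reverse_complement

__all__ = ["BindingSite", "Amplicon", "MultiplexPattern", "find_binding_sites",
           "amplify", "multiplex_predict"]

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_CLAMP_LEN = 3
DEFAULT_MAX_PRODUCT = 3000


@dataclass(frozen=True)
class BindingSite:
    """One ungapped primer/template alignment.

    ``start`` is the 0-based position of the 5'-most template base covered
    (on the unwrapped template for circular molecules).  On the '-' strand
    the primer matches the reverse complement of the template window.
    """

    template_id: str
    primer_name: str
    start: int
    strand: str  # '+' or '-'
    length: int
    mismatches: int
    three_prime_mismatch: bool = False


@dataclass(frozen=True)
class Amplicon:
    """A located PCR product, footprints of both primers included."""

    template_id: str
    fwd_primer: str
    rev_primer: str
    start: int      # 0-based, 5' end of the forward primer site
    end: int        # 0-based exclusive, covers the reverse primer's 5' end
    length: int
    sequence: str
    fwd_mismatches: int = 0
    rev_mismatches: int = 0


@dataclass(frozen=True)
class MultiplexPattern:
    """The in-silico analogue of a multiplex gel lane."""

    template_id: str
    products: frozenset  # of (pair_name, length)
    pattern_key: tuple   # product lengths sorted descending

    def __str__(self) -> str:
        return "/".join(str(n) for n in self.pattern_key) if self.pattern_key else "(no product)"


def _match_cost(primer_base: str, template_base: str) -> int:
    """0 for a match, 1 for a mismatch.

    Concrete template bases match when they lie in the primer base's
    degeneracy set.  Ambiguous template bases count as mismatches unless the
    primer's set covers every base the template code could be.
    """
    tset = IUPAC_SETS[template_base]
    pset = IUPAC_SETS[primer_base]
    if len(tset) == 1:
        return 0 if template_base in pset else 1
    return 0 if tset <= pset else 1


def _scan(
    template_id: str,
    search_space: str,
    primer: Primer,
    strand: str,
    max_mismatches: int,
    clamp_len: int,
    max_start: int,
) -> list[BindingSite]:
    """Scan one strand; ``search_space`` is already oriented so the primer
    reads 5'->3' left to right ('+') or is compared via its reverse
    complement ('-')."""
    plen = len(primer)
    if strand == "+":
        query = primer.sequence
        # clamp indices: last clamp_len query positions
        clamp_idx = set(range(max(0, plen - clamp_len), plen))
    else:
        query = reverse_complement(primer.sequence)
        # the primer's 3' end maps to the first positions of the window
        clamp_idx = set(range(0, min(clamp_len, plen)))

    sites = []
    limit = len(search_space) - plen
    for s in range(0, min(max_start, limit) + 1):
        mism = 0
        clamp_ok = True
        for i in range(plen):
            if _match_cost(query[i], search_space[s + i]):
                if i in clamp_idx:
                    clamp_ok = False
                    break
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            if clamp_ok:
                sites.append(BindingSite(
                    template_id=template_id, primer_name=primer.name, start=s,
                    strand=strand, length=plen, mismatches=mism,
                ))
    return sites


def find_binding_sites(
    template: NucleotideSequence,
    primer: Primer,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    clamp_len: int = DEFAULT_CLAMP_LEN,
) -> list[BindingSite]:
    """All binding sites of ``primer`` on both strands of ``template``.

    Returns sites sorted by (start, strand).  A primer longer than the
    template yields an empty list.
    """
    if max_mismatches < 0 or clamp_len < 0:
        raise ValueError("max_mismatches and clamp_len must be >= 0")
    n = len(template)
    if len(primer) > n:
        return []
    if template.topology == "circular":
        space = template.bases + template.bases
        max_start = n - 1  # dedupe modulo length: only starts in [0, n)
    else:
        space = template.bases
        max_start = n - len(primer)
    sites = []
    for strand in ("+", "-"):
        sites.extend(_scan(template.id, space, primer, strand,
                           max_mismatches, clamp_len, max_start))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    template: NucleotideSequence,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    clamp_len: int = DEFAULT_CLAMP_LEN,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[Amplicon]:
    """Predict products of one primer pair on one template.

    Every pairing of a '+' forward site with a '-' reverse site whose 5' end
    lies downstream yields a product; the printed length counts both primer
    footprints (5' end of the forward site to the 5' end of the reverse
    site, inclusive).  Results are sorted by length descending.
    """
    if max_product <= 0:
        raise ValueError("max_product must be positive")
    n = len(template)
    circular = template.topology == "circular"
    space = template.bases + template.bases if circular else template.bases

    fwd_sites = [s for s in find_binding_sites(template, fwd, max_mismatches, clamp_len)
                 if s.strand == "+"]
    rev_sites = [s for s in find_binding_sites(template, rev, max_mismatches, clamp_len)
                 if s.strand == "-"]

    products: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for fs in fwd_sites:
        for rs in rev_sites:
            starts = [rs.start]
            if circular:
                starts.append(rs.start + n)  # product may span the origin
            for r0 in starts:
                length = r0 + rs.length - fs.start
                if length < max(fs.length, rs.length):
                    continue
                if length > max_product or (circular and length > n):
                    continue
                key = (fs.start, length)
                if key in seen:
                    continue
                seen.add(key)
                seq = space[fs.start:fs.start + length]
                products.append(Amplicon(
                    template_id=template.id,
                    fwd_primer=fwd.name, rev_primer=rev.name,
                    start=fs.start, end=fs.start + length, length=length,
                    sequence=seq,
                    fwd_mismatches=fs.mismatches, rev_mismatches=rs.mismatches,
                ))
    products.sort(key=lambda a: (-a.length, a.start))
    return products


def multiplex_predict(
    template: NucleotideSequence,
    pairs: list[tuple[Primer, Primer]],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    clamp_len: int = DEFAULT_CLAMP_LEN,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> MultiplexPattern:
    """Predict the banding pattern of several primer pairs in one reaction.

    Products are the union of :func:`amplify` over pairs, deduplicated by
    (pair name, length).  ``pattern_key`` lists lengths sorted descending,
    the in-silico analogue of reading a gel lane top to bottom.  No
    polymerase-competition or dropout model is applied.
    """
    if not pairs:
        raise ValueError("multiplex needs at least one primer pair")
    products = set()
    for f, r in pairs:
        for amp in amplify(template, f, r, max_mismatches, clamp_len, max_product):
            products.add((f"{f.name}:{r.name}", amp.length))
    key = tuple(sorted((length for _, length in products), reverse=True))
    return MultiplexPattern(template_id=template.id, products=frozenset(products),
                            pattern_key=key)
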