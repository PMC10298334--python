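"""Bundled Sparidae assay definitions and synthetic reference genomes.

The bundled primer panel (22 oligos with their reported design Tms) and the
market-survey sample panel are shipped as TSV data.  The reference genomes,
by contrast, are SYNTHETIC: deterministic mtDNA-like circular sequences of
~5 kb with the real primer binding sites planted at coordinates that
reproduce the published amplicon structure of the assays —

* a 706 bp COI barcode (COIpp/COIUnR) containing the 116 bp HRM fragment
  and the multiplex sites (461/295/211 bp from COI4FU with COIR5/COIR4U/
  COIR3), with species-specific HindIII sites;
* a 583 bp cytb fragment (cytbF1/cytbUR) containing the 113 bp HRM fragment,
  with species-specific Sau3AI maps (e.g. 423/90/70 for Greek-caught red
  porgy);
* a 1292 bp control-region fragment (cytbF2/CRR) with an XbaI site in
  Greek-caught red porgy, placed across the circular origin;
* a 681 bp 16s fragment (16sF2/16SR2) containing the 156 bp HRM fragment,
  one base longer in *D. dentex* and *P. caeruleostictus* (planted 1-base
  insertion);
* a 249 bp ND2 fragment (ND2Fd/ND2Rd) and a 673 bp COII–ATP6 fragment
  (COIIF/ATP6R) with species-specific presence.

HRM diagnostic positions inside each short fragment carry an A·T→G·C ladder
so group melting temperatures are ordered and mutually separated; primer
"knockouts" (4 mismatches, two of them in the 3' clamp) remove binding
sites from species that do not amplify a given fragment.

These genomes exist so every assay can be exercised offline; they are not
the real mitogenomes and carry no biological information outside the
planted structure.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import IUPAC_SETS, NucleotideSequence, Primer, load_tables, reverse_complement

__all__ = ["bundled_primers", "bundled_panel", "reference_genomes",
           "HRM_MARKERS", "PP_MULTIPLEX", "DD_MULTIPLEX", "SPECIES_GROUPS",
           "get_primer", "GENOME_SEED"]

GENOME_SEED = 1255

#: HRM marker name -> (forward primer, reverse primer, nominal length)
HRM_MARKERS = {
    "cytb113": ("HRMcytbF2", "HRMcytbR1", 113),
    "16s156": ("HRM16sF1", "HRM16sR1", 156),
    "coi116": ("HRMCOIF1", "HRMCOIR1", 116),
}

#: Multiplex pair sets, red porgy assay and common dentex assay.
PP_MULTIPLEX = [("COI4FU", "COIR5"), ("COI4FU", "COIR4U"), ("COI4FU", "COIR3")]
DD_MULTIPLEX = [("COIIF", "ATP6R"), ("cytbF1", "cytbUR"),
                ("COI4FU", "COIR4U"), ("ND2Fd", "ND2Rd")]

# "COI4RU" appears as an alternate spelling of COIR4U in assay tables.
_PRIMER_ALIASES = {"COI4RU": "COIR4U"}

#: Species group codes: G = Greek-caught, I = imported, M = Mediterranean.
SPECIES_GROUPS = ["PpG", "PpI", "PpM", "Pm", "Pc", "Pe", "Dg", "Dd", "Da"]

_SPECIES_NAMES = {
    "PpG": "Pagrus pagrus", "PpI": "Pagrus pagrus", "PpM": "Pagrus pagrus",
    "Pm": "Pagrus major", "Pc": "Pagrus caeruleostictus", "Pe": "Pagellus erythrinus",
    "Dg": "Dentex gibbosus", "Dd": "Dentex dentex", "Da": "Dentex angolensis",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("meltmark.data").joinpath(name)))


def bundled_primers() -> dict[str, Primer]:
    """The bundled 22-primer Sparidae panel, keyed by primer name."""
    return {p.name: p for p in load_tables(_data_path("sparidae_primers.tsv"), "primers")}


def get_primer(name: str, primers: dict[str, Primer] | None = None) -> Primer:
    """Look a primer up by name, tolerating known alternate spellings."""
    primers = primers or bundled_primers()
    return primers[_PRIMER_ALIASES.get(name, name)]


def bundled_panel():
    """The bundled market-survey sample panel (one row per species × origin)."""
    return load_tables(_data_path("sparidae_panel.tsv"), "panel")


# ---------------------------------------------------------------------------
# Synthetic genome construction

_REGION_ORDER = ["COI", "cytb", "CR", "16s", "ND2", "ATP6"]
_REGION_LEN = {"COI": 706, "cytb": 583, "CR": 1292, "16s": 681, "ND2": 249, "ATP6": 673}
_SPACER_LEN = 120

# Universal plantings: region -> [(primer, region-relative pos, orientation)]
_PLANT = {
    "COI": [("COIpp", 0, "+"), ("COI4FU", 30, "+"), ("HRMCOIF1", 80, "+"),
            ("HRMCOIR1", 177, "-"), ("COIR3", 220, "-"), ("COIR4U", 302, "-"),
            ("COIR5", 472, "-"), ("COIUnR", 680, "-")],
    "cytb": [("cytbF1", 0, "+"), ("HRMcytbF2", 150, "+"),
             ("HRMcytbR1", 240, "-"), ("cytbUR", 560, "-")],
    "CR": [("cytbF2", 0, "+"), ("CRR", 1271, "-")],
    "16s": [("16sF2", 0, "+"), ("HRM16sF1", 300, "+"),
            ("HRM16sR1", 433, "-"), ("16SR2", 660, "-")],
    "ND2": [("ND2Fd", 0, "+"), ("ND2Rd", 221, "-")],
    "ATP6": [("COIIF", 0, "+"), ("ATP6R", 653, "-")],
}

# Diagnostic ladder positions (region-relative, interior of each HRM fragment).
_DIAG = {
    "COI": [106, 116, 126, 136, 146, 156, 166],
    "cytb": [176, 182, 188, 194, 200, 206, 212, 218, 224, 230],
    "16s": [326, 332, 338, 344, 350, 356, 362, 368, 374, 380, 386, 392, 406, 412],
}

# Per-species A.T -> G.C flip counts on each ladder (Tm order of HRM clusters).
_FLIPS = {
    "COI": {"PpG": 0, "PpM": 0, "PpI": 1, "Pm": 2, "Pc": 3, "Pe": 4, "Dg": 5, "Dd": 6, "Da": 7},
    "cytb": {"PpG": 0, "PpM": 0, "PpI": 2, "Pm": 4, "Pc": 6, "Pe": 8, "Dg": 10, "Dd": 0, "Da": 0},
    "16s": {"PpG": 0, "PpM": 0, "PpI": 2, "Pm": 4, "Pc": 6, "Pe": 8, "Dg": 10, "Dd": 12, "Da": 14},
}

# Restriction maps: region-relative recognition-site start positions.
_HINDIII_SITE = {"PpG": 499, "PpM": 499, "Pm": 625, "Dg": 499, "Dd": 455, "Da": 455}
_SAU3AI_CUTS = {"PpG": (70, 493), "PpM": (70, 493), "PpI": (50, 500),
                "Pm": (423,), "Pc": (433,), "Pe": (383,)}
_XBAI_SITE = {"PpG": 499, "PpM": 499}

# Primer binding sites removed per species (4 mismatches incl. the clamp).
_KNOCKOUTS = {
    "PpG": {"COIIF"}, "PpI": {"COIIF"}, "PpM": {"COIIF"},
    "Pm": {"COIIF", "COIR5", "COIR3", "COIR4U"},
    "Pc": {"COIIF", "COIR5", "COIR3"},
    "Pe": {"COIIF", "COIR5", "COIR3"},
    "Dg": {"COIR5", "COIR3"},
    "Dd": {"COIIF", "COI4FU", "cytbF1", "COIR5", "COIR3"},
    "Da": {"COIIF", "COIR5", "COIR3", "ND2Fd"},
}

#: Species whose 16s fragment carries a 1-base insertion (region pos 400).
_16S_INSERTION = {"Dd", "Pc"}
_16S_INSERT_POS = 400

_FORBIDDEN_WORDS = ("GATC", "AAGCTT", "TCTAGA")

# genome rotation so the control-region amplicon spans the circular origin
_ROTATION = _SPACER_LEN + 706 + _SPACER_LEN + 583 + _SPACER_LEN + 600


def _concretize(seq: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT" else sorted(IUPAC_SETS[c])[0] for c in seq)


def _scrub(region: np.ndarray, protected: np.ndarray, allowed: set[int],
           word_positions_ok: dict[str, set[int]]) -> None:
    """Remove accidental restriction words, never touching planted bases."""
    text = "".join(region)
    for _ in range(200):
        dirty = False
        for word in _FORBIDDEN_WORDS:
            start = text.find(word)
            while start != -1:
                if start not in word_positions_ok.get(word, set()):
                    for i in range(start, start + len(word)):
                        if not protected[i]:
                            region[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[region[i]]
                            dirty = True
                            break
                    else:
                        raise AssertionError(
                            f"accidental {word} at {start} overlaps planted bases only"
                        )
                    text = "".join(region)
                start = text.find(word, start + 1)
        if not dirty:
            return
    raise AssertionError("could not scrub accidental restriction sites")


def _mismatch_base(iupac_char: str, current: str) -> str:
    for b in "ACGT":
        if b not in IUPAC_SETS[iupac_char] and b != current:
            return b
    raise AssertionError(f"cannot pick mismatch base for {iupac_char}")


def _build_regions(rng: np.random.Generator, primers: dict[str, Primer]):
    """Ancestral region arrays with universal plantings, plus bookkeeping.

    ``intrinsic`` records restriction words that occur inside the planted
    primer sequences themselves (e.g. HRM16sF1 carries a GATC); they are
    unavoidable, left in place and accounted for in the final checks.
    """
    regions: dict[str, np.ndarray] = {}
    protected: dict[str, np.ndarray] = {}
    footprints: dict[str, tuple[str, int, str, int]] = {}
    intrinsic: dict[str, dict[str, set[int]]] = {}
    for name in _REGION_ORDER:
        n = _REGION_LEN[name]
        arr = rng.choice(np.array(list("ACGT")), size=n)
        prot = np.zeros(n, dtype=bool)
        intr: dict[str, set[int]] = {}
        for pname, pos, orient in _PLANT[name]:
            seq = _concretize(primers[pname].sequence, rng)
            if orient == "-":
                seq = reverse_complement(seq)
            arr[pos:pos + len(seq)] = list(seq)
            prot[pos:pos + len(seq)] = True
            footprints[pname] = (name, pos, orient, len(seq))
            for word in _FORBIDDEN_WORDS:
                start = seq.find(word)
                while start != -1:
                    intr.setdefault(word, set()).add(pos + start)
                    start = seq.find(word, start + 1)
        for pos in _DIAG.get(name, ()):
            arr[pos] = rng.choice(np.array(list("AT")))
            prot[pos] = True
        regions[name] = arr
        protected[name] = prot
        intrinsic[name] = intr
    spacers = {
        i: rng.choice(np.array(list("ACGT")), size=_SPACER_LEN)
        for i in range(len(_REGION_ORDER) + 1)
    }
    return regions, protected, footprints, spacers, intrinsic


def _species_genome(code: str, regions, protected, footprints, spacers,
                    primers, intrinsic) -> NucleotideSequence:
    parts: dict[str, np.ndarray] = {k: v.copy() for k, v in regions.items()}
    prot: dict[str, np.ndarray] = {k: v.copy() for k, v in protected.items()}
    planted_ok: dict[str, dict[str, set[int]]] = {
        k: {w: set(pos) for w, pos in intrinsic[k].items()} for k in parts
    }

    # diagnostic ladders
    for region, flips in _FLIPS.items():
        for pos in _DIAG[region][: flips[code]]:
            base = parts[region][pos]
            parts[region][pos] = "G" if base == "A" else "C"

    # restriction sites
    def plant_word(region: str, word: str, pos: int) -> None:
        parts[region][pos:pos + len(word)] = list(word)
        prot[region][pos:pos + len(word)] = True
        planted_ok[region].setdefault(word, set()).add(pos)

    if code in _HINDIII_SITE:
        plant_word("COI", "AAGCTT", _HINDIII_SITE[code])
    for cut in _SAU3AI_CUTS.get(code, ()):
        plant_word("cytb", "GATC", cut)
    if code in _XBAI_SITE:
        plant_word("CR", "TCTAGA", _XBAI_SITE[code])

    # knockouts: 4 mismatches, 2 of them inside the 3' clamp
    for pname in _KNOCKOUTS[code]:
        region, pos, orient, length = footprints[pname]
        primer = primers[pname].sequence
        if orient == "+":
            offsets = [length - 1, length - 2, length - 6, length - 10]
            iupac = primer
        else:
            offsets = [0, 1, 5, 9]
            iupac = reverse_complement(primer)
        for off in offsets:
            cur = parts[region][pos + off]
            parts[region][pos + off] = _mismatch_base(iupac[off], cur)
            prot[region][pos + off] = True  # scrubbing must not restore binding

    for region in parts:
        _scrub(parts[region], prot[region], set(), planted_ok[region])

    # 16s one-base insertion
    seq16 = "".join(parts["16s"])
    if code in _16S_INSERTION:
        seq16 = seq16[:_16S_INSERT_POS] + "C" + seq16[_16S_INSERT_POS:]

    pieces = []
    texts = {"16s": seq16}
    for i, region in enumerate(_REGION_ORDER):
        pieces.append("".join(spacers[i]))
        pieces.append(texts.get(region, "".join(parts[region])))
    pieces.append("".join(spacers[len(_REGION_ORDER)]))
    genome = "".join(pieces)
    genome = genome[_ROTATION:] + genome[:_ROTATION]

    # consistency check: restriction words occur exactly where planted,
    # plus those intrinsic to the planted primer sequences
    intr_count = {w: sum(len(intrinsic[r].get(w, ())) for r in intrinsic)
                  for w in _FORBIDDEN_WORDS}
    expected = {
        "AAGCTT": (1 if code in _HINDIII_SITE else 0) + intr_count["AAGCTT"],
        "GATC": len(_SAU3AI_CUTS.get(code, ())) + intr_count["GATC"],
        "TCTAGA": (1 if code in _XBAI_SITE else 0) + intr_count["TCTAGA"],
    }
    for word, n in expected.items():
        found = genome.count(word)
        if found != n:
            raise AssertionError(f"{code}: {word} occurs {found} times, expected {n}")

    return NucleotideSequence(
        id=f"SYN_{code}_mtDNA",
        bases=genome,
        topology="circular",
        species_label=_SPECIES_NAMES[code],
        group_label=code,
    )


def reference_genomes(seed: int = GENOME_SEED) -> dict[str, NucleotideSequence]:
    """Synthetic circular reference genomes for all nine species groups.

    Deterministic in ``seed``; the same seed reproduces identical FASTA
    bytes.  All genomes share one ancestral background so that the only
    differences between species are the planted diagnostics, restriction
    maps, knockouts and the 16s insertion.
    """
    rng = np.random.default_rng(seed)
    primers = bundled_primers()
    regions, protected, footprints, spacers, intrinsic = _build_regions(rng, primers)
    # scrub the shared ancestor once so per-species scrubbing is minimal
    for name in _REGION_ORDER:
        _scrub(regions[name], protected[name], set(), intrinsic[name])
    for i in spacers:
        _scrub(spacers[i], np.zeros(_SPACER_LEN, dtype=bool), set(), {})
    return {
        code: _species_genome(code, regions, protected, footprints, spacers,
                              primers, intrinsic)
        for code in SPECIES_GROUPS
    }
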