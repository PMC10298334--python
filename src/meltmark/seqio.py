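"""Sequence, alignment and table I/O with IUPAC nucleotide semantics.

Everything downstream (primer matching, digestion, marker design) relies on
the degeneracy sets defined here, so this module is the single authority on
the 15-letter IUPAC DNA alphabet and on the file dialects the toolkit reads:
plain/aligned FASTA, GenBank flat files (sequence + LOCUS topology only),
and TSV/CSV tables for primers, sample panels and melt-curve exports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "NucleotideSequence",
    "Primer",
    "Alignment",
    "SamplePanel",
    "ParseError",
    "SchemaError",
    "load_sequences",
    "load_alignment",
    "load_tables",
    "write_fasta",
    "write_curves",
    "reverse_complement",
    "iupac_match",
    "expand_degenerate",
    "is_concrete",
]

#: Degeneracy set of every IUPAC DNA code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}


class ParseError(ValueError):
    """Raised when a file or string violates the expected dialect."""


class SchemaError(ParseError):
    """Raised when a delimited table is missing a mandatory column."""


def _canonical_bases(raw: str, *, where: str = "", allow_gaps: bool = False) -> str:
    """Uppercase, map U->T and validate against the IUPAC alphabet.

    The only accepted gap character is '-'; '.' is rejected so a single
    alignment dialect reaches the rest of the toolkit.
    """
    bases = raw.upper().replace("U", "T")
    allowed = set(IUPAC_SETS)
    if allow_gaps:
        allowed.add("-")
    for pos, char in enumerate(bases):
        if char not in allowed:
            raise ParseError(
                f"illegal character {char!r} at position {pos + 1}"
                + (f" in {where}" if where else "")
            )
    if not bases:
        raise ParseError(f"empty sequence{' in ' + where if where else ''}")
    return bases


@dataclass
class NucleotideSequence:
    """An IUPAC DNA sequence with optional species/group annotation.

    ``topology`` is ``"linear"`` by default; ``"circular"`` marks complete
    mitochondrial genomes so that PCR site searches wrap the origin.
    """

    id: str
    bases: str
    topology: str = "linear"
    species_label: str | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.bases = _canonical_bases(self.bases, where=self.id)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_concrete(self) -> bool:
        return is_concrete(self.bases)


@dataclass
class Primer:
    """A 5'->3' oligonucleotide, possibly degenerate, with an optional
    vendor/design-tool melting temperature in deg C."""

    name: str
    sequence: str
    reported_tm: float | None = None

    def __post_init__(self) -> None:
        self.sequence = _canonical_bases(self.sequence, where=self.name)
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name}: length {len(self.sequence)} < 10")
        if self.reported_tm is not None and not (30.0 < self.reported_tm < 80.0):
            raise ValueError(f"primer {self.name}: reported_tm {self.reported_tm} outside (30, 80)")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """A gapped multiple alignment; all rows share one column count."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        cleaned = []
        width = None
        for rid, bases in self.rows:
            bases = _canonical_bases(bases, where=rid, allow_gaps=True)
            if width is None:
                width = len(bases)
            elif len(bases) != width:
                raise ParseError(f"row {rid} has length {len(bases)}, expected {width}")
            cleaned.append((rid, bases))
        self.rows = cleaned

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, bases in self.rows:
            if r == rid:
                return bases
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")

    def column(self, idx: int) -> list[str]:
        return [bases[idx] for _, bases in self.rows]


_PANEL_COLUMNS = [
    "species", "sample_id", "region", "fao_region",
    "n_total", "n_fc", "n_fm_sm", "n_re", "n_frozen", "n_cooked",
]


@dataclass
class SamplePanel:
    """Bookkeeping table of a sampling survey: per-row species, group code,
    collection region and counts by acquisition route / state."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"panel table missing columns: {missing}")
        counts = self.table[["n_total", "n_fc", "n_fm_sm", "n_re", "n_frozen", "n_cooked"]]
        if (counts < 0).any().any():
            raise ValueError("panel counts must be >= 0")
        for col in ("n_fc", "n_fm_sm", "n_re", "n_frozen", "n_cooked"):
            bad = self.table[self.table[col] > self.table["n_total"]]
            if len(bad):
                raise ValueError(f"{col} exceeds n_total in row(s) {list(bad.index)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_samples(self) -> int:
        return int(self.table["n_total"].sum())


# ---------------------------------------------------------------------------
# IUPAC primitives

def is_concrete(bases: str) -> bool:
    """True when every base is one of A/C/G/T."""
    return all(c in "ACGT" for c in bases)


def reverse_complement(bases: str) -> str:
    """IUPAC-aware reverse complement; an involution on valid input."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(bases.upper().replace("U", "T")))
    except KeyError as exc:
        raise ParseError(f"illegal character {exc.args[0]!r}") from exc


def iupac_match(primer_base: str, template_base: str) -> bool:
    """Whether a concrete template base falls in the primer base's degeneracy set.

    Templates must be concrete; call sites that tolerate ambiguous templates
    decide separately how to score them.
    """
    if template_base not in "ACGT":
        raise ValueError(f"template base must be concrete A/C/G/T, got {template_base!r}")
    try:
        return template_base in IUPAC_SETS[primer_base]
    except KeyError as exc:
        raise ParseError(f"illegal primer base {primer_base!r}") from exc


def expand_degenerate(bases: str, max_expansions: int = 64) -> list[str]:
    """All concrete sequences compatible with a degenerate one.

    The expansion count is the product of per-position degeneracies and is
    capped to keep downstream averaging bounded.
    """
    count = 1
    for c in bases:
        count *= len(IUPAC_SETS[c])
        if count > max_expansions:
            raise ValueError(
                f"degenerate sequence expands to more than {max_expansions} concrete sequences"
            )
    out = [""]
    for c in bases:
        out = [prefix + b for prefix in out for b in sorted(IUPAC_SETS[c])]
    return out


# ---------------------------------------------------------------------------
# Sequence I/O

def load_sequences(path: str | Path, format: str = "fasta") -> list[NucleotideSequence]:
    """Read FASTA or GenBank records into :class:`NucleotideSequence` objects.

    FASTA ids are taken verbatim up to the first whitespace.  GenBank records
    carry the accession as id and honour the LOCUS line's circular flag.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"format must be fasta or genbank, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[NucleotideSequence] = []
    for rec in SeqIO.parse(str(path), format):
        topology = "linear"
        if format == "genbank":
            if str(rec.annotations.get("topology", "linear")).lower() == "circular":
                topology = "circular"
            rid = rec.id
        else:
            rid = rec.id
        out.append(NucleotideSequence(id=rid, bases=str(rec.seq), topology=topology))
    return out


def load_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA ('-' gaps) into an :class:`Alignment`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ParseError(f"no records in {path}")
    return Alignment(rows=rows)


def write_fasta(
    sequences: Iterable[NucleotideSequence] | Alignment, path: str | Path
) -> None:
    """Write sequences (or a gapped alignment) as FASTA.

    Circular topology is recorded as a ``[circular]`` token in the
    description so a write/load round trip preserves it.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(sequences, Alignment):
            for rid, bases in sequences.rows:
                fh.write(f">{rid}\n{bases}\n")
        else:
            for seq in sequences:
                topo = " [circular]" if seq.topology == "circular" else ""
                fh.write(f">{seq.id}{topo}\n{seq.bases}\n")


def _load_fasta_with_topology(path: str | Path) -> list[NucleotideSequence]:
    """Round-trip-aware FASTA reader honouring the ``[circular]`` token."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = "circular" if "[circular]" in rec.description else "linear"
        out.append(NucleotideSequence(id=rec.id, bases=str(rec.seq), topology=topo))
    return out


# ---------------------------------------------------------------------------
# Delimited tables

def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        # keep_default_na=False preserves literal "NA" region codes; fillna
        # covers rows with missing trailing fields
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False).fillna("")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no header row") from exc


def load_tables(path: str | Path, kind: str):
    """Load a delimited table of the given ``kind``.

    * ``primers`` -> list of :class:`Primer` (columns name, sequence, tm;
      blank tm allowed);
    * ``panel``  -> :class:`SamplePanel` (survey schema; blank counts are 0);
    * ``curves`` -> list of :class:`~meltmark.thermo.MeltCurve`, one per
      non-temperature column (column 1 must be ``temperature_C``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)

    if kind == "primers":
        required = {"name", "sequence", "tm"}
        if not required.issubset(df.columns):
            raise SchemaError(f"primer table needs columns {sorted(required)}, got {list(df.columns)}")
        primers = []
        for i, row in df.iterrows():
            tm_text = str(row["tm"]).strip()
            try:
                tm = float(tm_text) if tm_text else None
            except ValueError as exc:
                raise ParseError(f"row {i + 2}: non-numeric tm {tm_text!r}") from exc
            primers.append(Primer(name=row["name"], sequence=row["sequence"], reported_tm=tm))
        return primers

    if kind == "panel":
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"panel table missing columns: {missing}")
        out = df.copy()
        for col in ("n_total", "n_fc", "n_fm_sm", "n_re", "n_frozen", "n_cooked"):
            cells = out[col].astype(str).str.strip().replace("", "0")
            try:
                out[col] = cells.astype(int)
            except ValueError as exc:
                bad = [i + 2 for i, v in enumerate(cells) if not v.lstrip("-").isdigit()]
                raise ParseError(f"non-numeric count in column {col}, row(s) {bad}") from exc
        return SamplePanel(table=out.reset_index(drop=True))

    if kind == "curves":
        from .thermo import MeltCurve  # local import avoids a module cycle

        if df.columns[0] != "temperature_C":
            raise SchemaError(f"first curve column must be temperature_C, got {df.columns[0]!r}")
        try:
            temps = df["temperature_C"].astype(float).to_numpy()
        except ValueError as exc:
            raise ParseError("non-numeric temperature value") from exc
        curves = []
        for col in df.columns[1:]:
            try:
                fluor = df[col].astype(float).to_numpy()
            except ValueError as exc:
                raise ParseError(f"non-numeric fluorescence in column {col!r}") from exc
            curves.append(MeltCurve(sample_id=col, temperatures=temps, fluorescence=fluor))
        return curves

    raise ValueError(f"unknown table kind {kind!r}")


def write_curves(curves: Sequence, path: str | Path) -> None:
    """Write melt curves to the TSV dialect ``load_tables(..., 'curves')`` reads."""
    if not curves:
        raise ValueError("no curves to write")
    data = {"temperature_C": curves[0].temperatures}
    for c in curves:
        data[c.sample_id] = c.fluorescence
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False)
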