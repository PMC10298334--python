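# meltmark

In-silico PCR, PCR-RFLP, nearest-neighbor melting thermodynamics and
high-resolution-melting (HRM) analysis for mitochondrial-DNA-based species
identification — built around the marker panel used to authenticate
commercially traded Sparidae (red porgy *Pagrus pagrus*, common dentex
*Dentex dentex*, and the look-alike species they are substituted with).

Seafood mislabeling is detected by molecular assays on short mitochondrial
fragments: a ~700 bp *COI* barcode and *cytb*/*16s*/control-region fragments
analysed by restriction digestion, multiplex PCR band patterns, or melting
of 113–156 bp amplicons in an HRM instrument. `meltmark` re-creates every
post-wet-lab step of that workflow so assays can be designed, predicted and
validated entirely in software, and ships a deterministic synthetic-data
module so everything runs with no downloads.

## What the package computes

- **In-silico PCR** (`meltmark.pcr`) — IUPAC-degenerate primer binding-site
  search by mismatch counting with a 3'-clamp (no mismatches allowed in the
  terminal bases), on both strands, across the origin of circular mtDNA;
  single-pair product prediction and multiplex "gel lane" patterns.
- **Duplex thermodynamics** (`meltmark.thermo`) — unified nearest-neighbor
  ΔH/ΔS sums with terminal A·T initiation penalties and the entropy salt
  correction 0.368·(N−1)·ln[Na⁺]; oligo Tm via
  `Tm = ΔH·1000 / (ΔS + R·ln(C_T/4)) − 273.15`. Amplicon melt curves use a
  unimolecular two-state helicity `θ(T) = 1/(1 + exp[(ΔH/R)(1/Tm − 1/T)])`,
  optionally averaged over sliding windows for multi-domain products.
  Because the primer panel's published Tms come with no stated formula, one
  global (Na⁺, strand-concentration) convention is calibrated once by least
  mean-absolute-error against all 22 reported values.
- **PCR-RFLP** (`meltmark.rflp`) — fragment patterns for HindIII, Sau3AI and
  XbaI (palindromic sites, top-strand scan), greedy band matching at gel
  tolerance (±12% by default), and per-group digest keys with an explicit
  verdict on which species pairs an enzyme cannot separate.
- **HRM analysis** (`meltmark.hrm`) — baseline normalization between
  pre-/post-melt windows, difference curves, and a deterministic two-stage
  clustering reconstruction of the two documented software knobs: a Tm
  difference threshold (single-linkage on estimated Tm) and a curve-shape
  sensitivity (average-linkage on RMS curve distance, cut at
  `(1 − sensitivity/100) · max pairwise distance`). Per-sample confidence is
  a Gaussian softmax over clusters; unknowns that do not join a labeled
  cluster at the confidence floor are reported as possible new variants.
- **Marker design** (`meltmark.design`) — scan a multi-species alignment for
  100–160 bp windows that are identical within groups, discriminate every
  required group pair at an interior column, and carry near-conserved flanks
  from which (possibly degenerate) universal primers are read off.
- **Synthetic data** (`meltmark.synth`, `meltmark.sparidae`) — seeded
  generators for group-structured panels with planted diagnostic ladders,
  melt-curve plates with instrument baselines and noise, market surveys with
  known mislabels, and ~5 kb synthetic circular reference genomes carrying
  the real primer sites at coordinates that reproduce the published amplicon
  sizes and restriction maps.
- **Pipeline + CLI** (`meltmark.pipeline`, `meltmark.cli`) — reference-assay
  construction, sample identification with mislabel flagging, survey-panel
  bookkeeping, and a `meltmark` command with subcommands `amplify`,
  `multiplex`, `digest`, `tm`, `melt`, `normalize`, `cluster`, `identify`,
  `design` and `simulate-*`.

## Worked example

```python
from meltmark.sparidae import reference_genomes, bundled_primers
from meltmark.pcr import amplify
from meltmark.rflp import digest, get_enzyme
from meltmark.pipeline import build_reference, identify_sample
from meltmark.hrm import HRMConfig
from meltmark.seqio import NucleotideSequence

genomes = reference_genomes()          # synthetic labeled reference mtDNAs
primers = bundled_primers()            # the 22-primer assay panel

# 1. amplify the cytb fragment on Greek-caught red porgy and digest it
amp = amplify(genomes["PpG"], primers["cytbF1"], primers["cytbUR"])[0]
print("cytb amplicon:", amp.length, "bp")
print("Sau3AI digest:", digest(amp.sequence, get_enzyme("Sau3AI")))

# 2. build an HRM reference on the 113 bp cytb marker and identify a sample
refs = [genomes[c] for c in ("PpG", "PpI", "Pm", "Pc", "Pe", "Dg")]
assay = build_reference(refs, primers["HRMcytbF2"], primers["HRMcytbR1"],
                        HRMConfig(), seed=0)
sample = NucleotideSequence(id="market_sample_07", bases=genomes["Pm"].bases,
                            topology="circular")
call = identify_sample(sample, assay, declared_label="PpG")
print(f"call={call.call} confidence={call.confidence:.1f}% "
      f"mislabel={call.mislabel_flag}")
```

prints

```
cytb amplicon: 583 bp
Sau3AI digest: 423/90/70
call=Pm confidence=100.0% mislabel=True
```

The 583 bp amplicon and the ~420/90/70 Sau3AI pattern are the diagnostic
signature of Greek-caught *P. pagrus*; the sample declared as `PpG` melts
with the *P. major* cluster at full confidence, so it is flagged as
mislabeled — the aquaculture-substitution scenario the assay exists to
catch.

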