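# Methods

This note records the models behind `meltmark`, the defaults that matter,
what the synthetic data does and does not emulate, and the places where the
design was genuinely open.

## In-silico PCR

Primer binding is modeled by ungapped mismatch counting under IUPAC
degeneracy — no hybridization thermodynamics. A site is accepted when at
most `max_mismatches` (default 2) positions mismatch and the 3'-terminal
`clamp_len` bases (default 3) match perfectly; the clamp models the
polymerase's requirement for a paired 3' end, and the 2-mismatch budget
reflects that several panel primers were designed on other taxa and must
still prime on every Sparidae template. A concrete template base matches
when it lies in the primer base's degeneracy set; an ambiguous template base
counts as a mismatch unless the primer's set covers every base it could be.

Circular templates (complete mtDNA) are searched on the doubled sequence
with site starts deduplicated modulo length, so products spanning the
replication origin — the control-region amplicon in the bundled fixtures is
deliberately placed there — are found and unwrapped. Product length counts
both primer footprints (5' end of the forward site to the 5' end of the
reverse site, inclusive), matching how amplicon sizes are conventionally
printed. All overlapping/nested products are reported; polymerase
competition and the dropout of long products in degraded samples are out of
scope. Coordinates are 0-based half-open internally and 1-based inclusive
in CLI output.

## Nearest-neighbor thermodynamics

Duplex ΔH and ΔS are sums of unified nearest-neighbor stack terms plus
initiation terms with the terminal A·T penalty; parameters live in
`src/meltmark/data/nn_unified.json` (kcal/mol and cal/(mol·K) at the 1 M
Na⁺ reference state) so an alternative set can be swapped without touching
code. The entropy salt correction is `0.368·(N−1)·ln([Na⁺]/1 M)`
cal/(mol·K). Oligo Tm uses the bimolecular, non-self-complementary form
`ΔH·1000/(ΔS + R·ln(C_T/4)) − 273.15` with R = 1.987 cal/(mol·K).
Degenerate primers are averaged over all concrete expansions (capped at 64):
ΔH/ΔS as expansion means, Tm as the mean of per-expansion Tms, mirroring
common design-tool behavior.

The bundled primer panel reports design Tms without naming the formula or
conditions that produced them. We therefore calibrate one global
(Na⁺, total strand concentration) pair by minimizing the mean absolute
error against all 22 reported values — coarse grid search then Nelder–Mead
in log space, fully deterministic. The fit lands at ≈91 mM Na⁺ and
≈0.83 µM total strand; those values are frozen as the package defaults
(`DEFAULT_NA_MM`, `DEFAULT_STRAND_CONC_M`) and the fit itself achieves
MAE ≈ 0.95 °C with no single error above ≈2.2 °C. `calibrate_convention`
re-runs the fit at any time; `scripts/acceptance.py` does exactly that.

Amplicon melting uses a unimolecular two-state approximation: helicity
`θ(T) = 1/(1 + exp[(ΔH_melt/R)(1/T_m − 1/T)])` with `T_m = ΔH/ΔS`
(salt-corrected) and no concentration term — long products re-anneal
intramolecularly on HRM timescales, and the observables that matter
downstream are curve shape and relative ΔTm, not absolute Tm. The
`windowed` variant averages per-window θ over overlapping windows (default
50 bp windows stepped by 10 bp, the tail window pinned to the 3' end),
producing staged transitions for amplicons with domains of unequal
stability. Full partition-function melting, heteroduplexes and dye kinetics
are not modeled. A single A·T→G·C substitution in a 113 bp amplicon shifts
the two-state Tm by ≈0.35–0.45 °C under the default convention, which is
what makes single-SNP discrimination at a 0.2 °C threshold plausible.

## PCR-RFLP

Only palindromic enzymes are accepted (HindIII A^AGCTT, Sau3AI ^GATC, XbaI
T^CTAGA are built in), so a top-strand scan finds every site; overlapping
occurrences are counted. Zero sites yield one full-length fragment — a
species lacking the site is representable, and several are in the bundled
fixtures. Fragments always sum to the input length. Band matching against
gel estimates uses greedy one-to-one pairing within a relative tolerance,
default 0.12: printed gel sizes in this assay family carry roughly ±10%
read-off error. Fragments under 40 bp are kept but flagged as possibly
unresolvable (50 bp ladder floor). Methylation sensitivity, star activity
and partial digests are out of scope.

## HRM analysis

Raw plate curves are normalized by fitting least-squares straight baselines
in a pre-melt and a post-melt temperature window and rescaling to
`100·(F − lower)/(upper − lower)` over the window-bounded range; the Tm
estimate is the linearly interpolated 50% crossing (the steepest crossing
wins if noise creates several). Baselines fitted in windows far from the
transition extrapolate noise into the melt region; placing the windows
close around the transition — as melt-analysis software does when it sets
the melt region — keeps replicate Tm estimates tight. The package defaults
(first and last 2 °C of the 65–95 °C, 0.2 °C grid) are deliberately generic;
assay-specific configs should narrow them.

The clustering is an explicit reconstruction of the two knobs that
commercial melt-analysis software documents without disclosing its
algorithm, and is stated as such:

1. **Tm difference threshold** (default 0.2 °C): single-linkage grouping on
   estimated Tm — samples separated by at least the threshold can never
   share a cluster. Curves that never cross 50% skip this stage, are
   clustered by shape only and flagged.
2. **Shape sensitivity** (default 75%): within each Tm group,
   average-linkage hierarchical clustering on the RMS distance between
   normalized curves, cut at `d_cut = (1 − sensitivity/100) · d_scale`,
   where `d_scale` is the largest pairwise RMS distance in the whole
   dataset. The linear mapping from the percentage to the cut height is our
   committed interpretation of the knob.

Confidence for sample *i* in cluster *c* is
`100·exp(−d_ic²/2σ²) / Σ_c' exp(−d_ic'²/2σ²)` with `d_ic` the RMS distance
to the cluster mean and σ the pooled within-cluster RMS deviation (floored
at 10⁻³); confidences sum to 100 per sample. The published per-sample
confidence percentages of the vendor software are software-specific and are
not reproduction targets; this definition is per-sample because reported
ranges span samples. Everything is deterministic: no random initialization,
ties broken on sorted sample id, cluster ids ordered by mean Tm. Difference
curves are a reporting view; clustering uses the normalized curves directly
(identical information, simpler metric). Temperature superimposition
(`shift_curves`) exists but is off by default.

Unknown assignment re-clusters the unknown with the reference curves. A
call requires joining a labeled cluster at the confidence floor (default
95%); otherwise the sample is reported as "unassigned — possible new
variant" with the nearest labeled cluster as evidence — matching how a
novel single-SNP haplotype should behave rather than being forced into the
nearest group.

## Marker design

Candidate windows are aligned-column ranges of 100–160 bp (the deployed
fragments run 113–156 bp; the upper default is set to cover the longest)
satisfying: column-identity within every group; at least one interior
column separating each required group pair; and at most 2 variable columns
in each 18-column flank across *all* sequences, so near-universal primers
can be read off the flank consensus with IUPAC codes at the variable
positions (more than 3 degenerate positions rejects the candidate).
Candidates are ranked by diagnostic-column count, ties to the shorter
window. Windows containing indel columns are allowed and flagged — the 16s
marker in the bundled fixtures carries a one-base insertion in two species,
so per-group amplicon lengths are reported after gap removal. Separation
prediction reports per-pair percent identity (gaps count as differences)
and the simulated |ΔTm| between group-consensus amplicons; a pair is
HRM-separable when |ΔTm| reaches the Tm threshold or the curve RMS distance
reaches a shape floor. By default every group pair must be discriminated;
an asymmetric goal (one target group against everything) is expressed by
listing only the pairs that contain it.

## Synthetic data

Two generators exist, with different jobs.

`meltmark.synth` builds abstract group-structured panels: a uniform random
ancestor, group consensi mutated at the between-group rate (default
0.02 substitutions/site), members mutated at the within-group rate (default
0.005), and one or more planted marker windows. Marker windows are exempt
from both background mutation processes; inside a marker the only
between-group differences are a planted A·T→G·C ladder (group *g* carries
`g·diag_step` flips, default step 2, giving ordered group Tms spaced by
≈0.7–0.9 °C) plus optional one-base indels. This mirrors how real
diagnostic fragments are *selected* — for intra-group identity and known
inter-group SNPs — rather than how neutral sequence evolves; it is a
generator of assay conditions, not a phylogenetic simulator (no trees, no
rate heterogeneity; substitutions are uniform over the twelve base changes
with an optional transition bias). Marker windows are drawn at ≈40% GC,
typical of the mitochondrial fragments being emulated, so that even the
most GC-shifted group finishes melting well inside the 65–95 °C ramp. Melt
plates add, per replicate curve, a random linear baseline (slope −0.10 to
−0.02 units/°C, offset 8–12 units — instrument drift that exercises
normalization) and i.i.d. Gaussian noise (default sd 0.3 fluorescence
units). Market surveys draw samples with declared labels and mislabel a
seeded fraction, recording the truth table. All randomness flows through
one `numpy` generator per call; identical seeds give identical bytes.

`meltmark.sparidae` builds the nine species-group reference genomes
(~5 kb, circular, SYNTHETIC — stated in ids and docstrings): one shared
ancestral background in which the real 22 primers are planted at
coordinates reproducing the published amplicon sizes (COI 706, cytb 583,
16s 681, control region 1292, ND2 249, HRM 113/156/116, multiplex
461/295/211), with species-specific restriction-site maps, a one-base 16s
insertion in *D. dentex* and *P. caeruleostictus*, HRM diagnostic ladders
inside each short fragment, and primer-site knockouts (4 mismatches, two in
the clamp) for species that do not amplify a given fragment. A construction-
time check verifies every restriction word occurs exactly where planted
(sites intrinsic to the primer sequences themselves are accounted for).
What passing tests on these fixtures shows is that the *workflow logic* —
site finding, digestion, melting, clustering, calling — reproduces the
published assay behavior on templates with exactly the published structure;
it says nothing about primer specificity or amplification efficiency on
real genomic backgrounds.

## Numerical and interface choices

- Problem sizes in the test suite: HRM recovery runs 100 seeded replicates
  of a 6-group panel (2 members × 3 replicate curves, 151-point grid);
  marker-design validation enumerates all windows of 50 seeded 300-column
  alignments against an independent brute-force validator. Both finish in
  well under a minute on one core.
- The two-state exponent is clipped at ±500 before `exp` to stay finite on
  wide grids; the confidence softmax is computed with a per-row max shift.
- Survey-panel counts: blank cells in the bundled table are zeros; the
  "frozen/filleted" and "cooked" columns are stored as independent
  out-of-total counts since their overlap is not documented.
- `load_sequences` takes FASTA ids verbatim up to the first whitespace;
  `U` is accepted on input and canonicalized to `T`; the only gap character
  is `-`.
- Exit codes of the CLI: 0 success, 2 input/schema error, 3 no-product or
  unassignable — so batch surveillance scripts can branch on them.

## Known limitations

- Binding-site search has no thermodynamic model: a primer with three
  spread-out mismatches is rejected even if it would prime at low annealing
  temperature, and primer-dimer/hairpin screening is absent.
- Absolute amplicon Tms from the unimolecular model are systematically high
  relative to instrument readings; only Tm differences and curve shapes are
  meaningful, which is all the clustering consumes.
- The shape-sensitivity knob's linear mapping to an average-linkage cut is
  one reconstruction of an undocumented proprietary algorithm; cluster
  *memberships* are the supported output, not vendor-identical confidence
  numbers.
- The synthetic genomes share one background; cross-reactivity of primers
  with off-target loci, pseudogenes, or nuclear copies of mitochondrial
  genes cannot be studied on them.
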