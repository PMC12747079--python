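# Methods

This note records the models behind each module, the parameters that
matter, the synthetic-data assumptions, and the numerical choices made
where the design was genuinely open.

## Coordinates and sequences

All intervals are 0-based half-open internally; GFF3 output converts to
1-based closed, BED stays 0-based half-open. Sequences are uppercase
A/C/G/T/N strings. Ambiguous bases (N) are excluded from every GC
denominator and never match anything in repeat or TSD comparisons.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *signal structure* the detectors rely on,
not the full texture of real genomes:

- **Host background** is i.i.d. per-base with P(G)+P(C) = gc (default
  0.52, the host nuclear genome's composition class). There is no
  higher-order composition, no repeat landscape, no genes. This is
  sufficient to test GC segmentation, which only consumes windowed base
  counts; it does not test robustness to compositional heterogeneity
  (isochores, simple-sequence repeats) found in real chromosomes.
- **Telomeres** are written as perfect tandem tracts (12 motif copies) at
  the planned ends, motif forward on the left end and reverse-complement
  on the right. The real motif of the organism is not modelled; the
  default `TTAGGG` is a configuration choice, and scenario files must set
  the motif explicitly when it matters.
- **Implanted elements** are exact constructions: the terminal repeat is
  literally copied (TDR) or reverse-complement-copied (TIR), the TSD is a
  literal duplication of the host bases left of the insertion point, and
  anchor peptides are embedded as exact single-ORF translations on the
  forward strand (a config flag places them on the reverse strand).
  Element length defaults to 20.29 kb at 35% GC with a 488-bp TIR and
  5-bp TSD — the median profile of the endogenous PLV complement this
  package was built to detect. Real elements accumulate substitutions
  after integration; mismatch tolerance is therefore exercised with
  explicitly mutated constructions in the tests rather than by the
  generator defaults.
- **Read alignments** are perfect-identity placements, uniform over
  positions whose full read interval avoids the excluded intervals. No
  sequencing error, quality strings, or FASTQ (out of scope). Coverage
  statistics and island detection only consume intervals, so this is the
  minimal faithful model; mapping ambiguity and edge effects of real
  aligners are not represented.
- **Survey tables** draw HNF densities log-normal (σ = 0.5 on the log
  scale) around a configurable mean (default 1500 cells/ml) and the
  lineage fraction Beta(1.02, 5.17), whose mean 0.165 matches the
  surveyed average relative abundance of ~16.5% of HNF. Covariates are
  independent normals unless a coupling coefficient is given (Gaussian
  copula-style mixing on the percentage z-score).
- **Growth curves** follow lag → exponential → instantaneous collapse:
  N(t) = N₀ for t < lag, N₀·exp(μ(t−lag)) after, multiplied by
  (1−collapse_frac) from t_collapse on, with mean-corrected multiplicative
  log-normal noise of coefficient of variation `cv` (default 0.1, typical
  of microscopy counts). Defaults mirror the isolation experiment:
  inoculum 200 cells/ml, ~1-week lag, doubling ≈ 29 h, collapse of ~80%.
  Because growth continues between samples, the *observed* per-sample drop
  at a collapse is 1 − (1−collapse_frac)·e^{μΔt}, smaller than
  collapse_frac — tests account for this.

Passing tests on these data show the detectors recover exactly-planted
signal under calibrated noise; they do not certify performance on real
assemblies with degraded repeats, nested insertions, or compositional
drift.

### Stand-ins for published summary tables

The per-sample survey table and per-element tables behind the published
cohort summaries are not redistributable here. Two stand-ins, clearly
labelled synthetic, carry exactly the published marginals and nothing
else:

- `synthetic_pct_from_marginals` builds a 263-value percentage vector
  with the published mean (16.47), lower median (12.08), n−1 SD (15.95),
  range (0–96.5) and strict category counts (154 samples > 10%, 39 < 1%).
  The construction fixes the category blocks and solves a one-parameter
  power-family for the free upper block by root-finding on the sum of
  squares; it is deterministic and exact to ~1e-10.
- `SYNTHETIC_PLV_SPECS` lists 13 element descriptors whose length median
  (20.29 kb), TIR median (488 bp, n = 11) and TDR median (266 bp, n = 2)
  equal the published cohort medians, with the TDR elements carrying YREC
  and no TSD, TIR elements rve-INT with 5–6 bp TSDs.

Recomputing the published summaries from these stand-ins verifies the
summary operations at the published operating point; it carries no
information about the underlying raw data beyond those marginals.

## EVE scanning

**GC track.** Window 1000 bp, step 200 bp (defaults; both config). Windows
with > 50% N yield a missing value and can never seed a candidate.

**Segmentation.** Candidate = maximal run of windows with GC ≤ baseline −
δ/100, merged across gaps of ≤ 1 window, length-filtered to [5, 60] kb
(brackets the 14–40 kb range of known elements with margin). δ defaults to
8 pp — roughly half the host−element contrast (~17 pp), leaving headroom
for composition noise in 1-kb windows (binomial SD ≈ 1.6 pp).

**Baseline.** Genome-wide GC is biased downward by the elements
themselves, so the baseline is re-estimated once with first-round
candidate intervals masked. One iteration suffices because elements are a
small genome fraction; further iterations change the threshold by far
less than the window noise.

**Terminal repeats.** The first and last `search_margin` bp are compared
in direct (TDR) and reverse-complement (TIR) orientation by exact 12-mer
seeding followed by per-diagonal extension: on each seeded diagonal a
sliding window keeps the mismatch count ≤ max_mismatch_frac × window
length, and the longest valid window wins. At max_mismatch_frac = 0 this
is exact (verified against a longest-common-substring dynamic program);
at > 0 the window search is greedy and may over-extend a repeat by
~f/(0.75−f) × repeat length junk bases at the flanks (≈ ±35 bp at the
default f = 0.05), which is why boundary assertions use a ±50 bp
tolerance. Ties prefer TIR over TDR at exact equal length. Within
`call_eves` the margin is widened by the segmentation slop (pad + window)
so a repeat near the true boundary is never truncated by the search
window. `search_margin` defaults to 2 kb; giant-virus-scale TIRs (~100 kb)
need the 150 kb setting.

**TSD.** Exact matching only, longest k ∈ [4, 8], comparing the k-mer
ending the left flank with the k-mer starting the right flank. No
mismatch license: the biological signal is a literal duplication, and at
flank length 20 the exact-match false-positive rate is already ~20·4⁻⁴
per element.

**Classification.** TDR+YREC and TIR+rve-INT are the two attested
configurations; everything else is `unclassified` rather than guessed. A
TSD co-occurring with TDR+YREC is flagged with a warning, since
recombinase-mediated integration through a circular intermediate should
not duplicate target sites.

**Summaries** use the lower median (even n) so reported medians are
always attained values.

## Telomeres and assembly statistics

An end is called when a tandem run of ≥ min_copies motif copies (either
orientation) starts within max_offset of the terminus; run counting
tolerates 1 mismatched base per 3 copies, and a copy with ≥ 2 mismatches
terminates the run. Defaults (min_copies 6, max_offset 100 bp)
operationalise a "high-quality" telomere; a looser recognizable-telomere
setting (4 copies within 1 kb) is a config choice. These thresholds are
declared operational definitions, not published criteria.

`min_chromosomes(n_both, n_one) = n_both + ceil(n_one/2)` assumes every
chromosome has two telomeres and one-telomere contigs pair optimally —
hence a lower bound.

N50 uses the standard descending-sort definition (length at which the
running sum first reaches half the total); GC excludes N from the
denominator. Values are reported in bp; rounding only at the CLI layer.

## Recruitment, islands, ANI

Covered fraction is computed at 1-bp resolution (depth ≥ 1); presence is
strict (> 0.5), and RPKM is zeroed for absent genomes so conserved-region
pile-ups cannot masquerade as abundance. Islands: bins (default 100 bp)
with depth ≤ 0, merged across single-bin interruptions, ≥ 5 kb. All three
island knobs are config; they were chosen so a ~27-kb island is found
robustly at the few-× coverages typical of viral genomes in freshwater
metagenomes while single uncovered bins are ignored.

ANI follows the fragment convention (1020 bp, ≥ 70% identity). Fragments
are aligned with edlib in infix mode (whole fragment vs best subject
locus, both strands), so alignment coverage of a full-length fragment is
1 by construction and the coverage filter is active only through the
identity filter. Identity = 1 − edit_distance/fragment_len slightly
underestimates percent identity under indel-rich divergence; under pure
substitution (the calibration case) it is exact in expectation. A trailing
partial fragment is dropped. With no qualifying fragment the ANI is
undefined (None), not an exception.

## Survey statistics

SD is the n−1 sample standard deviation; category counts use strict
inequalities. Samples without HNF counts are excluded and counted, never
imputed. The correlation screen computes Pearson and Spearman on
pairwise-complete observations and flags when either exceeds the
threshold in absolute value — a conservative treatment because the
published screen does not name its coefficient. Constant covariates give
undefined coefficients with a warning rather than an error. No
multiple-testing correction is applied: the screen mirrors a threshold
scan, not a hypothesis-test battery.

In-situ doubling considers consecutive increasing pairs only; it is a
descriptive minimum, biased low when abundances fluctuate by counting
noise (a caveat for sparse time series).

## Growth kinetics

The exponential window is selected among all contiguous windows with ≥ 4
strictly positive counts, positive ln-slope, and observed fold-change
(last/first) ≥ 2: the longest window with R² ≥ 0.99 wins (ties: higher R²,
then earlier start), falling back to the max-R² window when none reaches
the threshold. This rule was chosen after simulating alternatives at the
study conditions (cv = 0.1, doubling 29 h, 12–22 samples at 12–24 h
spacing, with and without lag and collapse): bare max-R² selection picks
short windows whose high R² is a noise fluke (~30% of seeds miss a ±10%
doubling-time band), and linear length-weighted scores (R²·(n−1)) swallow
the collapse step; the longest-linear-window rule recovered the doubling
time within ±10% in ≥ 93/100 seeds in every setting with |bias| ≤ 3.3%.
Fitting is by OLS on natural logs; doubling = ln 2 / μ, displayed to one
decimal. Zero counts are retained for collapse detection but exclude any
fitting window containing them.

Collapse events fire when a count falls ≥ drop_frac (default 0.5,
inclusive) below the running maximum within ≤ horizon (default 2)
sampling intervals; the drop is reported against the running maximum, so
events never precede their reference and a slow decline never fires.

## Problem sizes in the shipped tests

The test and acceptance suites run on desk-scale data chosen to exercise
every code path with comfortable statistical margins: 200-case oracle
suites for the repeat/TSD finders (sequences ≤ 5 kb), ten 440-kb genomes
with 3–8 implants for recall/precision, a 100-kb pair for ANI
calibration, a 5-Mb four-contig scenario with a 671-kb recruitment
reference for the end-to-end chain, and a 188-contig assembly for the
chromosome-accounting recomputation. All sizes are configuration, not
limits; the same code paths take full-scale inputs.

## Known limitations

- Repeat boundary refinement is ungapped; indel-containing terminal
  repeats will be reported shorter than their true extent.
- The GC segmentation assumes a roughly homogeneous host background; in
  genomes with strong isochore structure the single global baseline will
  over- or under-call regionally.
- Anchor peptide scanning is exact-match; degenerate motifs belong in the
  GFF3 route (e.g. HMM hits produced upstream).
- `detect_islands` at max_depth 0 treats a single spanning read as
  coverage; low-complexity mapping artefacts in real data may mask true
  islands.
- The survey correlation screen is descriptive; it makes no claims about
  significance.
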