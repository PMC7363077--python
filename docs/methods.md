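# Methods

This note documents the models, estimators and numerical choices behind
`mtduplex`, what the synthetic-data generator does and does not emulate,
and the known limitations of each component.

## Duplex consensus model

A duplex library tags each double-stranded template with two random
12-nt barcodes (one per adapter end) separated from the insert by an
invariant 5-nt spacer. Reads descending from one template strand share
an oriented tag pair (mate-1 tag followed by mate-2 tag); the opposite
strand carries the same tags in swapped order. Consensus proceeds in
three gates:

* **Tag correction.** Observed tag pairs are visited in decreasing count
  order (ties broken lexicographically); a pair within Hamming distance
  3 of an already-accepted, at-least-as-frequent pair merges into it
  (largest family wins, ties lexicographic). The candidate search
  partitions the 24-nt key into four 6-nt blocks: any pair within 3
  mismatches of an accepted key shares at least one exact block
  (pigeonhole), so correction is exact yet near linear-time for random
  tags.
* **SSCS.** Families need ≥ 3 reads of equal length; per position, a
  base is called iff its count/size is ≥ 0.70 (inclusive, "at least
  70%"), else N. Base qualities are carried but not used in voting; the
  quality filter belongs to variant calling.
* **DCS.** A family keyed αβ pairs with the family keyed βα. The
  opposite family's mate 2 reads the same fragment end, on the same
  physical strand and in the same orientation, as this family's mate 1,
  so the duplex agreement compares mate 1 with the partner's mate 2
  positionwise; disagreement or N yields N. Lone SSCSs produce no DCS
  (kept for SSCS-level analyses). The first 12 nt of each consensus
  mate are trimmed (end-repair artifact zone).

With per-read error rate `e` and independent strands, a DCS miscall
requires concordant consensus errors on both strands, so the miscall
rate is far below `e²`; the suite asserts `< 10·e²` on simulation.

## Variant calling

Consensus mates are placed on the circular reference (from the
simulator's alignment sidecar, or from SAM via pysam with the
mapping-quality > 20, proper-pair and base-quality ≥ 20 filters).
Mate-overlap intervals are clipped so a template contributes one
observation per site — essential when most mutations are
single-molecule. Pileup treats the genome as circular, which makes the
two-pass relinearized-reference workaround of linear mappers
unnecessary; `select_window` reproduces the window-union behaviour for
externally mapped data. Every non-reference, non-N base with ≥ 1 DCS
becomes a call: duplex consensus has already done the error
suppression, and downstream classification handles biological
filtering. Minor-allele frequencies switch to SSCS counts when the DCS
minor-allele depth is < 5 molecules (SSCS depth is ≥ 2× DCS depth, so
low-count DCS frequencies are the less reliable of the two).

## Classification

A call is `inherited` when its site+allele is present in both a somatic
and a germline tissue of one individual or in two generations of a
pedigree (the site-level label applies to all carriers);
`early_somatic` when present in both somatic tissues but absent from
the individual's assayed oocytes (single oocytes and pools count
equally as germline); otherwise a tissue-specific de novo candidate.
Candidates recurring in more than 3 samples dataset-wide (both
pedigrees jointly, keyed on site+allele — distinct alternate alleles
are independent events) are excluded as hot spots or low-frequency
segregating variants, the two being indistinguishable. A>T/T>A
candidates in enzymatically fragmented libraries are excluded as
chemistry artifacts (at the cost of some true transversions, a
documented trade-off); a user exclusion list substitutes for
sequence-similarity screens against nuclear mitochondrial paralogs.
Multi-molecule observations collapse to one mutation event per sample
(assumed single mutational origin), with molecule support retained.

## Frequencies and tests

Mutation frequency is events per sequenced nucleotide: `n / (L · d̄)`
for a region of length `L` at mean DCS depth `d̄`; aggregation always
sums numerators and denominators. Type-resolved frequencies use
type-capable denominators (sequenced reference-strand X bases for
X>Y), which also underlie strand-bias comparisons of reciprocal type
pairs. Intervals on counts are exact Poisson (Garwood, via chi-squared
quantiles). Group comparisons: Fisher's exact test (two-sided) on
aggregated counts; one-sided permutation tests on per-sample medians
(exhaustive when the number of label arrangements fits the permutation
budget, else Monte-Carlo with the add-one estimator, which cannot
return 0). Spectrum independence uses Pearson's chi-squared with
Monte-Carlo tables drawn at fixed margins. FDR control is
Benjamini–Yekutieli by default with plain Benjamini–Hochberg
selectable; report tables label the method used.

## Selection (hN/hS)

Nei–Gojobori fractional site counts under the vertebrate mitochondrial
code (translation table 2): each non-stop codon contributes 3 sites
split by the fraction of its nine possible substitutions that preserve
the amino acid. `hN/hS` is nonsynonymous events per nonsynonymous site
over synonymous events per synonymous site; stop gains/losses and start
losses count as nonsynonymous; `hS = 0` yields an undefined ratio,
reported as such. The neutrality test bootstraps (default 100
replicates) the null by re-placing the observed number of mutations on
coding positions with probability proportional to the observed 12-type
spectrum times each type's base opportunity, and uses the add-one
two-sided empirical p-value.

An important subtlety the implementation makes explicit: the classical
"neutral ratio = 1" expectation holds only when every substitution is
equally likely. Under a transition-biased spectrum the neutral
expectation drops well below 1 (~0.64 for the packaged genome at
Ti/Tv = 3), because transitions preferentially create synonymous
third-position changes — this is precisely why the significance test
resamples from the observed spectrum instead of comparing the ratio to
1. Calibration tests therefore check mean ratio → 1 under a uniform
spectrum and a ~5% rejection rate under the biased spectrum.

## Heteroplasmy drift and the germline bottleneck

For each individual `i` and heteroplasmic site `j`, with `p_ij` the
mean allele frequency across the two somatic tissues and `p_ijk` the
frequencies in the `n_ij` offspring units (single oocytes, or pups of a
mother),

    sigma²_ij = (1/n_ij) Σ_k (p_ijk − p_ij)²,
    N_ij      = p_ij (1 − p_ij) / sigma²_ij,

and the effective bottleneck estimate is the arithmetic mean of the
`N_ij` (entries with boundary `p_ij` or zero variance are excluded and
counted — the estimator is undefined there). Confidence intervals are
percentile bootstrap over the `N_ij` (default 1,000 resamples).

Because `1/sigma²` is convex, this estimator is biased upward by
approximately `n/(n−2)` (≈ 1.5× at 6 offspring; verified by
simulation, where it also drives bootstrap coverage to ~0 at 200
sites). The uncorrected form is the package default, for comparability
with the published formulation; `small_sample_correction=True`
multiplies each `N_ij` by `(n_ij − 2)/n_ij`, which makes the estimator
approximately unbiased (median within a few percent of truth at
N ∈ {10, 50, 200}) with ~91–92% bootstrap coverage. Entries with
`n_ij ≤ 2` are uninformative for the corrected form and are excluded.

Two further caveats. First, measured allele frequencies carry
read-sampling variance `p(1−p)/depth` on top of drift variance
`p(1−p)/N`; when sequencing depth is comparable to or below `N` (as in
scaled-down demo runs, or single oocytes at ~133×), `sigma²`
is dominated by measurement noise and the estimator reports an
effective size closer to the harmonic combination of depth and
bottleneck. Quantitative bottleneck work should feed the estimator
deep-sequencing frequencies or true (transmission-level) frequencies.
Second, the same effect attenuates MAF correlations between tissues at
low depth. Both are properties of the method applied to shallow data,
not of the implementation.

Normalized variance `Var(p̂)/p(1−p)` uses the population (divide-by-n)
variance around the group mean and has expectation `1/N` under a
binomial bottleneck; age-group comparisons use one-sided permutation
tests on medians.

## Joint mixed-effects model

Cells are mutation counts `k` out of `w` type-capable sequenced
nucleotides per individual × tissue × compartment (D-loop vs outside) ×
mutation class (transversions, A>G/T>C, C>T/G>A); single oocytes are
combined per individual; cells under 200,000 nt are dropped (low-depth
guard; scaled-down runs shrink the cutoff by the same factor as the
rate scaling, preserving the counts-per-cell operating point). The
model is binomial-logit with treatment-coded fixed effects (baselines:
mother, brain, D-loop, transversion) and a Gaussian random intercept
per individual, fitted by maximising the exact marginal likelihood with
adaptive Gauss–Hermite quadrature (15 nodes; per-individual posterior
modes by Newton, Laplace scaling; BFGS over coefficients and
log-sigma; relative-tolerance 1e-6). The σ = 0 boundary of the same
code is an ordinary weighted logistic regression and agrees with a GLM
fit to ~1e-7 — the independent oracle used in tests. Wald standard
errors come from the numerical observed information; per-variable
likelihood-ratio tests refit with the variable (and, in the interaction
model, its interactions) removed; the random-effect LRT against the
fixed-only fit uses the naive 1-df chi-squared reference, conservative
at the variance boundary.

Variance explained follows the latent-scale pseudo-R² for logit
models: marginal `var(Xβ)/(var(Xβ) + σ² + π²/3)`, conditional adds
`σ²` to the numerator (distribution-specific variance fixed at π²/3),
and the partial pseudo-R² of a variable is
`((1 − R²_red) − (1 − R²_full)) / (1 − R²_red)` on marginal values.

## Synthetic-data generator

Defaults are the emulated study's conditions: two 2-generation
pedigrees (4 + 4 sister mothers, 11 + 17 pups, 19 female/9 male);
brain and muscle for every animal; 4 single oocytes plus an oocyte pool
(4–47 oocytes) per mother and 3 + pool per female pup; median DCS
depths 2,050× (brain), 1,986× (muscle), 133× (single oocytes), 932×
(pools); 28 inherited heteroplasmies in three sharing categories
(17 pup-only at founder MAF 0.3–3%, 7 mother-and-pups at 0.5–10%,
4 several-mothers at 3–30%, log-uniform) transmitted by one binomial
draw per generation with bottleneck 85 segregating units (optional
extra turnover rounds for mothers' oocytes, off by default); de novo
rates per tissue and age set to the study-scale medians
(1.2×10⁻⁶/bp mothers' brain … 2.4×10⁻⁷/bp pups' pools), placed with a
3× D-loop weight and a transition-biased spectrum (Ti/Tv = 3, G>A and
T>C excess); events occupy 1 molecule with probability 0.92, else 2–3;
250-nt paired reads, 12-nt tags, 5-nt spacer, fragment ~400 ± 60 bp,
per-strand family size 3 + Poisson(5) (mean 8), flat per-base error
10⁻³; enzymatically fragmented libraries (80% of single oocytes)
receive template-level A>T/T>A artifacts at 2×10⁻⁷/bp so they survive
duplex consensus, as the chemistry artifact does. One seed drives
everything through per-sample substreams, so any sample can be
regenerated independently and byte-identically.

What the generator does **not** emulate: indels and structural
variants, nuclear mitochondrial paralog reads, quality-score structure
(flat Q40), GC or position-dependent coverage bias, PCR duplicate
family-size correlations, and heteroplasmy selection. Passing
recovery tests therefore demonstrate the correctness of the
computational chain under the stated error model, not robustness to
every artifact class of real libraries — the artifact-facing filters
(recurrence, fragmentation chemistry, exclusion lists) are exercised
through their own planted signals.

**Problem sizes.** Pipeline-level tests and the acceptance script run
the full 36-animal design at reduced depths (40×/40×/20×/120×) with de
novo and artifact rates scaled up by the common factor 60, which
preserves expected mutation counts per sample and every estimand built
from count ratios (fold changes, enrichment ratios, spectra), while
keeping a laptop-scale run in minutes. Transmission-level analyses
(bottleneck recovery) use 200 sites × 6 offspring per replicate.
These sizes are the package's own validation choices.

## Numerical details and edge cases

* Coordinates are 1-based inclusive; all positional queries wrap
  circularly. Compartment labels resolve overlap by precedence
  D-loop > protein-coding > tRNA > rRNA > noncoding, so position
  totals partition the genome exactly.
* Insertion edits are keyed to the position they follow (the "9821.2"
  naming convention maps to an insertion after 9,821); features
  spanning the insertion stretch, downstream features shift.
* Consensus threshold comparisons are inclusive (≥ 0.70); the DCS
  minor-depth fallback is strict (< 5).
* Tag-pair palindromes (αβ = βα) cannot resolve strands and yield no
  DCS; mixed-length families are rejected rather than padded.
* Empty groups, boundary frequencies, undefined ratios (hS = 0,
  σ² = 0) raise or report as undefined — never silently coerced to a
  number.
* Monte-Carlo p-values use the add-one estimator; exhaustive
  enumerations return exact tail fractions.
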