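# Methods

This note documents the models, numerical choices and limitations behind
`wgdkit`, in the order the pipeline runs them.

## Genome-evolution simulator (`wgdkit.simulate`)

**Model.** An ancestral genome of `n_chromosomes × genes_per_chromosome`
genes evolves down a rooted species tree with branch lengths in Myr.  Each
branch applies (i) any WGD events placed on it and (ii) neutral sequence
divergence scaled by the branch's rate multiplier.  The true Ks peak of an
event of age T seen from a leaf is `2 × (rate-weighted path from the event
to the leaf) × ks_per_myr`; the factor 2 counts both descending copies'
paths.  A WGD sits at a chosen fraction `time_frac` along its branch
(default 0: the rootward end).

**Sequence model.** Ancestral CDS are an ATG start plus random codons from
the Ala/Thr/Pro/Ser families (`NCN`, second position fixed to C).  Every
such codon has one fully fourfold-degenerate site (the third position) and
two strictly nonsynonymous sites, so:

- synonymous evolution is an exact Jukes–Cantor process on third positions
  (flip probability `(3/4)(1 − e^{−4ks/3})`, uniform over the three
  alternatives) — per-branch draws compose exactly along any path, and the
  Nei–Gojobori estimator is consistent for the summed path length;
- no stop codon can ever arise, and codon differences are always
  single-nucleotide, so path enumeration in the estimator is exercised by
  dedicated random-codon tests rather than by simulator output.

This idealisation is deliberate: real codon usage mixes two- and fourfold
degenerate sites, for which the estimator is only approximately
self-consistent under multi-branch evolution.  Passing recovery tests on
simulated data therefore demonstrates correctness of the estimator and the
downstream machinery, not robustness to codon-usage effects.  A residual
convexity (Jensen) bias of order `σ²·f″/2` affects the *mean of per-gene*
JC-corrected estimates at high divergence (~+0.01 at Ks = 1 with 300-codon
genes); pooled estimates (sum counts, then correct) are unbiased, and tests
use the pooled form where 3-SE accuracy is asserted.

**Gene loss.** Each WGD copies every chromosome `multiplicity−1` extra
times (copy-sets labelled a, b, c…), then each copy-set loses a budget of
`round(loss_prob × genes)` genes: a uniformly random retained gene starts a
deletion of L consecutive retained genes with `L ~ geometric(run_p)`,
repeated until the budget is met (the final run is trimmed; runs also
truncate at chromosome ends, a negligible distortion for realistic
parameters).  The truth ledger records both the drawn run lengths (i.i.d.
geometric, used in goodness-of-fit checks) and every gene's fate.  Observed
maximal absence runs along the reference order merge adjacent draws and
interior older losses, so observed spectra are longer-tailed than
geometric(run_p) — the same "deviation grows with run length" behaviour
expected of real fractionation data.  Translocations, inversions and tandem
duplications are not simulated: statistics that conflate loss with
translocation are exercised in the loss-only regime where their accounting
is exact.

**Defaults.** `run_p = 0.6` (mean run 1.67 genes, matching the
"small runs of one or two genes" regime), `ks_per_myr = 0.004` (a typical
angiosperm synonymous clock of ~4×10⁻⁹ substitutions/site/year), loss
probabilities per scenario.  Hit tables are emitted from the truth ledger in
BLAST outfmt6 form (the pipeline consumes external BLAST output for real
data; running BLAST is out of scope).

## Collinearity (`wgdkit.collinearity`)

Hits are filtered (E < 1e-5, self-hits dropped, best-N per query by bit
score) and chained per chromosome pair and orientation.  A chain requires
strictly increasing ordinals on both chromosomes (decreasing on B for `−`
orientation) and at most `max_gap = 50` intervening genes on each side per
step.  The objective is maximal anchor count, ties broken by minimal total
gap, then by lexicographically smallest anchor sequence; the best chain is
extracted, its anchors removed, and the search repeats until no chain of
`min_anchors = 4` remains.  The DP is windowed on the sorted first ordinal
(O(n · max_gap)), and is verified against an exhaustive chain-enumeration
oracle on small instances.  Within-genome comparisons keep one triangle of
same-chromosome hits and mask the identity diagonal (|Δordinal| ≤ max_gap),
and keep one canonical chromosome ordering for cross-chromosome hits.
Block significance modelling is deliberately not implemented; the anchor
count filter is the criterion.  Transposition symmetry holds up to
tie-breaking (the lexicographic rule is direction-dependent).

## Ka/Ks (`wgdkit.kaks`)

Nei–Gojobori (1986), unweighted-pathway variant.  Site counts per codon:
each position contributes `syn/3` synonymous sites where `syn` is the
number of the three single-nucleotide changes that preserve the amino acid;
mutations to stop codons count as nonsynonymous, so every codon contributes
exactly 3 sites.  Codon differences at 2–3 positions are averaged over all
orderings with equal weights; path steps into or out of a stop codon count
as nonsynonymous (configurable conventions elsewhere differ — Biopython,
used as an independent cross-check in tests, scores a stop→stop step as
synonymous, so the cross-check is restricted to stop-free paths).
Proportions are Jukes–Cantor corrected; `ps ≥ 3/4` yields a `SATURATED`
marker rather than an exception.  All 64×64 pair counts are precomputed, so
per-pair estimation is a vectorised lookup.  Codon alignment is
protein-guided (BLOSUM62, gap open 10, extend 0.5) only when sequence
lengths differ; equal-length pairs use the identity alignment.  Gap columns
and stop-containing columns are excluded and counted.

## Peaks and dating (`wgdkit.dating`)

Mixture fitting restricts the sample to Ks ∈ (0.02, 2.0] (allelic noise and
saturation excluded), finds kernel-density modes (Silverman bandwidth) as
initial means, and runs EM (`sklearn` GaussianMixture, tol 1e-6, ≤ 500
iterations, seeded) with BIC selection over k = 1..5 when `k="auto"`.  The
"±" spread reported with a peak is the component σ.

Rate correction is multiplicative: given one shared (same-age) benchmark
event observed at peaks μ_i per lineage, `λ_i = μ_ref/μ_i` with
`λ_ref = 1`; within-genome Ks are rescaled by λ_i, cross-genome Ks by
`(λ_i + λ_j)/2` (each lineage contributed half the divergence path).  This
is the package's own model of the correction: it reproduces the arithmetic
of the headline corrected values but is not claimed identical to any other
published correction procedure.  Dating is linear against a single
calibrated event, `t = Ks′/κ_cal × [T_lo, T_hi]`, bounds rounded to integer
Myr (printed ages are integers).  Bayesian dating and multi-calibration
models are out of scope.

## Depth, subgenomes and the alignment table (`wgdkit.depth_align`)

Depth per reference gene = number of blocks (≥ min anchors) whose
reference-side span covers its ordinal.  The summary ratio is the pair of
modal depths over genes with depth ≥ 1 (zeros would bias ratios under heavy
fractionation) and is reported unreduced — 2:4 is informative precisely
because it is not 1:2.  Subgenome assignment partitions the query fragments
covering each reference chromosome into the event's multiplicity groups by
greedy interval partitioning (first non-overlapping group in reference
order), ranks groups by retained anchors (dominant → sensitive, ties
arbitrary and flagged), and warns when > 5% of covered reference genes
exceed the expected depth.  Group labels are positional per reference
chromosome: pairwise collinearity cannot phase subgenome identity across
chromosomes, so column k need not be the same parental genome on different
chromosomes — statistics that pool columns (absence totals, pooled run
spectra, per-chromosome retention) are invariant to this.  The alignment
table holds one row per reference gene in order; blocks fill cells
best-first, and a query gene landing in two columns on one reference
chromosome raises an integrity error.  The absence mark `.` does not
distinguish loss from translocation or assembly gaps.

## Fractionation and the P-index (`wgdkit.fractionation`)

Loss runs are maximal absence runs per reference chromosome.  The geometric
fit uses the closed-form MLE `p̂ = n_runs / total lost` (support starts at
L = 1) with a chi-square goodness of fit, tail-pooled to ≥ 5 expected per
cell, dof = cells − 2.  Retention windows are 100 genes sliding by 1 within
each chromosome (shorter chromosomes are skipped with a warning).  The
window difference test combines the absolute rule (|A−B| < 0.05) with a
two-proportion chi-square test at α = 0.05, reporting the fraction of
windows showing no significant difference under either.

P-index: `d_i = |A_i−B_i|/(0.5(A_i+B_i))` (0 when both rates are 0),
inclusion `δ_i = 1` iff `0.1 < d_i < 3`, per-chromosome contribution
`|Σ sign(A_i−B_i)·δ_i| / Σ δ_i` (0 when no window is included), chromosome
weights `W_C = N_C/ΣN_c`.  The denominator is read as the count of included
windows — the only reading that bounds every contribution in [−1, 1] and
hence the P-index in [0, 1]; windows with A_i = B_i are always excluded, so
the sign is always defined.  Note `d_i ≤ 2` by construction, so the upper
cutoff 3 can never bind; it is kept as stated.  The allopolyploidy call
threshold is 0.3.

A practical observation, built into the test scenarios: with 100-gene
windows, a chromosome of L genes has roughly L/100 independent retention
regions, and a balanced (autopolyploid-like) P-index concentrates around
`sqrt(2/(π·L/100))` per chromosome.  The 0.3 threshold therefore behaves as
published only at real genome scale; separation simulations use 8
chromosomes × 3500 genes (a basal-eudicot-like genome), where balanced runs
land at ~0.10–0.23 and biased runs (loss 0.2 vs 0.5) at ~1.0.

## Gene-tree support (`wgdkit.phylosupport`)

Orthogroups are rows of the alignment table matching per-genome minimum
copy counts.  Topology classification works on bipartitions (invariant to
tip order, branch lengths and rooting): a split isolating the paralog pair
from all other genomes supports a lineage-specific WGD; minimal splits
grouping each paralog with a different ortholog copy of the sharing genome
support a shared WGD; the key support is the bootstrap of the defining
split (the weaker of the two for shared calls), and calls below the 50%
threshold are unresolved.  The bundled tree builder is neighbor-joining
(scikit-bio) on Jukes–Cantor distances with column-resampling bootstrap —
a deliberately lightweight stand-in so simulations run end to end;
externally inferred maximum-likelihood trees are the intended input for
real analyses.  Only the generic shared/specific patterns are classified;
finer topology catalogues (donor-lineage patterns etc.) are configurable
ground the package does not guess.

## Problem sizes and determinism

Test and acceptance simulations use genomes of 10²–10⁴ genes: large enough
that every stochastic assertion has its stated power (3-SE bands, 18/20
replicate criteria, the P-index scale effect above), small enough that the
whole suite runs in minutes.  All randomness flows from explicit seeds
(`numpy.random.default_rng`); reruns with the same configuration are
bit-identical except for EM fits on degenerate samples, which are seeded
too.  Known limitations: no rearrangements or tandem arrays in the
simulator, no block-significance statistics, a single-calibration linear
clock, and subgenome phasing only within reference chromosomes.
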