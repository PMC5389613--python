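# Methods

`bulkpop` implements the analysis chain used in population-bulk SSR
surveys of crop landraces: pooled DNA from N plants (default N = 15) is
genotyped at multi-allelic microsatellite loci, allele frequencies are read
off relative peak intensities, and all downstream population-genetic
machinery — diversity statistics, shared-allele distances, trees,
ordination, and Bayesian admixture clustering — runs on those
population-level frequency profiles or on simulated pseudo-individuals
derived from them. This note records the models, the defaults and why they
are set where they are, the numerical conventions, and what the synthetic
test bed does and does not establish.

## Peak calling (pooled allele-frequency estimation)

A fragment-analysis export is modeled as records (bulk, locus, size in bp,
height, optional quality). Processing per (bulk, locus):

1. **Binning.** True alleles sit on the ladder `size_min + k·repeat_unit`.
   Observed sizes are snapped to the nearest rung; equidistant observations
   go to the *lower* rung (deterministic, documented tie-break). Peaks
   farther than `bin_tolerance` (default half a repeat unit) from every
   rung are dropped; peaks binned to one rung have their heights summed.
2. **Stutter removal.** Scanning rungs from largest to smallest, the peak
   one repeat unit below a retained peak at `a` is deleted iff its height
   is below `stutter_ratio × height(a)`. The default ratio 0.2 is standard
   fragment-analysis practice; −2-repeat stutter removal exists behind a
   flag but is off, since −1 slippage dominates for short motifs. The
   operation is idempotent and retaining-set monotone in the ratio.
3. **Noise floor.** Remaining peaks below `noise_floor` (default 0.05) of
   the tallest retained peak are deleted. This is the main source of
   systematic error for genuinely rare alleles in a pool: an allele carried
   by one plant in 15 (frequency 1/30 ≈ 0.033) is lost whenever a
   competing allele exceeds ~0.67. Lower the floor for small pools.
4. **Normalization.** Frequencies are retained heights over their sum.
   Preferential amplification is treated as false-peak deletion only; an
   optional linear re-weighting of height with fragment size
   (`size_reweight`, default 0 — off) is provided for users who want a
   first-order correction of short-fragment bias.

Empty results mark the (bulk, locus) cell missing; missingness is carried
as absence, never as zero frequencies, because zero is a legitimate
observed frequency.

## Pseudo-individual simulation

Genotype-based software needs individuals, so each population's frequency
profile is expanded into N diploids per locus:

* **Apportionment.** 2N allele copies are assigned by the
  largest-remainder (Hamilton) rule: floor of the quota `2N·p_a` for every
  allele, leftovers to the largest fractional remainders, ties broken by
  larger quota then smaller allele size. Every count is within one copy of
  its quota, so round-trip frequency error is at most 1/(2N) per allele.
* **Pairing with heterozygosity repair.** Copies are shuffled (seeded) and
  paired. If realized heterozygosity deviates from the Hardy-Weinberg
  expectation `1 − Σ p̂²` (computed from the apportioned counts, for
  internal consistency) by more than `het_tolerance` (default 0.05),
  single-allele exchanges between genotypes raise or lower the heterozygote
  count one unit at a time until within tolerance or `max_repair_iters`.
  Swaps conserve allele counts exactly; an unreachable target (a parity
  constraint can forbid some heterozygote counts) returns the best
  achieved with a warning. Repair is preferred over rejection sampling
  because it terminates and never perturbs the frequencies.
* Loci are simulated independently and heterozygosity is enforced per
  locus. No inbreeding or linkage model is included.

## Diversity statistics

Gene diversity (expected heterozygosity) is Nei's `H = 1 − Σ p²` per
locus. Group summaries average allele frequencies *unweighted* across the
group's member populations (pairwise-deleting missing loci) before
computing `H` and counting alleles; a pooled-copy route from genotype
tables is available via `frequencies_from_genotypes`. Unique alleles are
those with positive pooled frequency in exactly one group of the
comparison set; sub-group comparisons restrict the set to siblings under
one parent cluster. Presence means strictly `> 0` — no minimum-frequency
filter.

## Distances, trees, ordination

* **PSA distance.** `d(i,j) = 1 − (1/L') Σ_l Σ_a min(p_i, p_j)` over the
  `L'` loci both populations were scored at (pairwise deletion, no
  imputation). A bounded semimetric on [0, 1].
* **Neighbor joining.** Saitou-Nei agglomeration with the Q-criterion
  `(n−2)d(i,j) − r_i − r_j`; ties break toward the lexicographically
  smallest pair of node labels (internal nodes are labeled by their
  smallest descendant leaf), making output deterministic. Negative branch
  lengths are clamped to zero with the deficit moved to the sibling branch,
  preserving the joined pair's path length. On additive inputs the tree's
  path-length matrix reproduces the input to 1e-9.
* **PCoA.** Gower double-centering of squared dissimilarities,
  `B = −½ J D∘D J`, symmetric eigendecomposition, coordinates scaled by
  √eigenvalue. Negative eigenvalues (non-Euclidean input) are reported and
  excluded; variance explained is over the positive spectrum. No Cailliez
  correction; a Lingoes correction is available by flag and suggested in a
  log message when the negative mass exceeds 5% of the positive trace.
  Raw distances are squared inside the centering — no further transform.

## Admixture model

The clustering engine is a Gibbs sampler for the standard admixture
model: K clusters with allele frequencies `P_k,l ~ Dirichlet(λ)`
(independent across clusters and loci — the correlated-frequencies prior
is deliberately not implemented), each allele copy's cluster origin
`Z_c ~ Categorical(q_i)`, and ancestry vectors `q_i ~ Dirichlet(α)` with a
single α shared by all sampling units, uniform prior on (0, α_max = 10],
updated by random-walk Metropolis with step 0.025. A full sweep updates
Z, P, Q, α in that order; the Z update is vectorized over all allele
copies, which is what makes desk-scale scans tractable (≈6 ms per sweep
for 900 individuals × 28 loci at K = 5 on one core).

Sampling units default to the simulated pseudo-individuals
(`unit="individual"`); a population's reported ancestry Q̄ is the mean of
its individuals' posterior-mean Q vectors. `unit="population"` treats each
bulk as one unit instead. Determinism holds for a fixed population order
and seed; permuting input populations is equivalent only in distribution,
not bit-for-bit, because all units share one RNG stream.

**Model selection.** Each run reports `LnP(D) = mean(log L) − var(log L)/2`
over post-burn-in sweeps. Replicate runs per K feed the Evanno table:
`L′(K)` and `|L″(K)|` are first/second differences of the mean across K,
and `ΔK = |L″(K)|/sd(K)`. ΔK is undefined at the K-range endpoints and
wherever the between-run sd is zero (flagged NaN, not infinity); the
argmax of the defined values is the suggested K, and all values are
reported so a user can override when several local maxima compete. That
override matters in practice: ΔK is known to favor the uppermost
hierarchical split of the data (often K = 2) even when a deeper K fits
better — on strongly structured three-cluster data the evidence curve
bends almost as sharply at K = 2 as at K = 3, and converged replicate runs
at K = 2 agree closely, inflating ΔK(2). Inspect the full table (and the
LnP(D) means) rather than trusting the argmax blindly.
Against the K = 1 closed form (Dirichlet-multinomial marginal), the
mean − var/2 estimator agrees to within ~10% on desk-scale data; the
residual is the estimator's Gaussian approximation of the log-likelihood
distribution, a known property of this estimator class.

**Assignment.** A population joins its largest ancestry component's group
iff that component exceeds the 51% cutoff, else it is "mixed"; assigned
populations at or below the 80% strong cutoff are flagged weakly assigned.
Row sums within 1 ± 0.02 are accepted (printed tables carry rounding) and
the raw maximum is reported.

**Sub-structure.** Each non-mixed top-level group with ≥ 2 populations is
re-analyzed independently: full K-scan, ΔK, consensus Q over label-aligned
runs (greedy column matching by Q-column dot products, without
replacement), assignment with labels namespaced `parent/kX`. Groups of
fewer than 2 populations are skipped with a warning.

**Run lengths.** Publication-grade settings for this model family are on
the order of 10⁶ replications after 5×10⁵ burn-in, five runs per K. The
package defaults are desk-scale (20 000/20 000, 3 runs) and the test suite
uses 600/600 sweeps; on strongly structured synthetic data (F ≈ 0.25) that
depth already gives stable LnP(D), ancestry error under 0.03 MAE, and a
clear evidence plateau at the planted K — though the ΔK *argmax* can still
sit at the K = 2 top split (see above), and deeper runs sharpen rather
than resolve that ambiguity. All run seeds derive deterministically from
one user seed.

## Synthetic data generator

The generator emulates the shape of the target surveys: K ancestral
clusters under the F-model (cluster frequencies
`~ Dirichlet(p_anc·(1−F)/F)`, F defaults to 0.2), populations with
Dirichlet(α = 0.2) ancestry, 15-individual bulks, 28 loci with 2–21
alleles each, and peak tables rendered as the inverse of the peak-calling
stage (lognormal height jitter σ = 0.05, stutter ratio U(0.05, 0.18),
occasional sub-floor noise peaks on unused rungs, all on an arbitrary 10⁴
intensity scale where only ratios matter). Ancestral simplexes are
symmetric Dirichlet(θ = 0.3) draws, chosen analytically so that
study-scale datasets show overall gene diversity near 0.62, the level
reported for Latin-American maize landrace SSR panels. Dirichlet sampling
goes through log-space gamma draws so that near-zero concentrations
(α → 10⁻³) produce correctly degenerate simplexes instead of underflowing.

**What the generator does not emulate.** Real surveys draw on far richer
substructure than a K-cluster F-model: the maize data this package is
shaped around resolves three main groups *and* ~16 sub-clusters, each a
partially independent reservoir of alleles. Under a plain K = 3 F-model,
low-frequency ancestral alleles are often lost from all three cluster
draws, so the union of detected alleles across 194 synthetic bulks
(~200–210 over 28 loci, ~7.5 per locus) undershoots the ancestral 2–21
range, and the maximum pairwise PSA distance (~0.5) stays below what
maximally diverged real landraces show (~0.7). Passing tests on synthetic
data therefore demonstrate correctness of the estimators and the recovery
machinery, not that a 3-cluster F-model reproduces every marginal feature
of real landrace panels. Allelic dropout, null alleles, plus-A artifacts,
dye pull-up and size-calibration drift are likewise not modeled.

## Numerical conventions

* Frequency cells summing within 1 ± 0.02 are renormalized (spreadsheet
  rounding); outside that window they raise — silent renormalization of
  grossly wrong rows would hide corruption.
* Probability floors of 1e-30 guard log-space operations in the sampler;
  Q rows and P simplexes are renormalized on every draw by construction
  (gamma-normalization), so drift cannot accumulate.
* All stochastic components take explicit integer seeds;
  `k_scan` derives per-(K, run) seeds from the user seed with fixed
  multipliers, keeping every derived seed below 2³¹.
* Trees serialize to newick via scikit-bio `TreeNode`; distance matrices
  live in scikit-bio `DistanceMatrix` containers.

## Problem sizes used by the test suite

Module tests run on datasets of 4–30 populations. The acceptance-style
checks use: a 194 × 28 study-scale dataset for diversity and distance
totals (seconds); five replicate 60-population, 28-locus, K = 3 datasets
(F = 0.25) scanned at K = 1..5 with 3 runs × 600 + 600 sweeps each for ΔK
and ancestry recovery; and one end-to-end run of the same shape starting
from rendered peak tables. A 3 × 2 hierarchical dataset (30 populations,
20 loci, F_top = 0.3, F_sub = 0.1) exercises the sub-structure pipeline.
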