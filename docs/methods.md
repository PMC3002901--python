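# Methods

`crhnet` re-implements, as a single tested pipeline, a strategy for
extracting stimulus-regulated candidate genes from two-color time-course
microarray data and for inferring association structure among the
candidates. The reference design throughout is a CRH-stimulation time course
on spotted cDNA arrays: five time points (1, 3, 6, 12, 24 h), six technical
replicates per time point, three per dye orientation (a dye swap), thirty
two-color arrays in total, with spots deposited by 48 print tips.

## Synthetic data

Every stage is exercised against generated data with known planted truth;
no download is required.

**Intensity model.** Each spot's mean log2 intensity A is a property of the
probe, drawn log-uniformly over a configurable range (default 2^6 to 2^16)
and jittered per array by N(0, 0.3). The measured log ratio on an array is
`M = s·M_true + bias(A, tip) + e`, where `s = ±1` encodes which channel
carries the treated sample, `e ~ N(0, noise_sd)` is replicate noise
(log-normal multiplicative noise on the raw scale; default SD 0.25 log2
units), and the channel intensities are reconstructed on the MA geometry as
`2^(A ± M/2)` plus an optional background floor. The dye bias is a smooth
function of A — `amp·u + curv·(u² − 1/12)` on the centered unit interval
`u` — with per-print-tip coefficients fanned over [0.5, 1.5] of the
configured amplitude with alternating sign. Both terms integrate to zero
over a uniform A, so the bias is a pure intensity-dependent trend: exactly
the artifact print-tip loess normalization is designed to remove, which
makes the normalization stage testable against the injected function.

**Planted structure.** Three kinds of genes can be planted, in disjoint
blocks:

* *Differentially expressed genes* follow early-peaking, mid-peaking,
  late-rising, or sustained response shapes over the five time points,
  scaled by a single amplitude (default 1.5 log2 units, a strong ~3-fold
  response of the kind immediate-early genes show). The amplitude is six
  times the replicate noise so that 5-gene subsets of planted genes can
  discriminate all five time points perfectly — the regime the
  100%-goal-fitness selectors presuppose. (At amplitudes near 3× the noise
  the univariate ANOVA still recovers the genes, but no gene subset attains
  perfect leave-one-out accuracy, so the wrapper selectors would collect no
  solutions.)
* *Dye×time interaction genes* carry a dye-orientation offset whose sign
  alternates along the time grid; the pattern is centered (zero time
  average) and scaled to root-mean-square `interaction_effect` (default
  0.75 = 3× noise, the regime in which the exclusion ANOVA is expected to
  flag them). Centering puts the whole effect on the interaction term
  rather than the dye main effect.
* *Network genes* are drawn i.i.d. across the 30 samples from a Gaussian
  whose precision matrix encodes a planted sparse partial-correlation
  topology (unit diagonal, off-diagonal `−pcor`); the implied covariance is
  rescaled to a common marginal SD (default 1.5, matching the DE
  amplitude). The default topology has four clusters over ten genes — two
  positive pairs (pcor 0.8), a three-gene chain (0.65, the
  positive-definiteness limit for a symmetric chain), one negative pair
  (−0.8) and two singletons. Pair magnitudes were set from a power
  analysis: the shrinkage estimator attenuates partial correlations by
  roughly 40% at 10 genes × 30 samples, and replicate noise dilutes them
  further, so edges planted near the 0.35 reporting filter would sit on the
  decision boundary by construction.

What the generator does **not** emulate: spatial artifacts beyond per-tip
dye bias, correlated (co-printed) probe noise, intensity-dependent variance,
non-Gaussian heavy-tailed spot noise, and biologically structured
co-expression outside the planted network block. Tests passing on this
generator therefore demonstrate algorithmic correctness and calibration
under the design's sampling geometry, not robustness to every artifact of
real arrays.

## Normalization

Background: per array and channel, the dimmest `floor(0.10·n)` intensities
are erased (stable tie-break by intensity then spot id); an erased channel
masks the whole spot on that array, since a half-background spot has no
meaningful ratio. The quantile level is applied per array per channel — a
deliberate choice, configurable, since other groupings (global, per-array
pooled channels) are defensible.

MA transform: `M = log2(treated) − log2(control)` resolved per array from
the dye label, `A = (log2 I_Cy3 + log2 I_Cy5)/2`; zero intensities mask the
spot.

Loess: within each (array, print-tip) group, a robust local quadratic
regression of M on A (tricube weights, span 0.75, four bisquare robustness
iterations) is fitted at the observed points and subtracted. Groups below a
minimum size (default 10 spots) fall back to a whole-array fit with a
warning. The smoother is a local projection only approximately: normalizing
twice changes noisy residuals slightly (the idempotence test therefore uses
a noise-free fixture). All local systems are solved in one batched
normal-equation call with a 1e-12 Tikhonov term for degenerate
neighbourhoods.

Complete cases: only spots present on all 30 arrays enter the ratio matrix.

## Univariate prefilter

Per gene, a balanced fixed-effects two-way ANOVA (factors time and dye) is
computed by the classical cell-mean decomposition — with balance, Type
I/II/III sums of squares coincide, and unbalanced input is rejected rather
than silently re-weighted. Stage 1 fits the model *with* interaction and
excludes genes with raw interaction p < 0.01 (dye-orientation-dependent
profiles). Stage 2 fits the model *without* interaction on the remainder
and preselects genes with raw time-effect p < 0.01. Benjamini–Hochberg
adjusted values are reported alongside; the achieved FDR at each cut is the
maximum q among selected genes — an outcome, not an input, mirroring how
the thresholds are quoted in the source study. Genes with zero residual
variance get NaN p-values and a degeneracy flag and never enter the
preselected pool. Levene's test (Brown–Forsythe form, deviations from the
25%-trimmed group mean; scipy implementation) and per-gene Shapiro–Wilk
tests check the variance-homogeneity and normality assumptions.

## Classifier kernel

The shared classifier is maximum-likelihood discriminant analysis under
class-wise Gaussians with pooled within-class covariance and equal priors —
algebraically identical to classical LDA; a test asserts prediction-level
equality against a directly coded Gaussian-likelihood argmax on random
fixtures. Fitness of a gene subset is its leave-one-out cross-validation
accuracy over the 30 samples with the time point as the class label.

LOOCV is exact but never refits from scratch: for held-out sample *i* of
class *g*, the class mean and pooled scatter are downdated by rank-one
formulas and all 30 fold covariances are handled in a single batched linear
solve (`Σ⁻¹[x | μ_1..μ_G]`). A singular covariance (e.g. duplicated genes,
or k ≥ n − G) triggers a ridge of `1e-8 × mean diagonal` (with an absolute
floor for all-zero matrices), logged; a pseudo-inverse is deliberately not
used so the guard is a minimal, deterministic perturbation.

The generalization-curve diagnostic draws random subsets of each size
(default 2–30, 1000 draws; the acceptance run uses 100) and averages
resubstitution and LOOCV error. On a pool where every gene carries weak
time signal the curve shows the canonical small-n-large-p U-shape: test
error minimal near 10–15 genes and rising past ~20 while training error
goes to zero. On pure-noise data the test error is pinned at the 5-class
chance level (0.8) at every size, so the rising branch is only visible with
signal present — the reason the overfitting check runs on a weak-signal
pool emulating a preselected gene set.

## Genetic algorithm

Chromosomes are unordered 5-gene subsets of the preselected pool. Each
search: random initial population (default 50), fitness-proportional
selection on min-shifted fitness (so the worst chromosome has essentially
zero reproduction probability — plain roulette on accuracies in [0.2, 1]
gives almost no selection pressure), single-point crossover on the sorted
gene representation with duplicate repair, per-slot mutation probability
0.05 replacing a gene by a uniform random non-member, and one-elite
carryover. A search succeeds when a chromosome reaches the goal fitness
(100% LOOCV accuracy) and is abandoned after 200 generations. The search is
restarted up to `max_solutions` times (2500 in the reference configuration;
scaled runs use 250) and every returned solution is re-scored by an
independent LOOCV pass before storage. Genes are ranked by occurrence
frequency in the stored solutions (ties broken by gene id); duplicates
count, with the unique-chromosome count reported separately. Four
repetitions with seeds spawned from a master seed feed the consensus: genes
in the top-50 of at least three repetitions.

The GA's internal parameters (population size, rates) are not dictated by
the procedure being reproduced and are all configurable; the defaults above
are ordinary GA practice.

## Simulated annealing (INSEL)

Same state space and energy (LOOCV error). A move exchanges one uniformly
chosen chromosome slot for a uniformly chosen non-member gene; acceptance
is by the Metropolis rule `min(1, exp(−ΔE/T))`. The starting temperature is
calibrated from the data as the mean absolute difference between successive
energies of 10000 randomly drawn chromosomes (a standard deviation variant
is available behind a flag); a degenerate all-equal stream is floored at
1e-3. Cooling follows the classical SANN logarithmic schedule
`T_t = T0 / ln(⌊(t−1)/tmax⌋·tmax + e)` with `tmax = 10` evaluations per
level — the published schedule of the cited annealing variant; its
constants are configurable since the reproduced procedure does not pin them
down. Each search spends exactly `maxit = 1000` energy evaluations
(including the initial state) and returns the best-ever chromosome;
chromosomes whose independently recomputed LOOCV accuracy is 100% are kept
and frequency-ranked exactly as in the GA. Four repetitions are supported
with spawned seeds.

For cross-method comparisons the package pools the solutions of the four
repetitions of each method before ranking: the low-frequency tail of a
single 250-solution run is dominated by near-ties, and pooling stabilizes
it (single-run GA-vs-GA top-50 agreement is itself only ~65%).

## Baseline selectors

*Greedy Wilks-Λ.* `Λ = det(W)/det(T)`; adding a candidate to a p-variable
model is scored by the partial `Λ_{p+1}/Λ_p` with
`F = ((n−G−p)/(G−1))·(1−Λp)/Λp` on `(G−1, n−G−p)` degrees of freedom (the
standard stepwise-MANOVA formula; at one variable and two groups it reduces
to the squared two-sample t). Selection proceeds while the best candidate's
p-value is below the niveau (default 0.001), with a safety cap of 10 genes
and a collinearity guard: candidates making W singular are ineligible.
Inside the leave-one-out wrapper, each fold selects on 29 samples, fits LDA
on the selected genes and predicts the held-out sample; genes are ranked by
how many folds picked them. A fold with an empty selection falls back to
the majority training class and is counted separately — note that on pure
noise at a strict niveau *every* fold is empty and the majority fallback is
always wrong (the held-out sample's class is the minority), so the reported
error is 1.0, not the 0.8 chance level; both accountings are visible via
`extras['empty_folds']`.

*Random forest.* scikit-learn's `RandomForestClassifier` with 500 trees,
`mtry` = all genes, terminal node size 1, ranked by mean decrease in Gini
impurity (permutation importance behind a flag), out-of-bag error reported.
Ties (e.g. never-used genes at importance 0) break by gene id.

## PCA and graphical Gaussian model

PCA row-centers the genes × samples matrix and takes the SVD; scores
(`U·S`) carry the genes, loadings (`V`) the samples, so the biplot
reconstruction `scores·loadingsᵀ` reproduces the centered matrix exactly.

The GGM route estimates a weighted Pearson correlation matrix — the
"dynamic" time-series weighting assigns each time point a trapezoid-rule
weight over the (1, 3, 6, 12, 24) h grid, split equally among its
replicates; a flag disables weighting — and shrinks it toward the identity
with the analytic intensity `λ* = Σ var̂(r_ij) / Σ r_ij²` (off-diagonal
sums, clipped to [0, 1]), where `var̂(r_ij)` is the usual small-sample
estimate from the spread of products of standardized values, weight-
generalized. Partial correlations come from the inverse:
`r_p(i,j) = −Ω_ij/√(Ω_ii Ω_jj)`.

Edge significance uses the null density of partial correlations,
`f(r) ∝ (1−r²)^((κ−3)/2)`, equivalently `r² ~ Beta(1/2, (κ−1)/2)`. That
density describes *unshrunk* partial correlations, while the shrinkage
estimate attenuates every entry by roughly `(1−λ)`; the statistic is
therefore de-attenuated by that factor before the tail probability is
taken, and a fully shrunk estimate (`λ* = 1`, all partial correlations
zero) carries no evidence and yields p = 1 on every edge. The effective
degrees of freedom κ are fitted to the observed (de-attenuated) edge
ensemble under the assumption that most edges are null — by default with a
robust median-moment match (`κ = median(χ²₁)/median(r²) + 2`), which
ignores the minority of true edges; a full maximum-likelihood fit is
available but, on ensembles as small as 55 edges, is dominated by the very
edges under test and is conservative. With fewer than five edges the
theoretical `κ = n − (p − 2)` is used.

A structural property worth knowing: on pure-noise data at 11 genes × 30
samples the analytic λ* clips to 1 in roughly half of all datasets — the
estimator correctly concludes "no signal" and rejects nothing — so the
edge-wise null rejection rate averages ~0.033 rather than the nominal
0.05. Conditional on partial shrinkage, calibration is close to nominal.

Reported edges must pass `|r_p| > 0.35` *and* `p < 0.05` jointly (both on
the shrunk `r_p` scale for the magnitude filter); unconnected genes remain
in the node set, and edge signs distinguish positive from negative partial
correlation.

## Pipeline, determinism, problem sizes

`run_pipeline` chains the stages, writes every artifact as TSV/JSON plus a
manifest of all consumed parameters and seeds, and aborts with the failing
stage's name while keeping completed artifacts. A single master seed
determines every downstream artifact (seeds for the stages and for each
selector repetition are spawned from it); rerunning a configuration
reproduces byte-identical ranked lists.

The shipped test and acceptance configurations run the full design at
reduced search budgets chosen as the package's own working scale: a
400-gene pool with 10 planted discriminative genes, 4 GA repetitions of 250
collected solutions (vs 2500 in the reference configuration), 4 annealing
repetitions of 250 searches at `maxit` 1000, 50-seed averages for network
recovery, and 100 draws per subset size for the generalization curve. All
budgets are plain parameters; the reference values are the defaults on
`GaParams`/`SaParams`.

## Known limitations

* The annealing cooling constants and the GA's internal parameters are
  educated defaults, not reproductions of unpublished settings.
* Edge p-values are calibrated to ~0.03–0.04 at a nominal 0.05 on 11-gene
  null ensembles; with very few genes the κ fit is replaced by a
  theoretical value.
* The loess smoother extrapolates its local fit at group boundaries; spots
  far outside a tip's fitted A-range are normalized by boundary
  extrapolation.
* `greedy_loocv`'s error depends visibly on the empty-fold fallback policy
  on signal-poor data (see above).
* Between-array scale/quantile normalization is intentionally absent: the
  reproduced procedure normalizes within arrays only.
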