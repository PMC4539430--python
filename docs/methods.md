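# Methods

This note documents the statistical model, the algorithms of each pipeline
stage, the simulation framework, and the design choices made where the
design was genuinely open. Parameter defaults are stated with their units
and rationale.

## 1. The QTS mixed model

For line *k* (of *n* fully inbred RILs) in environment *h* (of *H*):

    y_hk = mu + Σ_i x_ik a_i + Σ_{i<j} x_ik x_jk aa_ij + e_h
         + Σ_i x_ik ae_hi + Σ_{i<j} x_ik x_jk aae_hij + eps_hk,
    eps_hk ~ N(0, sigma2) i.i.d.

Genotype codes `x` are +1 for the homozygote of the high-frequency allele,
−1 for the other homozygote, 0 for a heterozygote (allele-frequency ties
broken lexicographically so coding is deterministic). Environment
interaction vectors are stored sum-to-zero across environments
(`Σ_h ae_hi = 0`), which separates them from the main effects; a flag
disables the constraint for non-centred inputs. Dominance is not modelled —
the target populations are fully inbred.

### Heritability accounting

Every elementary effect (each `a_i`, each `ae_hi`, each `aa_ij`, each
`aae_hij`) contributes the empirical variance of its fitted values over the
realized design (all lines × all environments). The modelled phenotypic
variance is the **sum** of these per-term variances plus `sigma2`;
cross-term covariances are ignored. Consequences: the per-effect
heritabilities sum exactly to the reported total, every component lies in
[0, 100]%, and the residual-variance solver (below) is consistent with the
reported heritabilities. For the bundled designs the ignored covariances are
negligible (true loci sit on different chromosomes or >50 cM apart); for
heavily linked architectures the total can deviate from the variance of the
summed genetic value by the covariance terms. The environment main effect is
excluded from both numerator and denominator (policy `"exclude"`; a
`"denominator"` policy adds its variance to the denominator only).

## 2. RIL simulation

Genotypes: each chromosome is a first-order Markov chain along its markers.
The first marker is ±1 with probability 1/2; each subsequent marker flips
sign with probability `R = 2r/(1+2r)` where `r = (1 − exp(−2d/100))/2` is
Haldane's map function of the inter-marker distance `d` (cM). `R` is the
expected recombinant fraction between fixed RIL genotypes under repeated
selfing; the Markov walk is exact for all pairwise expectations and far
cheaper than gamete-level simulation of the selfing generations. Assumes no
crossover interference and no segregation distortion; simulated panels have
no heterozygous or missing calls (real panels may, and the coding layer
carries both).

Phenotypes are drawn from the model above. The residual variance is solved
per dataset so the genetic terms (a, aa, ae, aae — not the environment main
effect) explain a target heritability on the realized genotype matrix:
`sigma2 = V_g (1 − h2)/h2`.

The bundled study design mirrors a typical dense-marker RIL experiment:
3 chromosomes × 175 markers at 1 cM (the counts are fixed by the design;
the spacing is a package default, configurable), two environments with fixed
effects ±1 trait unit (an explicit, transparent choice; a random-environment
mode exists), population mean 10, three additive QTSs (chr1 marker 28,
chr2 marker 100, chr3 marker 93) and one epistatic pair (chr2:44 × chr3:63).
Two generating scales are bundled, "large" (a ≈ −3.2…−1.8, aa = 3.86) and
"small" (a ≈ −0.8…−0.4, aa = 0.39); they differ only in magnitude.
Replicate *i* uses seed `base_seed + i`; the permutation-threshold
calibration dataset uses `base_seed + n_replicates`.

What passing the simulation studies does **not** show about real data:
markers here segregate 1:1 without distortion or missingness, environments
are balanced complete blocks, and residuals are Gaussian — real RIL panels
violate all of these to some degree.

## 3. Stage 1 — GMDR screening

Score statistic: the residual of each line-by-environment observation from
the null covariate model (grand mean + environment means), so scores sum to
zero within every environment.

Cells are **genotype × environment** classes. This matters: under the
sum-to-zero convention a line's summed score cancels `x(ae_1 + ae_2)`
exactly, so a QTS whose effect reverses across environments is invisible to
cells pooled over environments, while environment-specific cells retain the
signal. With one environment the scheme is the classical quantitative-trait
GMDR. A cell is HIGH if its summed training score is positive, LOW if
negative, UNCLASSIFIED if empty or exactly zero (such observations are
skipped in scoring, which avoids arbitrary risk assignment in sparse cells).

Each 1-, 2- (optionally 3-) locus combination is scored by k-fold (default
k = 10, folds assigned to whole lines, seeded) cross-validated **balanced
testing accuracy**: an observation is "positive" if its score is positive,
"predicted positive" if its cell is HIGH. Consistency is reported as the
number of folds whose accuracy exceeds 0.5 — a per-model quantity (the
classical "folds in which this model is best" definition requires scoring
every competitor in every fold, which the exhaustive search cannot afford
per model). Ranking is (accuracy, consistency, lexicographic ids), fully
deterministic.

For homozygous ±1 panels the exhaustive search is vectorized through the
bilinear identity `Σ_k w_k 1[x_ik = u, x_jk = v] =
(S0 + u S1_i + v S1_j + uv S2_ij)/4` with `S2 = X' diag(w) X`, reducing each
fold to a handful of Gram products; panels with heterozygous or missing
codes fall back to a generic per-combination evaluator. A combination budget
(default 5 × 10⁷) refuses searches that would not finish, instructing the
user to lower the order or pre-filter.

**Candidate construction.** RIL linkage disequilibrium decays slowly
(genotype correlation 1 − 2R ≈ 0.67 at 10 cM, 0.37 at 30 cM), so the ranked
model list is dominated by linkage shadows of the strongest locus. Retention
is therefore *clumped*: a model is retained only if it contributes a marker
farther than `clump_window_cm` (default 30 cM, the distance where RIL LD
falls below ~0.4) from every marker already retained at its order, until
`retain_m` (default 10) models per order are kept. Because cross-validated
accuracy localizes a *region*, not a marker (the accuracy-best marker can
sit 10–15 markers from the true locus), each retained marker is expanded by
`expand_markers` (default 15) neighbours per side into the 1D candidate
list — the scan's F profile does the fine mapping — and each retained
two-locus model contributes its `expand_pair_markers` (default 5) pair
neighbourhood as explicit 2D terms for panels too large for the exhaustive
pair sweep. The clumped representatives become the background cofactor pool.

## 4. Stage 2a — scans and permutation thresholds

A QTS is "detected" when it has an effect in *some* environment, matching
how power is tallied per SNP, so the scan statistic is the joint partial F
of a term's effect **and** its environment interactions (numerator df = H):

* 1D: block `x_i·1[env=h]` (spanning `a_i, ae_hi`) over a baseline of
  per-environment regressions on the background cofactors.
* 2D: block `x_i x_j·1[env=h]` (spanning `aa_ij, aae_hij`) over the same
  baseline form.

Baselines are *per-environment* (cofactor × environment columns) because a
background QTS's per-environment effect is `x(a + ae_h)`; environment-
constant cofactor columns would leave all background G×E variance in the
residual. The 1D baselines additionally include the *products* of each
retained two-locus model's markers, absorbing background epistatic variance
(a pair at the large bundled scale carries ~69 trait-units² of
environment-1 variance that no additive column can touch). Products are
omitted from the 2D baseline, where they would absorb the tested pair's own
signal; the 2D residual carries no additive background anyway because a ±1
product is orthogonal to every single-marker code.

That orthogonality also makes the 2D family cheap: `Σ_k x_ik x_jk w_k =
(X' diag(w) X)_ij`, so the pair sweep over **all** marker pairs is a few
Gram products per environment. The 2D family is exhaustive whenever the pair
count fits a budget (default 2 × 10⁵; 525 markers → 137,550 pairs) and falls
back to the screened pair neighbourhoods otherwise. This is deliberate:
a weak pure-interaction pair is invisible to marginal screens — any
two-locus model containing a strong additive marker inherits that marker's
accuracy and outranks it — so epistasis detection must not be gated on the
screen. Near-constant products (tightly linked pairs, centred product
variance < 0.25·n) are excluded from the family. Member additive blocks are
not added per pair (orthogonality again; the permutation calibration absorbs
the O(1/√n) finite-sample leakage).

Cofactors within `cofactor_window_cm` (default 30 cM) of a tested 1D marker
are excluded from that test's baseline — the composite-interval-mapping
convention; with narrower windows a shadow representative 11–30 cM away
absorbs about half of the tested marker's own signal.

**Thresholds.** Whole line profiles are permuted jointly across lines
(preserving each line's multi-environment vector, the correct null of no
genotype–phenotype association), the maximum F per scan family is recorded
per permutation, and the threshold is the `ceil((B+1)(1−alpha))`-th smallest
of the B maxima (B ≥ 19; default B = 200, alpha = 0.05). The 1D and 2D
families carry separate thresholds, flagged in the output. The permutation
path evaluates exactly the same projections as the observed scan, vectorized
across permutations. In replicated power studies the threshold is calibrated
once per scenario on a dedicated calibration dataset and reused across
replicates; thresholds are conditional on that dataset's candidate set, so
familywise control is exact for the scan stage given the screen.

**Single-term mixed-model fit.** `fit_term_model` provides the
random-interaction formulation: the term's additive (and epistatic) effect
fixed; environment and the term's interactions as independent Gaussian
random effects; variance ratios by profiled REML (Woodbury identities;
coarse log-grid search with Nelder-Mead refinement); Wald F with an
approximate Satterthwaite denominator df (finite-difference gradient and
REML information). It reduces exactly to the OLS partial F in one
environment. It is **not** the scan's detection statistic: with H
environments the F for `a` against a random `ae` has noncentrality bounded
by `H a²/σ²_ae` no matter how many lines are genotyped, which leaves even
strong QTSs undetectable at H = 2 — the joint fixed-form test is the one
whose power grows with n.

## 5. Stage 2b — full-model MCMC

Significant 1D markers enter as additive terms, significant 2D pairs as
epistatic terms, and each pair's members also receive additive terms (the
model is hierarchical). Clusters of significant terms within
`prune_window_cm` (default 30 cM) on a chromosome are pruned to their local
F peak first — without pruning the model carries near-collinear copies of
one signal and per-marker posteriors are unstable.

The Gibbs sampler: fixed effects (intercept, `a`, `aa`) from their joint
normal conditional (flat prior, 1e−10 ridge); each random group (`e`, one
`ae` group per additive term, one `aae` group per pair) has i.i.d. normal
effects across environments with its own variance component under an
InverseGamma(0.01, 0.01) prior; the residual variance has the same prior.
Within a group the H random columns have disjoint support (one environment
block each), so group updates are diagonal. Each retained draw is
re-expressed in the sum-to-zero convention (interaction means folded into
the corresponding main effect, the environment mean into the intercept),
which resolves the mean/interaction confounding before summaries.

Defaults: 12,000 iterations, 2,000 burn-in, thinning 2 — sized so a full
model of ~10 terms mixes well at desk scale; the power-study driver uses
4,000/1,000/1 (its estimates are averaged over replicates, so per-replicate
Monte Carlo noise is pooled). Summaries per effect: posterior mean, SD,
t = mean/SD, two-sided P from a t distribution with df = effective sample
size − 1 (ESS via `arviz`; conservative when mixing is slow), −log10 P, and
the per-effect heritability from the posterior-mean effect set. A summary
whose minimum ESS falls below 100 is still returned, flagged
`converged=False`.

## 6. Power studies

Per replicate: simulate genotypes and phenotypes, screen, scan against the
scenario's calibrated thresholds, optionally estimate. A true term counts as
detected only when **that exact marker (or pair)** is declared significant
(a declaration window of ±w markers is available but defaults to exact).
Estimates are averaged over detecting replicates only — matching how
conditional means are reported alongside partial power — with the full-model
term matched to the truth within ±2 markers, since the pruned F peak can
land on an immediate neighbour. Replicates that raise are logged and
excluded.

Two operating characteristics worth knowing:

* Additive-QTS power is screen-limited in the weak regimes (the scan's F at
  a nominated marker almost always clears the threshold; most misses are
  regions the screen did not nominate or localized poorly).
* Pair power under experiment-wise control is scan-limited: at the
  modest-effect scale (aa = 0.39 against σ² ≈ 2) the joint-F noncentrality
  is ~26–60 against an exhaustive-family threshold of F ≈ 16–20, i.e.
  detection is partial, and the detected-replicate mean of `aa` is
  selection-biased upward. The per-environment regression coefficients at
  the pair are unbiased (checked directly), so this is a property of
  conditioning on detection, not of the estimator.

## 7. Numerical choices and degenerate inputs

* Rank-revealing SVD bases for all projections; terms whose block is
  collinear with the baseline are skipped with a warning and recorded as
  missing.
* Monomorphic markers are excluded at coding time (warning) and skipped as
  scan terms; markers with zero residual variance after projection are
  dropped from their group.
* Lines with incomplete phenotype profiles are dropped by the scan and the
  sampler (logged count); the permutation scheme requires balanced profiles.
* Cell-sum ties in GMDR use a 1e−12 tolerance around zero.
* Scan F is invariant to affine rescaling of the phenotype; all stages are
  bit-reproducible given a seed, and results are independent of thread
  count because every replicate derives its own seed.

## 8. Known limitations

* No dominance, no outbred designs, no kinship/population-structure random
  effect (single biparental RIL population), no selective genotyping.
* The heritability accounting ignores cross-term covariances (see §1).
* With two environments the REML variance components of `fit_term_model`
  rest on H = 2 interaction levels and are weakly identified; the scan's
  fixed-form joint test is the supported detection route.
* The exhaustive 2D sweep requires fully homozygous ±1 codes; heterozygous
  or missing panels use the screened pair families.
* Experiment-wise thresholds are conditional on the screened candidate set;
  the screen and the scan are not jointly permuted (rerunning the screen
  inside every permutation is computationally out of reach and the
  per-family error rates verify at alpha in the null calibration).
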