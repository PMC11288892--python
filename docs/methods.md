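# Methods

This note records the model, the tunable parameters, the synthetic-data
generator, and the numerical and design choices behind `meltshift`, at the
level of detail a maintainer or reviewer needs to judge what the package's
tests do and do not demonstrate.

## Profile model

Peptide intensities along the temperature gradient are treated as noisy
observations of a smooth latent profile per (peptide, condition). Replicates
enter as independent observations at the same temperature; they are never
averaged before fitting. A peptide enters fitting only if it is quantified
(finite, positive intensity) at ≥ 8 of the 10 gradient temperatures in every
condition — below that an exact GP with four hyperparameters is poorly
identified. Zero intensity is treated as missing, since a DIA zero usually
means "not quantified" rather than "absent".

Scaling is min–max per peptide, pooled across conditions and replicates.
Pooling is essential: scaling each condition separately would erase exactly
the between-condition differences the area score measures.

The GP has a constant mean c, squared-exponential kernel (signal variance
σ_f², lengthscale ℓ) and homoscedastic Gaussian noise σ_n². Hyperparameters
are found by L-BFGS-B on (c, log σ_f², log ℓ, log σ_n²) with analytic
gradients of the exact marginal likelihood, initialized at c = mean,
σ_f² = var, ℓ = 10 °C, σ_n² = 0.1·var, with a restart from ℓ = 30 °C if the
first optimization reports failure. Bounds: ℓ ∈ [1, 500] °C (the floor
prevents the kernel from chasing replicate noise; gradient spacing is
3.5–4.9 °C), variances ≥ 1e−8. An optimizer stop at the iteration cap with a
finite objective is accepted as a local optimum; only a non-finite objective
marks a peptide unfit.

**Shared hyperparameters.** The two condition models of a peptide share one
hyperparameter vector, fitted by maximizing the *sum* of their marginal log
likelihoods. Noise level and smoothness are properties of the peptide and
assay, not of the condition; sharing doubles the data behind σ_n², whose
occasional collapse under the (heteroscedastic, multiplicative) replicate
noise is otherwise the dominant source of spurious band separations. Each
condition keeps its own posterior mean, so a genuine condition shift cannot
inflate the shared noise estimate. A pooled-data fit of both conditions
together is available as a per-peptide diagnostic
(`joint_fit_diagnostic`: ΔMLL of separate vs pooled fits), not used in
scoring.

**Confidence band.** The ±2 s.d. band uses the posterior *predictive*
standard deviation (latent variance + σ_n²). This is the conservative
convention for comparing two independently fitted curves; the latent-only
band is available via `band_includes_noise=False`.

A peptide is flagged *flat* (the in-situ disorder signature) when the raw
per-temperature mean intensities satisfy |log2(max/min)| < 0.5, strictly.

## Clustering and shape groups

Fitted control-condition profiles, evaluated on the 20-point clustering grid
(37, 39, …, 75 °C), are clustered by fuzzy k-means with entropy
regularization: J = Σ u·d² + p·Σ u log u, closed-form membership update
u ∝ exp(−d²/p), membership-weighted centroid means; k = 20, p = 2, best of 5
restarts, convergence when the largest membership change is < 1e−6 or 500
iterations. Two numerical choices deviate from the most naive
implementation, both forced by failure modes observed on synthetic data:

* **Initialization** is k-means++ seeding of centroids at data profiles.
  Random Dirichlet membership rows start every centroid at the global mean
  profile, a degenerate configuration the entropy update does not escape.
* **Distances are computed on per-temperature z-scored profiles** (the
  standardization option of classical fuzzy-clustering packages). On raw
  0–1 profiles, squared distances are small relative to the fixed p = 2 and
  all memberships collapse toward uniform, which destroys the minority
  (nonmonotonous) shape group; with standardization, archetype recovery on
  synthetic data is 100% at σ = 0.05. Centroids are reported back in
  original units so the grouping threshold keeps its stated scale.

Clusters are grouped by their centroid's endpoints: *nonmonotonous* iff
|c(75) − c(37)| < 0.5, otherwise *increasing*/*decreasing* by sign; the
pointwise weighted-median profile is available as an alternative
representative (`cluster_representative="median"`). A peptide's group
probabilities are its memberships summed within each group; its label is the
argmax. Osmolyte-induced shape changes are called from a second, joint
clustering of control + osmolyte profiles: changed iff some group's
probability differs by more than 0.5 between conditions.

## Scoring and rollup

Both condition curves are evaluated on a 0.5 °C grid (37–76). Maximal runs
of grid points with disjoint bands form non-overlap intervals; each
interval's area is the spacing-weighted Riemann sum of (m_osm − m_ctl), so
scores are grid-independent (halving the step changes scores by < 2%).
Intervals are classed by midpoint: < 44.4 °C binding, > 68.6 °C aggregation
(the 3rd and 8th gradient temperatures — the binding analysis uses the first
two temperatures and the aggregation analysis the last ones), otherwise
stabilization; boundaries are configurable. Among stabilization-class
intervals the maximal |area| is the peptide score, signed +1 for decreasing
profiles, −1 for increasing, and by the local control-curve trend over the
interval for nonmonotonous peptides (a falling segment behaves like a
decreasing profile). Swapping the conditions negates every score exactly.

**Fit weight.** Each peptide carries w = ε + RSS_ctl + RSS_osm (ε = 1e−3),
the goodness of fit summed over conditions, used as its weight in the
quantile rollup. Weighting *by* the residual sum of squares rather than its
inverse is deliberate: with marginal-likelihood-fitted GPs on replicated
data, a near-zero RSS signals a fit that interpolated the replicate noise
(σ_n² collapse) — precisely the failure mode that produces spurious band
separations — so such peptides should carry little weight. On the synthetic
null this choice reduces the protein-level false-positive rate from ~8% to
< 1% at unchanged sensitivity; `weight_mode="inverse_rss"` restores the
opposite convention.

**Weighted quantile.** The rollup quantile is the inverse of the weighted
empirical CDF (smallest value whose cumulative weight fraction reaches q),
which is exactly invariant under replacing a weight-k point with k unit
copies. The step form matters: a protein whose positive-score positions
carry less than 1 − q of the weight rolls up to exactly 0, which is what
keeps the protein-level false-positive rate at the calibrated level. An
interpolated midpoint-CDF variant (with the tie-merging required for its own
expansion invariance) is available as `method="interpolated"`.

Rollup: per covered residue position, the mean of covering peptide scores
decides the direction and the weighted 0.75 (stabilized) or 0.25
(destabilized) quantile gives the position score; per protein, the same rule
applies across positions with the positions' mean fit weights. A protein is
called stabilized/destabilized iff its score is nonzero. The quantile pair
is the calibration knob: `sweep_quantile` scans (q, 1 − q) for q ∈
{0.5, 0.55, …, 1.0} on a replicate-split null and returns the smallest q
meeting a target FDR (default 5%), sharing the GP fits across the sweep.

## FDR calibration and statistics

The null experiment generates four replicates of the control condition from
identical parameters and labels replicates {1, 2} and {3, 4} as two
pseudo-conditions. The empirical FDR is the fraction of units with nonzero
stabilization-class score. On the default null (200 proteins × 8 peptides,
σ = 0.05) the pipeline measures ≈ 1.5–2% at peptide level and ≤ 1% at
protein level with the 0.75/0.25 pair.

Differential abundance (binding: 37/40.5 °C, adj. p < 0.01, |log2FC| > 1.5;
LiP aggregation: 72.5/76 °C, adj. p < 0.05, |log2FC| > 1; TPP aggregation:
68.6/72.5/76 °C; protease-activity mode without a temperature subset) pools
log2 intensities across the included temperatures into one Welch or
moderated t-test per peptide, BH-corrected over all tested peptides, with
log2FC on mean raw intensities and strict threshold inequalities; a protein
is flagged as soon as one proteotypic peptide is a hit. The moderated test
shrinks pooled variances toward a scaled-inverse-chi-square prior whose
(d0, s0²) come from method-of-moments on log sample variances
(digamma/trigamma moments, Newton inverse-trigamma); d0 → 0 recovers the
pooled t-test, d0 → ∞ fixes all variances at s0². TPP profiles (abundance
relative to 37 °C) pass through the same scale–fit–score machinery with no
rollup; a protein is a nonprecipitator iff > 50% remains soluble at the top
temperature (strict). The Spearman analysis correlates each protein's score
vector across osmolytes with the across-protein mean vector; its null
re-correlates against the mean vector randomly permuted across conditions,
independently per protein and repetition (1,000 by default).

Sequence features: length, amino-acid and group percentages, Kyte–Doolittle
GRAVY, aliphatic index (A% + 2.9·V% + 3.9·(I% + L%)), maximal Eisenberg
hydrophobic moment (100° periodicity, window 11), and net charge / pI by
Henderson–Hasselbalch bisection with the EMBOSS pKa set (N-term 8.6, C-term
3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1).

## DSF model

The two-state unfolding equation with linear baselines,
S(T) = (S_f + m_f T + (S_u + m_u T)·e^g)/(1 + e^g) with
g = (ΔH_m/RT)·(T − T_m)/T_m and R = 8.314 J K⁻¹ mol⁻¹, is evaluated in the
overflow-safe sigmoid form; temperatures are kelvin internally, °C at the
interface. Curves are min–max scaled (making the fit invariant to affine
transformations of the raw signal) and fitted by bounded nonlinear least
squares: T_m initialized from the derivative peak and bounded to the data
range, ΔH_m ∈ [10, 2000] kJ/mol starting at 200, baselines from straight
lines through the first/last 15% of points; up to three starts. The
derivative-based T_m smooths with a 5-point centred moving average (edges
dropped — padding creates spurious edge peaks), takes |dS/dT|, and reports
every local maximum with prominence ≥ 0.05 of the largest slope, so
multi-domain proteins yield multiple transitions and a monotone linear
signal yields none. Replicates are fitted jointly with shared parameters.

## Synthetic data

The generator reuses the two-state sigmoid (flat baselines,
ΔH_m = 300 kJ/mol, so a transition spans ~3–4 gradient steps) as the
folded-fraction curve f(T; Tm). Fully tryptic peptides of an *unfolder*
protein follow f; of an *aggregator*, 1 − f; *nonmonotonous* proteins follow
a bump, the product of a rising sigmoid at T_m − 5 and a falling one at
T_m + 5 (both scaled endpoints low, so the profile lands in the
nonmonotonous group by construction). Half-tryptic peptides carry 1 − profile
with an independent amplitude. The osmolyte condition shifts every midpoint
of a protein by its delta_Tm. Observed intensity is amplitude (log-uniform
in [1e4, 1e6] per peptide) × profile × lognormal noise (log-s.d. σ), with
optional missingness ≤ 0.2. Peptides tile the protein (default length 160,
8 peptides of 15 residues, 30% overlap). The default archetype mix (60%
unfolder, 25% aggregator, 15% nonmonotonous) reflects the
decreasing-dominated shape distribution of bacterial lysate profiles. All
generators are pure functions of (parameters, seed); the seed is mandatory.

What the generator does *not* emulate: additive electronic/background noise
(noise is purely multiplicative, so scaled plateaus near zero are almost
noise-free — harder for a homoscedastic GP than real data), intensity-
dependent missingness, correlated replicate effects, shared peptides between
proteins, protease-activity drift, and retention-time/charge-state effects.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under its own model assumptions plus multiplicative heteroscedasticity, not
performance on any particular real instrument's data.

## Problem sizes

Tests and the acceptance script use 200 proteins × 8 peptides for the null
calibration (the size at which the calibration claims are stated), 45–100
proteins for recovery and sensitivity checks, and 100 Monte-Carlo seeds for
DSF parameter-recovery statistics — sizes chosen so the whole suite runs in
a few minutes on one CPU while keeping binomial error on the measured rates
well below the margins being tested.

## Known limitations

* The GP noise model is homoscedastic while scaled LiP intensities are not;
  the shared-hyperparameter fit and RSS weighting mitigate, but peptides
  with extreme amplitude profiles remain the main false-positive source.
* Fuzzy-membership softness depends on the distance scale; the fixed entropy
  degree p = 2 is calibrated to standardized profiles and should be re-tuned
  if standardization is disabled.
* The area score saturates for shifts larger than the gradient span of the
  transition and is attenuated near the gradient edges.
* Domain-level tests assume peptide scores within a domain are independent,
  which overlapping peptides violate mildly.
* `sweep_quantile` calibrates on a single null dataset; the returned
  quantile inherits that dataset's sampling error.
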