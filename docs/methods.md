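# Methods

`spikedyn` analyzes binary spike rasters — neurons × 1-ms time bins, 1 =
at least one spike — recorded under three repeated conditions per culture
(control, drug, washout). All information quantities are reported in bits.

## Estimation philosophy

Every estimator is a **plug-in (maximum-likelihood) discrete estimator**:
empirical joint frequencies over integer-encoded words, no bias
correction. Significance never comes from the point estimate but from
surrogate tests (or, in the bivariate prefilter, from the asymptotic
chi-squared null), so the small positive bias of plug-in mutual
information cancels between the observed statistic and its null
distribution — *provided the null preserves the statistical structure the
observed estimate is exposed to* (see "Surrogates" below).

## First-order measures

**Entropy.** H(X_t) = −Σ P(x) log₂ P(x) over the empirical bin-state
frequencies of one neuron. For a binary series 0 ≤ H ≤ 1, and H
increases with firing rate throughout the sparse regime, so rate effects
appear as entropy effects.

**Active information storage (AIS).** AIS(X) = I(X_past; X_t), with
X_past a *nonuniform embedding*: a sparse subset of past lags 1..τ_max
(default τ_max = 5 bins). Selection is greedy: each round picks the
candidate lag with maximal conditional mutual information given the
already-selected lags and tests it against `n_shuffles` surrogates
(default 1,000) of the **maximum statistic over all remaining candidate
lags**, permuted within strata of the selected-lag word; selection stops
at the first non-significant round (α = 0.05). The max-statistic is
essential: testing the best of τ_max candidates against a single-lag null
would inflate the per-round false-selection rate from α to roughly
1 − (1 − α)^τ_max (≈ 23% at τ_max = 5). Exact ties break toward the
smaller lag. Because H, AIS and the conditional entropy rate H_μ are
computed from one shared empirical joint, the information regression
H(X_t) = AIS + H_μ holds to machine precision. The **memory horizon** is
the deepest selected lag in ms; an empty embedding reports it as missing
(excluded from condition means, with AIS = 0 and H_μ = H). Normalized
AIS is AIS/H(X_t), undefined (flagged, excluded) for silent neurons.

A structural caveat: greedy selection requires each additional lag to be
*marginally* informative given the current set. Processes whose past is
informative only jointly — e.g. X_t = XOR(X_{t−1}, X_{t−2}), where every
single lag has exactly zero mutual information with the present — are
invisible to any forward-selection embedding, ours included.

**Entropy production.** Time irreversibility of one neuron's train:
the 1-ms series is compressed into non-overlapping 5-bin macroframes
(32 states; trailing partial frame dropped), ordered successive frame
pairs are counted, only pairs observed in both directions are retained,
forward pair frequencies are renormalized over that symmetric support,
and D = Σ p(i→j) log₂ [p(i→j)/p(j→i)] is returned. Reading p(i→j) as the
*joint* frequency of ordered pairs makes D a true KL divergence between a
distribution and its transpose on a common support: nonnegative by
Gibbs' inequality, zero exactly under detailed balance, and invariant to
relabeling the word states. The conditional-probability reading (row-
normalized transition matrix in the log ratio) is exposed as
`entropy_production(mode="conditional")` but carries no nonnegativity
guarantee. An empty retained support reports the value as missing. The
plug-in estimate is biased upward at finite length, decaying roughly like
(#retained pairs)/(2 · #frames); condition comparisons are unaffected
because recording lengths match across conditions.

## Network inference

Effective connectivity by multivariate transfer entropy (mTE), two stages
per target, each conditioning on 5 bins of the target's own history:

1. **Bivariate prefilter.** Every other neuron is screened at source lags
   1–30 bins with the analytic null: under conditional independence,
   2N·CMI (nats) is asymptotically χ² with (|Y|−1)(|X|−1)·|C| degrees of
   freedom, counting only observed symbols and conditioning states.
   Lags are Bonferroni-corrected within a source (α/30); a surviving
   source enters at the lag maximizing its significant bivariate TE and
   contributes exactly that one lagged bin downstream.
2. **Greedy multivariate selection.** Candidates are added by maximal CMI
   given the target past and already-selected parents, tested against the
   max-statistic over 250 surrogates of all remaining candidates
   (one-step family-wise control, α = 0.05); a pruning pass re-tests each
   selected parent given the final set. Edge weight is the conditional
   transfer entropy I(Y_past; X_t | Z⁻ʸ_past, X_past), also reported
   normalized by the target entropy.

**Surrogates.** The default surrogate permutes the candidate source
within strata of the conditioning word, drawn exactly via vectorized
hypergeometric cell counts — the exact permutation null for conditional
independence. A time-rotation ("circular shift") surrogate is available
(`surrogate_mode="circular"`); it preserves the source's autocorrelation
but also destroys its dependence on the *conditioning* variables, so when
a candidate is genuinely correlated with a selected parent or the target
history (chains, siblings, autocorrelation), the observed plug-in
statistic carries a larger finite-sample bias than the rotated null and
weak spurious edges pass. On ground-truth benchmarks this miscalibration
halves edge precision; the stratified default keeps the false-positive
rate at α while leaving true-edge recovery unchanged.

No final across-target FDR pass is applied (single-α design). Per-node
metrics are in-degree, total normalized inflow, and the local clustering
coefficient of the binarized inferred digraph (directed generalization by
default; undirected projection via config). The decomposition
H(X_t) = AIS + mTE(Z→X) + H_μ is exact when all terms share one plug-in
joint (`information_regression`).

## Partial information decomposition

For every two-parent/one-target motif of the inferred network (parents at
their inferred lags), the joint mutual information splits as
I(Y₁,Y₂;X) = Red + Unq₁ + Unq₂ + Syn with I(Y_i;X) = Red + Unq_i.
Unique information follows the BROJA definition: Unq₁ = min_Q I_Q(X;Y₁|Y₂)
over distributions preserving the (X,Y₁) and (X,Y₂) pairwise marginals.
For binary triads that feasible set is a 2-D box (one Fréchet-bounded
free cell per target state), and since H_Q(X|Y₂) is fixed by the
constraints the problem reduces to maximizing the concave H_Q(X|Y₁,Y₂):
a 33×33 grid scan locates the basin and L-BFGS-B polishes it. The
remaining atoms follow from the marginal identities, so the identities
hold to ~1e−6 bits by construction and nonnegativity holds to optimizer
tolerance. An independent dense-grid search over the same polytope serves
as the test oracle. Synergy is reported normalized by the target entropy;
for condition comparisons the unit is the *target neuron* (mean
normalized synergy over its motifs), because individual motifs are not
stable units across conditions when the inferred network changes.

## Condition comparison

Measures span orders of magnitude, so values are natural-log transformed;
nonpositive or missing values are excluded with a count, and only
complete cases (units with values in all three conditions after
exclusion) enter the tests, the reported means ± SD, and the CDF plots.
The omnibus test is Friedman's χ² (average-rank ties, 2 df); post hoc
contrasts are paired t-tests per condition pair with paired Cohen's d
(mean difference / SD of differences; the pooled-SD variant is reported
alongside), Bonferroni-corrected across the three pairs with the
uncorrected p also reported. Neurons are pooled across cultures as one
sample. This treats neurons as independent units; in a coupled network,
neurons sharing upstream parents have correlated fluctuations, which
inflates between-condition contrasts that are null — a limitation
inherent to pooled-neuron repeated-measures designs that our calibration
tests sidestep by using uncoupled generators, and that real-data analyses
should keep in mind.

## Synthetic generator

The generator emulates the recording design end to end: per culture,
≥ 30 neurons with baseline rates log-spaced over 0.5–20 spikes/s (sparse
firing spanning orders of magnitude) for about an hour per condition at
1-ms bins (defaults; analyses in tests and the acceptance script use
shorter durations, stated where used). Couplings form a directed acyclic
graph with per-edge lag (1–5 bins) and transmission probability; a target
fires by probabilistic OR of its baseline and each parent's lagged,
Bernoulli-thinned drive. Acyclicity is required so conditions simulate in
topological order without a per-bin loop; recurrent motifs are out of
scope. Condition effects are multiplicative on rates and transmissions
and additive on edge count: the default "drug" condition applies rate
×1.3, transmission ×0.7, and +5 weak edges (transmission 0.25), the
qualitative signature under study (entropy up, per-edge flow down, edge
count up). Note that with a coupled graph the *net* firing-rate (hence
entropy) effect of the drug condition combines the baseline boost with
the loss of coupled drive from weakened transmissions, and can go either
way for strongly driven, low-baseline neurons; the entropy-contrast
calibration therefore injects a pure rate effect into an uncoupled
experiment. XOR triads (targets equal to the lag-1 XOR of two parents,
with flip noise) inject pure synergy; an order-2 chain whose rising- and
falling-edge continuation probabilities are biased by ±b injects broken
detailed balance (a 2-state order-1 chain is always reversible, so order
2 is the minimal irreversible binary construction; b = 0 recovers i.i.d.
flips). Every generator is a pure function of (config, seed), and the
ground-truth ledger records all drawn parameters, so edge recovery is
scored without re-deriving anything.

What the generator does *not* emulate: bursting/avalanche statistics,
refractoriness, nonstationary rates, common-input latent drive, and
recurrent (cyclic) connectivity. Passing tests therefore certify the
estimators and the inference logic on data satisfying the model
assumptions, not robustness to every property of real recordings.

## Numerical and design choices

- Bins are half-open [kw, (k+1)w), 0-based; spikes at or beyond the
  stated duration are a hard error.
- "Active" in a condition means ≥ 1 spike (configurable); cultures need
  ≥ 30 active neurons; only neurons active in all three conditions are
  analyzed (complete-case / repeated-measures validity).
- Surrogate p-values use (1 + exceedances)/(1 + S), so the smallest
  attainable p is 1/(S+1).
- All randomness flows from one root seed through per-task streams keyed
  by (culture, condition, unit), making results independent of neuron
  ordering and job count; reruns are byte-identical, and stage outputs
  are cached under a config hash.
- Macroframes align to the start of each condition's raster.
- Triad estimation requires ≥ 100 aligned bins; the BROJA solver demands
  marginal feasibility to 1e−8 and raises otherwise.

## Problem sizes used by the test suite and acceptance script

Estimator validation uses 10⁵-bin series (50 seeds for stochastic
closed-form checks); network recovery uses the 10-neuron, 2-parents-per-
target, transmission-0.6 benchmark at 2×10⁵ bins (10 seeds) with a
50-seed independent-raster null; the end-to-end acceptance run uses 30
neurons × 2×10⁵ bins per condition. These sizes are the package's chosen
desk-scale defaults; all estimators scale linearly in recording length.
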