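# Methods

`expertpool` aggregates *structured expert judgements* about binary
claims. Each participant `i` gives, for each claim `c`, a three-point
probability judgement: lower bound `L_ic`, best estimate `B_ic`, upper
bound `U_ic` with `0 <= L <= B <= U <= 1`, interpreted as the 5th, 50th
and 95th percentiles of the participant's subjective distribution. Two
elicitation rounds may be present (estimate, discuss, re-estimate); the
post-discussion round is the analysis round. The package pools the
panel into a per-claim group probability `p_hat_c` under 21 methods and
scores any prediction set against resolved outcomes with four measures.

## Average-type pools

* **ArMean** — arithmetic mean of the `B_ic`; the standard benchmark.
* **Median** — sample median (mean of the central pair for even counts;
  the standard convention, chosen where the literature is silent).
* **LOArMean** — `expit(mean(logit(B)))` after clipping estimates into
  `[eps, 1-eps]` (default `eps = 0.01`). Clipping keeps log odds finite
  when participants answer exactly 0 or 1; 0.01 matches the coarsest
  elicitation granularity the proxy weights consider.
* **BetaArMean** — `F_Beta(a,a)(ArMean)` with default `a = 7`.
  Averaged well-calibrated probabilities are under-confident; a
  symmetric Beta CDF fixes {0, 0.5, 1} and pushes the pool away from
  0.5 ("extremising"). The default is the published operating value for
  replication-forecasting panels; tuning `a` against known outcomes is
  deliberately out of scope.
* **DistribArMean** — each judgement becomes a minimally informative
  piecewise-uniform distribution on [0, 1] with mass 0.05 / 0.45 /
  0.45 / 0.05 on the segments between `0, L, B, U, 1`; the pool is the
  median of the pointwise-average CDF. Degenerate segments carry their
  mass as an atom at the shared point (tail mass stays inside [0, 1]
  because the probability scale is bounded), and the median is the
  left-continuous generalized inverse, which is well defined in the
  presence of atoms. The implementation is exact (piecewise-linear
  algebra on the union of breakpoints); tests compare it against a
  dense-grid oracle at 1e-4.

## Proxy-weighted linear pools

Thirteen pools of the form `p_hat_c = sum_i w~_ic B_ic`, with weights
normalised per claim over exactly that claim's assessors. The proxies
stand in for forecasting skill when no scored track record exists. The
unnormalised recipes are tabulated in `expertpool/weights.py`; the
descriptions they encode are fixed, and each formula is the simplest
one consistent with its description, isolated behind the variant switch
so alternatives can be swapped in. Design choices worth noting:

* `eps = 0.01` is added wherever a zero proxy would annihilate a weight
  or divide by zero; degenerate panels then collapse toward equal
  weights, and a panel where a proxy is constant across assessors
  reproduces ArMean exactly (property-tested).
* **ShiftWAgg** emphasises best-estimate movement over bound movement by
  weighting bound shifts at one quarter
  (`eps + |dB| + (|dL| + |dU|)/4`); the emphasis direction is given,
  the magnitude is our documented, configurable choice.
* **VarIndIntWAgg** uses `Var_c(d_i.) + eps` so a participant with one
  claim (variance undefined, taken as 0) gets the floor weight.
* **GranWAgg** calls an estimate granular when it is not a multiple of
  0.05 after rounding to 4 decimals (tolerance 1e-9), avoiding
  floating-point false granularity such as 0.65 stored as 0.65000...01.
* **KitchSinkWAgg** multiplies the three normalised component weights
  (individual-rescaled width, asymmetry, width variability) and
  renormalises, mirroring the multiplication rule of IndIntAsymWAgg.
* **EngWAgg** counts comment words per claim (not per session).

## Bayesian pools

**BayTriVar** models the log-odds best estimates with a normal
likelihood and three additive variance components:

    y_ic = logit(clip(B_ic)) ~ Normal(mu_c, sqrt(s_claim^2 + s_part^2 + v_ic))
    v_ic = ((logit(clip(U_ic)) - logit(clip(L_ic))) / (2 z))^2

with `z = 1.645` reading the elicited interval as a central 90%
interval, consistent with the 5%/95% percentile interpretation.
Priors: `mu_c ~ Normal(m_c, 1)` and `s_claim, s_part ~ Uniform(0, 2)`
(weakly informative on the log-odds scale). The pooled probability is
the posterior median of `expit(mu_c)`. `v_ic` is floored at 1e-6 for
degenerate intervals. **BayPRIORSAgg** is the same model with
`m_c = logit(clip(prior_c))` supplied by an external per-claim prior
model; with all priors at 0.5 it reproduces the uninformative fit
draw-for-draw at equal seeds.

The two shared scalars enter the likelihood only through
`s_claim^2 + s_part^2`: the total extra-interval variance is well
identified, while the split between the labels is exchangeable and
informed only by the prior. Recovery tests therefore use equal true
components, where the symmetric posterior recovers each within a few
percent. An alternative reading (one scale per claim and one per
participant) would be separately identifiable but was not adopted;
"generic" variability is modelled as one number per level.

Sampling is a self-contained Gibbs-within-Metropolis scheme: the
`mu_c` are conditionally conjugate and drawn exactly; each standard
deviation takes an adaptive reflected random-walk step (target
acceptance 0.44, adaptation during warmup only); and a
likelihood-invariant rotation move resamples the split of the total
variance at fixed sum, which removes the slow ridge mixing the
exchangeability would otherwise cause. Defaults: 4 chains, 1000 warmup,
1000 draws. Convergence is monitored with split-R̂ (warning threshold
1.05) and a crude autocorrelation ESS; results are flagged, never
discarded.

## Performance measures

* **Average Brier score** — default single-term `mean((p - x)^2)` in
  [0, 1]; the literal two-outcome sum (range [0, 2]) is available as
  `variant="two_term"` and equals exactly twice the single-term value.
  The single-term convention is the default because reported scores for
  panels of this kind sit in [0, 1].
* **AUC** — Mann–Whitney concordance with ties at 1/2, computed via
  scikit-learn and cross-checked in tests against a brute-force
  all-pairs count. Undefined (reported as NaN with a warning) when only
  one outcome class is present.
* **Calibration** — predictions are assigned to bins
  `k = clamp(round(10 p), 1, 10)` (half-up; the bin scheme has no zero
  bin, so p < 0.05 folds into Bin 1), and the score is
  `sum_k c_k (p_k - s_k)^2 / C`. Empty bins contribute zero.
* **Informativeness** — `sum_k c_k KL((p_k, 1-p_k) || (0.5, 0.5)) / C`,
  natural log by default (`base2` available); zero iff every prediction
  is binned at 0.5. Needs no outcomes.

`score_methods` aggregates a panel under each requested method and
scores the resulting "virtual experts" on a common table; methods whose
required inputs are missing (bounds, both rounds, metadata, external
priors) are skipped with a named reason, so a point-estimate-only panel
yields exactly the six point-estimate methods.

## Synthetic panels

The generator emulates the structure of real two-round three-point
elicitation exercises (tens of claims, 5–50 assessors per claim, base
rates around 0.2–0.5, post-discussion convergence): claim truth is
Bernoulli(base rate); a latent log-odds signal with sign matching the
truth (|N(1, 0.75)|, scenario-scalable) is observed by each expert with
noise sd `expert_skill_sd * exp(-0.75 z_i)` for standard-normal skill
`z_i`; interval half-widths are lognormal around 0.15 with optional
skill correlation; round 2 shrinks each expert toward the round-1 group
mean by an expert-specific rate in U(0, 0.5); and proxy metadata (quiz,
comprehension, comment words, reasons from a 20-code codebook with
skill-tied breadth) is drawn with a configurable skill correlation
`proxy_effect`. A second generator draws panels exactly from the
BayTriVar likelihood for recovery tests.

What passing tests on these panels do **not** show: real panels have
missing assessments, heaping on round numbers, correlated experts and
informative disagreement patterns the generator does not model; results
on synthetic panels demonstrate correctness of the machinery and the
direction of proxy effects under known conditions, not field
performance of any particular pool.

## Problem sizes used in the shipped checks

The shipped verification uses panels of 4–40 claims and 5–15
participants, 100–200 simulation replicates for the statistical
properties, 50 replicates (20 claims × 15 participants, 4 chains ×
500/500) for Bayesian recovery, and a 1e-4 dense-grid tolerance for the
distribution pool — sizes at which every Monte-Carlo bound used in the
tests is comfortably discriminating.

## Known limitations

* The weighted-pool formulas are faithful to their qualitative
  descriptions but are this package's own reconstructions; numerical
  equivalence with any other implementation should be established
  before cross-comparing published score tables.
* The calibration measure is unstable for small claim sets (few claims
  per occupied bin); the sorting of methods by average Brier is the
  robust comparison surface.
* The Bayesian variance split is reported as drawn but is exchangeable
  (see above); only the sum is a data-identified quantity.
* No optimisation of the Beta extremisation parameter and no
  outcome-based (performance) weighting are provided by design.
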