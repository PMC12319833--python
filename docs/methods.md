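# Methods

## Task model

A session holds 24 gambles.  Each gamble is an urn with `nr ≥ 1` risky balls
and `na ≥ 1` ambiguous balls, `2 ≤ nr + na ≤ 4`.  The package's default urn
set is the complete enumeration of admissible compositions — (1,1), (2,1),
(1,2), (3,1), (1,3), (2,2) — which is exactly six urns; any other set can be
supplied by config.  Winning colors are split 8/8/8 across the three colors,
making 8 risky and 16 ambiguous gambles; urns are cycled evenly within each
winning color (4 gambles per urn) and the presentation order is a seeded
permutation.  Every gamble is followed by three scenarios presenting each
color once in seeded random order (72 scenarios per session).  Scenarios are
independent hypothetical draws from the initially shown urn, so every
scenario's model quantities condition on the binomial prior, not on earlier
scenarios.  Trial timing (8 s urn, 4 s scenario, 10 s bid windows, jitters
10–16 s and 4–10 s) is carried as metadata and used only to place fNIRS
events; nothing is simulated in real time.

## Bayesian observer

Belief over the unknown ambiguous-color count `na1` starts at the binomial
prior `P(na1) = C(na, na1)/2^na`.  Draw probabilities marginalize over the
belief; ambiguous-color draws update it by Bayes' rule (likelihood
proportional to the drawn color's count), risky draws leave it unchanged.
Valuation is `EV = 10 × P(win)`; predicted value updating is the EV change.
Expectancy violation is `1 − P(drawn color)` under the predraw belief.

Belief-update magnitude is not uniquely pinned down by the source analyses;
we use the Kullback–Leibler divergence of posterior from prior in bits
(`belief_divergence`), with total-variation and L1 selectable.  All belief
masses are dyadic rationals, hence exact in float64; equality with the
enumeration oracle is asserted at 1e-12.

## Synthetic agents

Bids are generated as

    wts_pre  = clip round(EV_pre + premium·[ambiguous] + ε)
    wts_post = clip round(wts_pre + w_belief·ΔEV + s·w_ev·10·(1 − P(draw)) + ε)

with `s = +1` when the draw matches the winning color (weight `w_ev_pos`)
and `−1` otherwise (`w_ev_neg`), ε additive Gaussian noise before
round-half-to-even and clipping to 0–10, and independent per-bid timeouts.
A timed-out predraw bid voids the whole gamble (no updating reference); a
timed-out postdraw bid voids that scenario only.  The ×10 factor puts the
surprise regressor on the euro scale of the task so `w_ev` is commensurate
with `w_belief`.

Cohorts draw profiles per agent.  The belief and surprise weights load on a
shared latent "heuristic reliance" factor with tradeoff `t` (default 0.6),
giving corr(w_belief, w_ev) ≈ −t: agents leaning on the surprise heuristic
use the Bayesian route less.  Without this trade-off a higher surprise
weight partly *compensates* under-updating in normative trials and the
overall deviation score becomes nearly independent of `w_ev`, which would
contradict the empirical phenomenon the generator is meant to emulate
(surprise-driven participants deviating more).  Noise, ambiguity premium
and timeout rate are independent truncated normals.

Preset calibration (fixed once, not revisited): `old_like` uses
`w_belief = 0.35`, `w_ev_pos = 0.06`, `w_ev_neg = 0.10`, premium 1 €, noise
1.2 €, timeouts 0.5%, n = 46 — chosen so the five category medians land near
the published older-adult magnitudes (≈ +0.8, −1.0, +0.4, −0.5, −0.85 €)
with the negative-valence asymmetry; `young_like` uses `w_belief = 0.85`,
`w_ev ≈ 0`, no premium, n = 45.  The reasoning-score covariate (Raven-like
scale: mean 44.6, SD 5.8 old; 53.1, 4.2 young) is coupled by Gaussian copula
with rank correlation −0.4 (configurable) to the agent's *analytic* expected
|DEV| — the signed per-category combination of the weights evaluated at
session-average model quantities.  In the default old_like world bid noise
attenuates the realized covariate–|DEV| correlation to roughly −0.2; the
linkage tests therefore use a low-noise cohort where the generative
deviation dominates.

What a green test does **not** establish: agents are linear-additive with
integer rounding — no learning across gambles, no probability weighting, no
ambiguity-attitude parameters, no response-time process.  The generator is
a statistical stand-in for the published data structure, not a cognitive
model of participants.

## Behavioral statistics

- **ΔWTS aggregation** — per-participant × category means; the two
  non-normative mismatch categories can be merged before valence ×
  normativity analyses.  Empty cells stay missing with a warning.
- **Wilcoxon signed-rank** — zeros dropped, midranks for ties; exact null by
  the shift (convolution) algorithm for ≤ 25 nonzero differences (doubled
  ranks keep midranks integral), normal approximation with continuity
  correction beyond; two-sided p = 2·min(P≤, P≥) capped at 1; rank-biserial
  effect size (W+ − W−)/(W+ + W−).
- **DEV** — ΔWTS − predicted update, averaged within participant ×
  category; negative-valence categories sign-flipped on request so DEV > 0
  always means over-updating.  The overall |DEV| score is the mean absolute
  category-wise deviation.
- **Mixed models** — statsmodels MixedLM random-intercept fits (REML for
  reported models, ML refits inside model selection).  Wald F tests per
  term use residual denominator degrees of freedom; Satterthwaite
  approximation is not available in statsmodels, and result metadata records
  `df_method="residual"`.  Partial eta squared is F·df1/(F·df1 + df2).
  Post hoc contrasts are estimated-marginal-mean differences with Holm
  adjustment.  Singular fits (random-intercept variance ≈ 0) are flagged,
  estimates still returned.
- **Process regressions** — urn-wise ΔWTS within one category on belief
  updating (KL by default; the predicted EV change is selectable) and
  expectancy violation; constant predictors are dropped with a warning;
  optional backward elimination removes the least significant term by
  likelihood-ratio test (ML refits, α = 0.05) while respecting marginality,
  and reports the elimination path.
- **Covariate correlations** — Spearman; the semi-partial variant ranks all
  variables and residualizes the covariate (or channel beta) on the control
  ranks by least squares before correlating.

## fNIRS chain

- **Optics** — DPF(λ, A) = α + β·A^γ + δλ³ + ηλ² + ζλ with the published
  coefficient defaults (α 223.3, β 0.05624, γ 0.8493, δ −5.723e−7,
  η 0.001245, ζ −0.9025); PPF = DPF/60.  The modified Beer–Lambert system
  at 760/850 nm is solved per sample with shipped standard extinction
  coefficients (1/(cm·M)); the forward model is the simulator's inverse, and
  round-trip equality is tested at 1e-9.  A signal-quality mask (SNR ≥ 6.67,
  mean intensity 0.1–10) filters simulated raw intensities.
- **HRF** — difference of gamma densities with modes at 4 s (peak) and 16 s
  (undershoot), undershoot ratio 1/6, unit peak; all configurable.
- **Design** — one boxcar per named regressor convolved with the HRF at
  3.472 Hz; parametric modulators are centered and unit-scaled per modulator
  across the scenario events and multiplied into the scenario boxcar before
  convolution; nuisance regressors cover urn presentation and both bidding
  phases with response-time durations.  Constant modulators are dropped with
  a warning; rank deficiency triggers a condition-number warning.
- **AR-IRLS** — iterate {AR(p) model of the (robust-weighted) residuals,
  order by BIC via Yule–Walker with cap 4 → prewhiten y and X with the AR
  filter → Tukey bisquare IRLS (c = 4.685) on the whitened data} until the
  coefficient change < 1e-6 (max 50 iterations; non-convergence returns the
  last iterate, flagged).  Weighting the residuals before the AR step keeps
  artifact samples from corrupting the noise model.  On noise-free input the
  weights are exactly 1 and the fit equals OLS; under Gaussian noise the
  redescending weights perturb estimates slightly (so OLS equality holds
  statistically, not to machine precision).
- **Group level** — with one coefficient per subject per channel ×
  regressor, the random-intercept group-mean model reduces to the one-sample
  t test on subject betas; Benjamini–Hochberg FDR runs over the declared
  family (all supplied channels × regressors × chromophores).  Zero-spread
  edge cases are handled explicitly (identical betas: p = 0 for a nonzero
  mean, 1 otherwise).
- **Montage** — a schematic frontoparietal 10-10 layout (two 8 × 8 systems,
  16 sources, 16 detectors, 40 channels, 3 cm separation) shipped as
  packaged JSON; positions are bookkeeping labels, not reconstruction-grade
  coordinates.

## Brain–behavior stage

Channel betas of subjects are correlated (Spearman, optionally
semi-partial) with overall |DEV|, FDR over the selected-channel family.
The relative-influence index |β_ev|/(|β_ev| + |β_bu|) ∈ [0, 1] (1 = purely
surprise-driven) is scale- and sign-invariant and undefined at the origin.
For testability the full-study simulator couples designated channels'
modulator betas to the agents' generative weights (β = gain · weight +
noise), making the expected direction of every downstream correlation known
by construction.

## Numerical and design choices

- All randomness flows through numpy `SeedSequence` spawning from named
  stage seeds; identical configs reproduce outputs byte-for-byte.
- Bids use round-half-to-even before clipping; recovery analyses of the
  surprise weight are run with a predraw premium that keeps bids off the
  0-euro floor, because floor censoring otherwise steepens the fitted slope
  (a property of the bounded bid scale, not of the estimator).
- Wilcoxon exact/approximate switch at n = 25; mixed-model optimizer falls
  back from the default BFGS to Powell on singular intermediate Hessians.
- FDR q values satisfy q ≥ p by the step-up construction; a family of size
  one returns q = p.

## Known limitations

- No Satterthwaite/Kenward–Roger degrees of freedom; small-sample mixed-model
  p values are residual-df approximations.
- The AR-IRLS internals (order cap, Tukey constant, tolerances) are standard
  choices, configurable, but not a clone of any particular toolbox.
- HbR is supported as a data type throughout, but no HbR-specific scientific
  behavior is modeled.
- Motion artifacts, short-channel physiology, and image reconstruction are
  out of scope.
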