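# urnbid

Simulation and analysis of belief updating under reducible versus
irreducible uncertainty in an Ellsberg-style gamble-bidding task, together
with the model-based fNIRS GLM used to relate frontoparietal hemodynamics to
the underlying processes.

## The scientific problem

In the task, an urn holds 2–4 balls: `nr` balls of a known "risky" color and
`na` "ambiguous" balls whose split between two further colors is unknown.
A predetermined winning color makes each gamble *risky* (winning probability
known — irreducible uncertainty) or *ambiguous* (reducible uncertainty).
Participants state a willingness-to-sell (WTS) price in integer euros 0–10
for each gamble, observe three hypothetical one-ball draws (one per color),
and re-price after each draw; payment is resolved once with a
Becker–DeGroot–Marschak lottery.

A normative Bayesian observer treats each ambiguous ball as either color
with probability ½, giving a binomial prior over the unknown count `na1`:

    P_pre(na1) = C(na, na1) / 2^na
    P(risky)   = nr / (nr + na)
    P(a1)      = Σ_na1 P(na1) · na1 / (nr + na)

An ambiguous-color draw updates the belief by Bayes' rule (closed form: the
binomial shifts to `na − 1` trials); a risky-color draw is uninformative.
Valuation is `EV = 10 € × P(win)`; the model's predicted value update is
`EV_post − EV_pre`, which is nonzero only for ambiguous-color draws in
ambiguous gambles ("normative" trials).  Two further trial-wise quantities
dissociate the candidate processes:

- **expectancy violation** `1 − P(drawn color)` — surprise, defined on every
  draw whether informative or not;
- **belief updating** — divergence of the posterior from the prior over
  `na1` (Kullback–Leibler, in bits).

The package provides: session construction (`urnbid.task`), the Bayesian
observer (`urnbid.bayes`), a synthetic-agent generator whose bids mix the
normative route with a surprise heuristic (`urnbid.agents`), the behavioral
statistics — Wilcoxon signed-rank with rank-biserial effect sizes, deviation
scores, valence × normativity and age-group mixed models, process
regressions with backward selection, Spearman covariate correlations
(`urnbid.behavior`) — and a channel-level fNIRS chain: Beer–Lambert optics,
double-gamma HRF designs with parametric modulators, AR-prewhitened robust
(Tukey) GLM, group statistics with Benjamini–Hochberg FDR (`urnbid.fnirs`),
plus brain–behavior correlations and the relative-influence index
`|β_ev| / (|β_ev| + |β_bu|)` (`urnbid.brain_behavior`).

## Worked example

```python
from urnbid.task import UrnComposition, ColorScheme, Gamble
from urnbid.bayes import trial_quantities

scheme = ColorScheme()                       # blue risky, red/yellow ambiguous
urn = UrnComposition(nr=2, na=2)             # two risky + two ambiguous balls
gamble = Gamble(urn, scheme, scheme.ambiguous_color_1)   # ambiguous gamble
q = trial_quantities(gamble, scheme.ambiguous_color_1)   # winning color drawn
print(q)
```

prints `p_win_pre=0.25, p_win_post=0.375, ev_pre=2.5, ev_post=3.75,
predicted_update=1.25, expectancy_violation=0.75, belief_update=0.5`: before
any draw the winning ambiguous color is expected to fill a quarter of the
urn (EV 2.50 €); observing one such draw raises its probability to 0.375
(EV 3.75 €), so the model predicts a +1.25 € price adjustment.  The draw
itself was 75% surprising, and the belief over the urn's composition moved
by 0.5 bits.  Had the winning color been the risky one,
`winning_probability` would be exactly 0.5 (the printed 50%) and the
predicted update zero for every draw.

A cohort-level run:

```python
from urnbid.agents import CohortSpec, simulate_cohort
from urnbid import behavior

trials, cov = simulate_cohort(CohortSpec.preset("old_like", seed=1))
print(behavior.category_summaries(trials))
```

yields per-category medians of the per-participant mean ΔWTS (= post − pre
bid) with Wilcoxon tests against zero — for this seed: `+1.00 / −1.22 /
+0.25 / −0.50 / −0.81` for the categories (normative positive, normative
negative, non-normative positive, risky draws in ambiguous gambles,
ambiguous draws in risky gambles), all p < 0.01.  The positive medians in
the match categories and negative medians in all mismatch categories — with
*nonzero* updating in the three non-normative categories — is the
older-adult-like signature: value updating driven by expectancy violation
rather than by uncertainty reduction.

The full chain (agents → behavioral statistics → coupled channel simulation
→ AR-IRLS GLM → group FDR → brain–behavior report) runs from the command
line:

```sh
urnbid full-study --seed 7 --out results/run1
urnbid simulate-task --seed 1 --out plan.csv
urnbid simulate-cohort --preset old_like --seed 2 --out cohort/
urnbid analyze-behavior --trials cohort/trials.csv \
    --covariates cohort/covariates.csv --out behavior/
```

`full-study` writes tidy result tables, a JSON behavior report, and a
manifest with versions, stage seeds, and content hashes of every output.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the design-level acceptance quantity from scratch — it builds the
canonical urn, evaluates the belief module's closed-form prior, and reports
the winning probability (in percent) of a risky-winning-color gamble on the
two-risky/two-ambiguous urn — and writes it as JSON keyed by target id.

## Layout

```
src/urnbid/
  task.py            sessions, gambles, scenarios, trial categories, BDM
  bayes.py           belief states, posteriors, EVs, process quantities
  agents.py          agent profiles, cohort presets, bid simulation
  behavior.py        Wilcoxon, DEV, mixed models, process regressions
  fnirs/             optics, HRF, designs, simulation, AR-IRLS GLM, montage
  brain_behavior.py  beta-|DEV| correlations, relative influence
  study.py, cli.py, io.py   full-study pipeline, CLI, table/config I/O
docs/methods.md      model, assumptions, defaults, limitations
scripts/acceptance.py
tests/               unit, property and acceptance suites
```
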