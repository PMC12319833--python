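"""Synthetic bidding agents and cohort generation.

Agents mix two generative routes for value updating: the Bayesian-normative
route (weight ``w_belief`` on the model's predicted EV change) and a
heuristic expectancy-violation route (euros-per-surprise weights ``w_ev_pos``
for draws matching the winning color and ``w_ev_neg`` for mismatching draws).
Predraw bids are the model EV plus an optional ambiguity premium; additive
Gaussian noise precedes integer rounding and clipping to the 0-10 bid range.
Bids time out (go missing) with a small per-bid probability; a missing
predraw bid voids the whole gamble because the updating reference is lost,
while a missing postdraw bid voids only that scenario.

Cohort presets: ``old_like`` emulates an older-adult sample (nonzero
expectancy-violation weights with negative > positive, under-weighted belief
route, positive ambiguity premium), ``young_like`` a younger sample (belief
route dominant, expectancy-violation weights near zero, no premium).  Weight
defaults were calibrated once against the published category-median updating
magnitudes and then frozen.  A per-agent reasoning-score covariate is coupled
with configurable negative rank correlation to the agent's generative
deviation magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from urnbid.bayes import trial_quantities
from urnbid.task import (
    MAX_BID,
    SessionPlan,
    TrialCategory,
    UrnComposition,
    build_session,
    categorize_trial,
    default_urn_set,
)

#: Scale factor putting the expectancy-violation regressor on the euro scale
#: of the task (probability x max payoff), so w_ev is comparable to w_belief.
EV_SCALE = float(MAX_BID)


@dataclass(frozen=True)
class AgentProfile:
    """Generative weights mapping model quantities to simulated bids."""

    w_belief: float = 1.0
    w_ev_pos: float = 0.0
    w_ev_neg: float = 0.0
    ambiguity_premium: float = 0.0
    noise_sd: float = 0.0
    timeout_rate: float = 0.0
    covariate_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.timeout_rate <= 1.0:
            raise ValueError("timeout_rate must lie in [0, 1]")


#: Older-adult-like preset: both routes active, negative surprise weighted
#: more than positive, premium on ambiguous gambles, realistic noise and the
#: published ~0.5% timeout rate.  Raven-scale covariate mean/sd per the
#: published older sample.
OLD_LIKE = {
    "n_agents": 46,
    "label": "old_like",
    "means": AgentProfile(
        w_belief=0.35,
        w_ev_pos=0.06,
        w_ev_neg=0.10,
        ambiguity_premium=1.0,
        noise_sd=1.2,
        timeout_rate=0.005,
    ),
    "sds": {
        "w_belief": 0.10,
        "w_ev_pos": 0.05,
        "w_ev_neg": 0.08,
        "ambiguity_premium": 0.5,
        "noise_sd": 0.3,
        "timeout_rate": 0.0,
    },
    "covariate_mean": 44.61,
    "covariate_sd": 5.81,
}

#: Younger-adult-like preset: belief-driven updating, expectancy-violation
#: weights ~0 (no non-normative updating), no ambiguity premium.
YOUNG_LIKE = {
    "n_agents": 45,
    "label": "young_like",
    "means": AgentProfile(
        w_belief=0.85,
        w_ev_pos=0.0,
        w_ev_neg=0.02,
        ambiguity_premium=0.0,
        noise_sd=1.0,
        timeout_rate=0.005,
    ),
    "sds": {
        "w_belief": 0.15,
        "w_ev_pos": 0.02,
        "w_ev_neg": 0.03,
        "ambiguity_premium": 0.3,
        "noise_sd": 0.3,
        "timeout_rate": 0.0,
    },
    "covariate_mean": 53.07,
    "covariate_sd": 4.17,
}

_PRESETS = {"old_like": OLD_LIKE, "young_like": YOUNG_LIKE}


@dataclass
class CohortSpec:
    """Specification of a simulated cohort of bidding agents."""

    n_agents: int = 46
    label: str = "custom"
    means: AgentProfile = field(default_factory=AgentProfile)
    sds: dict = field(default_factory=dict)
    covariate_mean: float = 45.0
    covariate_sd: float = 6.0
    covariate_rho: float = -0.4
    strategy_tradeoff: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be at least 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "CohortSpec":
        try:
            base = dict(_PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
            ) from None
        base.update(overrides)
        return cls(seed=seed, **base)

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "label": self.label,
            "means": vars(self.means).copy(),
            "sds": dict(self.sds),
            "covariate_mean": self.covariate_mean,
            "covariate_sd": self.covariate_sd,
            "covariate_rho": self.covariate_rho,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        cfg = dict(cfg)
        means = cfg.pop("means", {})
        means.pop("covariate_score", None)
        return cls(means=AgentProfile(**means), **cfg)


def _round_bid(x: float) -> float:
    """Round-half-to-even, clip to the integer bid range 0-10."""
    return float(np.clip(np.round(x), 0, MAX_BID))


def simulate_session(
    profile: AgentProfile,
    plan: SessionPlan,
    seed: int = 0,
    participant: str | int = 0,
    belief_metric: str = "kl_bits",
) -> pd.DataFrame:
    """Simulate one agent's bids over a session plan.

    Returns the long-format trial table (one row per scenario) carrying the
    session fields, the model quantities, and the simulated bids.  A timed-out
    predraw bid voids all three of the gamble's scenarios.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g_idx, gamble in enumerate(plan.gambles):
        q_pre = trial_quantities(gamble, gamble.scheme.colors[0])  # ev_pre only
        premium = profile.ambiguity_premium if gamble.gamble_type == "ambiguous" else 0.0
        pre_noise = rng.normal(0.0, profile.noise_sd) if profile.noise_sd else 0.0
        pre_timeout = rng.random() < profile.timeout_rate
        wts_pre = np.nan if pre_timeout else _round_bid(q_pre.ev_pre + premium + pre_noise)

        for scen in plan.scenarios_for(g_idx):
            q = trial_quantities(gamble, scen.drawn_color, belief_metric=belief_metric)
            category = categorize_trial(gamble, scen.drawn_color)
            post_timeout = rng.random() < profile.timeout_rate
            post_noise = rng.normal(0.0, profile.noise_sd) if profile.noise_sd else 0.0
            if pre_timeout or post_timeout:
                wts_post = np.nan
            else:
                sign = 1.0 if scen.drawn_color == gamble.winning_color else -1.0
                w_ev = profile.w_ev_pos if sign > 0 else profile.w_ev_neg
                wts_post = _round_bid(
                    wts_pre
                    + profile.w_belief * q.predicted_update
                    + sign * w_ev * EV_SCALE * q.expectancy_violation
                    + post_noise
                )
            rows.append(
                {
                    "participant": participant,
                    "session_seed": plan.seed,
                    "gamble_index": g_idx,
                    "nr": gamble.urn.nr,
                    "na": gamble.urn.na,
                    "urn": f"{gamble.urn.nr}r{gamble.urn.na}a",
                    "winning_color": gamble.winning_color,
                    "gamble_type": gamble.gamble_type,
                    "position": scen.position,
                    "drawn_color": scen.drawn_color,
                    "category": category.value,
                    "p_win_pre": q.p_win_pre,
                    "p_win_post": q.p_win_post,
                    "ev_pre": q.ev_pre,
                    "ev_post": q.ev_post,
                    "predicted_update": q.predicted_update,
                    "expectancy_violation": q.expectancy_violation,
                    "belief_update": q.belief_update,
                    "wts_pre": wts_pre,
                    "wts_post": wts_post,
                    "delta_wts": wts_post - wts_pre,
                }
            )
    return pd.DataFrame(rows)


def _truncnorm_field(rng, mean, sd, low=-np.inf, high=np.inf):
    """Resampling-based truncated normal draw (cheap at these scales)."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def draw_profile(spec: CohortSpec, rng: np.random.Generator) -> AgentProfile:
    """Draw one agent profile from the cohort's field distributions.

    The belief and expectancy-violation weights share a latent
    heuristic-reliance factor: with tradeoff ``t`` (``strategy_tradeoff``),
    corr(w_belief, w_ev_*) ≈ −t, emulating that reliance on the surprise
    heuristic comes at the expense of the Bayesian route.  Noise, premium and
    timeout fields are independent truncated normals.
    """
    m = spec.means
    sds = spec.sds

    def s(name):
        return sds.get(name, 0.0)

    t = float(np.clip(spec.strategy_tradeoff, 0.0, 1.0))
    z = rng.normal()
    loading, resid = np.sqrt(t), np.sqrt(1.0 - t)

    def coupled(mean, sd, sign):
        return float(mean + sd * (sign * loading * z + resid * rng.normal()))

    return AgentProfile(
        w_belief=coupled(m.w_belief, s("w_belief"), -1.0),
        w_ev_pos=coupled(m.w_ev_pos, s("w_ev_pos"), +1.0),
        w_ev_neg=coupled(m.w_ev_neg, s("w_ev_neg"), +1.0),
        ambiguity_premium=_truncnorm_field(rng, m.ambiguity_premium, s("ambiguity_premium")),
        noise_sd=_truncnorm_field(rng, m.noise_sd, s("noise_sd"), low=0.0),
        timeout_rate=_truncnorm_field(rng, m.timeout_rate, s("timeout_rate"), 0.0, 1.0),
    )


#: Session-average model quantities per category over the default urn set:
#: (mean predicted update, mean expectancy violation, draw/winning match sign).
_CATEGORY_MOMENTS = {
    "normative_positive": (1.597, 0.750, +1.0),
    "normative_negative": (-1.597, 0.750, -1.0),
    "nonnormative_positive": (0.0, 0.500, +1.0),
    "nonnormative_negative_risky_draw_in_ambiguous": (0.0, 0.500, -1.0),
    "nonnormative_negative_ambiguous_draw_in_risky": (0.0, 0.750, -1.0),
}


def deviation_magnitude(profile: AgentProfile) -> float:
    """Analytic expectation of an agent's overall |DEV| (noise ignored).

    Per category the expected deviation of the bid update from the model
    prediction is ``(w_belief - 1) * predicted_update + s * w_ev * 10 *
    expectancy_violation`` at the session-average model quantities; the
    overall score averages the absolute category deviations, mirroring how
    |DEV| is computed from data.  Used to couple the reasoning covariate to
    generative behavior.
    """
    devs = []
    for pu, viol, sign in _CATEGORY_MOMENTS.values():
        w_ev = profile.w_ev_pos if sign > 0 else profile.w_ev_neg
        devs.append(abs((profile.w_belief - 1.0) * pu + sign * w_ev * EV_SCALE * viol))
    return float(np.mean(devs))


def simulate_cohort(
    spec: CohortSpec,
    urns: list[UrnComposition] | None = None,
    seed: int | None = None,
    belief_metric: str = "kl_bits",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort: per-agent seeded sessions plus a covariate table.

    Returns ``(trials, covariates)``.  ``trials`` is the concatenated
    long-format trial table; ``covariates`` has one row per agent with the
    reasoning-score covariate (negatively rank-coupled to the agent's
    generative deviation magnitude via a Gaussian copula) and the generative
    profile fields for reference.
    """
    urns = urns if urns is not None else default_urn_set()
    root = np.random.SeedSequence(seed if seed is not None else spec.seed)
    profile_seq, session_seq, cov_seq = root.spawn(3)
    prof_rng = np.random.default_rng(profile_seq)
    cov_rng = np.random.default_rng(cov_seq)
    session_seeds = [int(s.generate_state(1)[0] % 2**31) for s in session_seq.spawn(spec.n_agents)]

    profiles = [draw_profile(spec, prof_rng) for _ in range(spec.n_agents)]

    # Gaussian-copula coupling of the covariate to deviation magnitude.
    dev = np.array([deviation_magnitude(p) for p in profiles])
    dev_rank = (pd.Series(dev).rank() - 0.5) / len(dev)
    from scipy.stats import norm

    z_dev = norm.ppf(dev_rank)
    rho = spec.covariate_rho
    z_cov = rho * z_dev + np.sqrt(max(0.0, 1 - rho**2)) * cov_rng.normal(
        size=spec.n_agents
    )
    covariate = spec.covariate_mean + spec.covariate_sd * z_cov

    trials = []
    cov_rows = []
    for i, (profile, sseed) in enumerate(zip(profiles, session_seeds)):
        pid = f"{spec.label}_{i:03d}"
        profile = replace(profile, covariate_score=float(covariate[i]))
        plan = build_session(urns=urns, seed=sseed)
        df = simulate_session(
            profile, plan, seed=sseed, participant=pid, belief_metric=belief_metric
        )
        df["age_group"] = spec.label
        trials.append(df)
        cov_rows.append(
            {
                "participant": pid,
                "age_group": spec.label,
                "covariate_score": float(covariate[i]),
                "deviation_magnitude": float(dev[i]),
                **{k: getattr(profile, k) for k in (
                    "w_belief", "w_ev_pos", "w_ev_neg",
                    "ambiguity_premium", "noise_sd", "timeout_rate",
                )},
            }
        )
    return pd.concat(trials, ignore_index=True), pd.DataFrame(cov_rows)
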