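"""Normative Bayesian observer for the urn-gamble task.

The observer knows an urn's counts of risky (``nr``) and ambiguous (``na``)
balls but not how the ambiguous balls split between the two ambiguous colors
(``na1`` of color a1, ``na2 = na - na1`` of color a2).  Each ambiguous ball is
assumed to be either color with probability 1/2 independently, so the prior
over ``na1`` is binomial:

    P_pre(na1) = C(na, na1) / 2**na.

Draw probabilities follow by marginalization — ``P(risky) = nr / (nr + na)``
and ``P(a1) = sum_na1 P(na1) * na1 / (nr + na)`` — and a draw of an ambiguous
color updates the belief by Bayes' rule, which in closed form shifts the
binomial to ``na - 1`` trials:

    a1 drawn:  P_post(na1) = C(na-1, na1-1) / 2**(na-1)
    a2 drawn:  P_post(na1) = C(na-1, na1)   / 2**(na-1)

while a risky-color draw leaves the belief unchanged.  Valuation multiplies
the winning color's probability by the 10-euro payoff, ``EV = 10 * Pw``; the
model's predicted value update is ``EV_post - EV_pre``.  Expectancy violation
is the surprise of the draw itself, ``1 - P(drawn color)`` under the predraw
belief.  Belief-update magnitude is the divergence of the posterior from the
prior over ``na1`` (Kullback–Leibler in bits by default).

All prior/posterior masses are dyadic rationals and hence exact in binary
floating point; downstream draw probabilities add only a division by
``nr + na``, so closed forms agree with the enumeration oracle to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal

import numpy as np

from urnbid.task import Gamble, MAX_BID, UrnComposition

_TOL = 1e-12

ColorRole = Literal["risky", "a1", "a2"]
ROLES: tuple[ColorRole, ColorRole, ColorRole] = ("risky", "a1", "a2")


class DegenerateEvidenceError(ValueError):
    """Raised when conditioning on a draw that has probability zero."""


@dataclass(frozen=True)
class BeliefState:
    """Probability distribution over ``na1``, the count of ambiguous color a1."""

    urn: UrnComposition
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != self.urn.na + 1:
            raise ValueError(
                f"belief needs {self.urn.na + 1} probabilities, got {len(self.probs)}"
            )
        arr = np.asarray(self.probs)
        if (arr < -_TOL).any() or abs(arr.sum() - 1.0) > _TOL:
            raise ValueError("belief probabilities must be non-negative and sum to 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.urn.na + 1)

    def expected_na1(self) -> float:
        return float(np.dot(self.support, self.probs))


@dataclass(frozen=True)
class ModelTrialQuantities:
    """Model quantities for one scenario draw.

    ``predicted_update`` is in euros (EV_post - EV_pre; zero by construction
    in all non-normative categories), ``expectancy_violation`` is a
    probability (1 - P(drawn color) under the predraw belief) and
    ``belief_update`` is the prior-to-posterior divergence (bits for KL).
    """

    p_win_pre: float
    p_win_post: float
    ev_pre: float
    ev_post: float
    predicted_update: float
    expectancy_violation: float
    belief_update: float


def prior_belief(urn: UrnComposition) -> BeliefState:
    """Binomial prior over ``na1``: each ambiguous ball is a1 w.p. 1/2."""
    na = urn.na
    probs = tuple(comb(na, k) / 2**na for k in range(na + 1))
    return BeliefState(urn=urn, probs=probs)


def color_draw_probability(belief: BeliefState, color: ColorRole) -> float:
    """Probability of drawing a ball of the given scheme role."""
    urn = belief.urn
    if color == "risky":
        return urn.nr / urn.n_total
    if color == "a1":
        return belief.expected_na1() / urn.n_total
    if color == "a2":
        return (urn.na - belief.expected_na1()) / urn.n_total
    raise ValueError(f"unknown color role {color!r}")


def posterior_belief(belief: BeliefState, drawn: ColorRole) -> BeliefState:
    """Bayes-rule update of the belief after observing one draw.

    The likelihood of drawing a1 given ``na1`` is proportional to ``na1``
    (and to ``na - na1`` for a2); a risky draw is equally likely under every
    ``na1`` and leaves the belief unchanged.
    """
    if drawn == "risky":
        return belief
    if drawn not in ("a1", "a2"):
        raise ValueError(f"unknown color role {drawn!r}")
    support = belief.support
    likelihood = support if drawn == "a1" else belief.urn.na - support
    unnorm = np.asarray(belief.probs) * likelihood
    total = unnorm.sum()
    if total <= _TOL:
        raise DegenerateEvidenceError(
            f"draw {drawn!r} has probability zero under the current belief"
        )
    return BeliefState(urn=belief.urn, probs=tuple(unnorm / total))


def winning_probability(belief: BeliefState, winning: ColorRole) -> float:
    """Probability that a future draw shows the winning color."""
    return color_draw_probability(belief, winning)


def expected_value(belief: BeliefState, winning: ColorRole) -> float:
    """Expected gamble value in euros: payoff times winning probability."""
    return MAX_BID * winning_probability(belief, winning)


def belief_divergence(
    prior: BeliefState,
    posterior: BeliefState,
    metric: Literal["kl_bits", "total_variation", "l1"] = "kl_bits",
) -> float:
    """Magnitude of the belief change from prior to posterior.

    ``kl_bits`` (default) is the Kullback–Leibler divergence of the posterior
    from the prior in bits; ``total_variation`` and ``l1`` are swappable
    alternatives.  Zero iff the belief did not change (risky-color draws).
    """
    p = np.asarray(posterior.probs)
    q = np.asarray(prior.probs)
    if metric == "kl_bits":
        mask = p > _TOL
        return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))
    if metric == "total_variation":
        return float(0.5 * np.abs(p - q).sum())
    if metric == "l1":
        return float(np.abs(p - q).sum())
    raise ValueError(f"unknown belief metric {metric!r}")


def trial_quantities(
    gamble: Gamble,
    drawn_color: str,
    prior: BeliefState | None = None,
    belief_metric: Literal["kl_bits", "total_variation", "l1"] = "kl_bits",
) -> ModelTrialQuantities:
    """All model quantities for one scenario of a gamble.

    Scenarios are independent hypothetical draws from the initially presented
    urn, so the predraw belief defaults to the binomial prior; pass ``prior``
    to evaluate counterfactual belief states.
    """
    prior = prior or prior_belief(gamble.urn)
    win_role = gamble.winning_role
    drawn_role = gamble.scheme.role(drawn_color)

    p_win_pre = winning_probability(prior, win_role)
    p_drawn = color_draw_probability(prior, drawn_role)
    posterior = posterior_belief(prior, drawn_role)
    p_win_post = winning_probability(posterior, win_role)

    ev_pre = MAX_BID * p_win_pre
    ev_post = MAX_BID * p_win_post
    return ModelTrialQuantities(
        p_win_pre=p_win_pre,
        p_win_post=p_win_post,
        ev_pre=ev_pre,
        ev_post=ev_post,
        predicted_update=ev_post - ev_pre,
        expectancy_violation=1.0 - p_drawn,
        belief_update=belief_divergence(prior, posterior, metric=belief_metric),
    )
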