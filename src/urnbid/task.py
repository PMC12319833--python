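"""Construction of gamble-bidding sessions.

A session presents 24 gambles.  Each gamble is an urn of two to four balls in
three colors: one "risky" color with a known count and two "ambiguous" colors
whose joint count is known but whose split is not.  A predetermined winning
color makes the gamble *risky* (winning probability known) when it is the
risky color and *ambiguous* otherwise.  Every gamble is followed by three
hypothetical one-ball draws ("scenarios"), one per color in seeded random
order, and the participant bids a willingness-to-sell (WTS) price in integer
euros 0–10 before the draws and after each draw.  Payment is resolved once at
the end through a Becker–DeGroot–Marschak (BDM) lottery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three ball colors used in the task.
COLORS: tuple[str, str, str] = ("red", "blue", "yellow")

#: Number of gambles in a full session.
N_GAMBLES = 24

#: Scenario draws per gamble (one per color).
N_SCENARIOS_PER_GAMBLE = 3

#: Maximum bid / gamble payoff in euros.
MAX_BID = 10

#: Timing metadata (seconds) carried for fNIRS event-table construction; the
#: task is not simulated in real time.
TIMING = {
    "urn_duration": 8.0,
    "bid_window": 10.0,
    "scenario_duration": 4.0,
    "pre_scenario_jitter": (10.0, 16.0),
    "pre_bid_jitter": (4.0, 10.0),
    "inter_scenario_jitter": (10.0, 16.0),
}


class TaskDesignError(ValueError):
    """Raised when a task component violates the paradigm's constraints."""


class TrialCategory(str, Enum):
    """Trial category from the (gamble type, drawn color, winning color) grid.

    Normative categories are those where the draw changes the Bayesian
    winning probability (ambiguous-color draws in ambiguous gambles);
    everywhere else zero updating is normatively expected, and any observed
    updating is non-normative, signed by whether the draw matches the
    winning color.
    """

    NORMATIVE_POSITIVE = "normative_positive"
    NORMATIVE_NEGATIVE = "normative_negative"
    NONNORMATIVE_POSITIVE = "nonnormative_positive"
    NONNORMATIVE_NEGATIVE_RISKY_IN_AMBIGUOUS = (
        "nonnormative_negative_risky_draw_in_ambiguous"
    )
    NONNORMATIVE_NEGATIVE_AMBIGUOUS_IN_RISKY = (
        "nonnormative_negative_ambiguous_draw_in_risky"
    )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_normative(self) -> bool:
        return self in (self.NORMATIVE_POSITIVE, self.NORMATIVE_NEGATIVE)

    @property
    def is_positive(self) -> bool:
        """True when the drawn color matches the winning color."""
        return self in (self.NORMATIVE_POSITIVE, self.NONNORMATIVE_POSITIVE)


@dataclass(frozen=True)
class ColorScheme:
    """Assignment of the three ball colors to the risky/ambiguous roles."""

    risky_color: str = "blue"
    ambiguous_color_1: str = "red"
    ambiguous_color_2: str = "yellow"

    def __post_init__(self) -> None:
        labels = (self.risky_color, self.ambiguous_color_1, self.ambiguous_color_2)
        if sorted(labels) != sorted(COLORS):
            raise TaskDesignError(
                f"color scheme must be a permutation of {COLORS}, got {labels}"
            )

    @property
    def colors(self) -> tuple[str, str, str]:
        return (self.risky_color, self.ambiguous_color_1, self.ambiguous_color_2)

    def role(self, color: str) -> str:
        """Map an actual color label to its scheme role ``risky``/``a1``/``a2``."""
        if color == self.risky_color:
            return "risky"
        if color == self.ambiguous_color_1:
            return "a1"
        if color == self.ambiguous_color_2:
            return "a2"
        raise TaskDesignError(f"unknown color {color!r} for scheme {self}")

    def color(self, role: str) -> str:
        """Inverse of :meth:`role`."""
        mapping = {
            "risky": self.risky_color,
            "a1": self.ambiguous_color_1,
            "a2": self.ambiguous_color_2,
        }
        try:
            return mapping[role]
        except KeyError:
            raise TaskDesignError(f"unknown role {role!r}") from None

    @classmethod
    def random(cls, rng: np.random.Generator) -> "ColorScheme":
        risky, a1, a2 = rng.permutation(COLORS)
        return cls(risky, a1, a2)


@dataclass(frozen=True)
class UrnComposition:
    """Counts of risky (``nr``) and ambiguous (``na``) balls in an urn."""

    nr: int
    na: int

    def __post_init__(self) -> None:
        if self.nr < 1 or self.na < 1:
            raise TaskDesignError(
                f"urn needs at least one ball of each type, got nr={self.nr}, na={self.na}"
            )
        if not 2 <= self.nr + self.na <= 4:
            raise TaskDesignError(
                f"urn must hold 2-4 balls, got {self.nr + self.na}"
            )

    @property
    def n_total(self) -> int:
        return self.nr + self.na


@dataclass(frozen=True)
class Gamble:
    """One urn plus its designated winning color.

    The gamble is *risky* iff the winning color is the scheme's risky color
    (winning probability then fully known from the urn), otherwise
    *ambiguous*.
    """

    urn: UrnComposition
    scheme: ColorScheme
    winning_color: str

    def __post_init__(self) -> None:
        if self.winning_color not in self.scheme.colors:
            raise TaskDesignError(
                f"winning color {self.winning_color!r} not in scheme {self.scheme}"
            )

    @property
    def gamble_type(self) -> str:
        return "risky" if self.winning_color == self.scheme.risky_color else "ambiguous"

    @property
    def winning_role(self) -> str:
        return self.scheme.role(self.winning_color)


@dataclass(frozen=True)
class Scenario:
    """One hypothetical draw from a gamble's urn."""

    gamble_index: int
    position: int  # 1..3 within the gamble
    drawn_color: str

    def __post_init__(self) -> None:
        if self.position not in (1, 2, 3):
            raise TaskDesignError(f"scenario position must be 1-3, got {self.position}")


@dataclass
class SessionPlan:
    """A full 24-gamble, 72-scenario session."""

    gambles: list[Gamble]
    scenarios: list[Scenario]
    seed: int
    scheme: ColorScheme = field(default_factory=ColorScheme)

    def __post_init__(self) -> None:
        if len(self.gambles) != N_GAMBLES:
            raise TaskDesignError(
                f"session must hold {N_GAMBLES} gambles, got {len(self.gambles)}"
            )
        if len(self.scenarios) != N_GAMBLES * N_SCENARIOS_PER_GAMBLE:
            raise TaskDesignError(
                f"session must hold {N_GAMBLES * N_SCENARIOS_PER_GAMBLE} scenarios"
            )
        for g in range(N_GAMBLES):
            colors = {s.drawn_color for s in self.scenarios_for(g)}
            if colors != set(COLORS):
                raise TaskDesignError(
                    f"gamble {g}: scenario draws must cover all three colors, got {colors}"
                )

    def scenarios_for(self, gamble_index: int) -> list[Scenario]:
        return [s for s in self.scenarios if s.gamble_index == gamble_index]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per scenario with gamble and category columns."""
        rows = []
        for s in self.scenarios:
            g = self.gambles[s.gamble_index]
            rows.append(
                {
                    "session_seed": self.seed,
                    "gamble_index": s.gamble_index,
                    "nr": g.urn.nr,
                    "na": g.urn.na,
                    "winning_color": g.winning_color,
                    "gamble_type": g.gamble_type,
                    "position": s.position,
                    "drawn_color": s.drawn_color,
                    "category": categorize_trial(g, s.drawn_color).value,
                }
            )
        return pd.DataFrame(rows)

    def to_config(self) -> dict:
        """Round-trippable structured representation (JSON/YAML friendly)."""
        return {
            "seed": self.seed,
            "scheme": {
                "risky_color": self.scheme.risky_color,
                "ambiguous_color_1": self.scheme.ambiguous_color_1,
                "ambiguous_color_2": self.scheme.ambiguous_color_2,
            },
            "gambles": [
                {
                    "nr": g.urn.nr,
                    "na": g.urn.na,
                    "winning_color": g.winning_color,
                }
                for g in self.gambles
            ],
            "scenarios": [
                {
                    "gamble_index": s.gamble_index,
                    "position": s.position,
                    "drawn_color": s.drawn_color,
                }
                for s in self.scenarios
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "SessionPlan":
        scheme = ColorScheme(**cfg["scheme"])
        gambles = [
            Gamble(UrnComposition(g["nr"], g["na"]), scheme, g["winning_color"])
            for g in cfg["gambles"]
        ]
        scenarios = [Scenario(**s) for s in cfg["scenarios"]]
        return cls(gambles=gambles, scenarios=scenarios, seed=cfg["seed"], scheme=scheme)


def default_urn_set() -> list[UrnComposition]:
    """The six canonical urn compositions.

    With 2–4 balls and at least one ball of each type there are exactly six
    admissible compositions; the default set is that complete enumeration
    (it includes the canonical two-risky/two-ambiguous urn).  Override via
    config where a different set is wanted.
    """
    return [
        UrnComposition(1, 1),
        UrnComposition(2, 1),
        UrnComposition(1, 2),
        UrnComposition(3, 1),
        UrnComposition(1, 3),
        UrnComposition(2, 2),
    ]


def validate_urn_set(urns: Sequence[UrnComposition]) -> list[UrnComposition]:
    """Validate a (possibly overriding) urn set, warning on unusual sizes."""
    urns = list(urns)
    if not urns:
        raise TaskDesignError("urn set must be non-empty")
    if len(set(urns)) != len(urns):
        raise TaskDesignError("urn set contains duplicates")
    if len(urns) != 6:
        logger.warning(
            "urn set has %d compositions (canonical design uses 6); using it verbatim",
            len(urns),
        )
    return urns


def build_session(
    urns: Iterable[UrnComposition] | None = None,
    seed: int = 0,
    scheme: ColorScheme | None = None,
) -> SessionPlan:
    """Build a seeded 24-gamble session.

    Winning colors are split 8/8/8 across the three colors (hence 8 risky and
    16 ambiguous gambles), urns are cycled as evenly as possible within each
    winning color, the gamble order is a seeded permutation, and each
    gamble's three scenarios present the three colors in seeded random order.
    Deterministic for a fixed seed.
    """
    urns = validate_urn_set(list(urns) if urns is not None else default_urn_set())
    scheme = scheme or ColorScheme()
    rng = np.random.default_rng(seed)

    per_color = N_GAMBLES // len(COLORS)
    slots: list[Gamble] = []
    urn_cycle = 0
    for color in scheme.colors:
        for _ in range(per_color):
            slots.append(Gamble(urns[urn_cycle % len(urns)], scheme, color))
            urn_cycle += 1
    order = rng.permutation(N_GAMBLES)
    gambles = [slots[i] for i in order]

    scenarios: list[Scenario] = []
    for g_idx in range(N_GAMBLES):
        draw_order = rng.permutation(COLORS)
        for pos, color in enumerate(draw_order, start=1):
            scenarios.append(Scenario(g_idx, pos, str(color)))

    return SessionPlan(gambles=gambles, scenarios=scenarios, seed=seed, scheme=scheme)


def categorize_trial(gamble: Gamble, drawn_color: str) -> TrialCategory:
    """Classify a scenario by gamble type and draw/winning-color relation."""
    if drawn_color not in gamble.scheme.colors:
        raise TaskDesignError(
            f"drawn color {drawn_color!r} not in scheme {gamble.scheme}"
        )
    drawn_role = gamble.scheme.role(drawn_color)
    if gamble.gamble_type == "ambiguous":
        if drawn_color == gamble.winning_color:
            return TrialCategory.NORMATIVE_POSITIVE
        if drawn_role == "risky":
            return TrialCategory.NONNORMATIVE_NEGATIVE_RISKY_IN_AMBIGUOUS
        return TrialCategory.NORMATIVE_NEGATIVE
    # risky gamble
    if drawn_role == "risky":
        return TrialCategory.NONNORMATIVE_POSITIVE
    return TrialCategory.NONNORMATIVE_NEGATIVE_AMBIGUOUS_IN_RISKY


def resolve_bdm(
    wts: int,
    lottery_number: int | None = None,
    win_draw: bool = False,
    seed: int | None = None,
) -> int:
    """Resolve the BDM lottery for one selected scenario bid.

    If the bid is lower than the random lottery number, the seller receives
    the lottery number as the bonus.  Otherwise the gamble is played and pays
    the maximum (10 euros) on a winning draw, zero otherwise.  When
    ``lottery_number`` is None it is drawn uniformly from 0–10 using ``seed``.
    """
    if not 0 <= wts <= MAX_BID:
        raise TaskDesignError(f"bid must be an integer 0-{MAX_BID}, got {wts}")
    if lottery_number is None:
        lottery_number = int(np.random.default_rng(seed).integers(0, MAX_BID + 1))
    if not 0 <= lottery_number <= MAX_BID:
        raise TaskDesignError(
            f"lottery number must be 0-{MAX_BID}, got {lottery_number}"
        )
    if wts < lottery_number:
        return lottery_number
    return MAX_BID if win_draw else 0
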