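"""Event tables and HRF design matrices with parametric modulators.

The design follows the conventional event-related construction: each named
regressor contributes a boxcar at its event onsets/durations convolved with
the canonical HRF; parametric modulators are centered and unit-scaled per
modulator, multiplied into the scenario boxcar *before* convolution, and
enter as separate columns.  Nuisance regressors (urn presentation, predraw
and postdraw bid entry) are built the same way from their own event rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from urnbid.fnirs.hrf import double_gamma_hrf
from urnbid.task import TIMING, SessionPlan

logger = logging.getLogger(__name__)

#: Event columns that are not parametric modulators.
_CORE_COLUMNS = ("onset", "duration", "regressor")

#: Canonical regressor names for a task session.
SCENARIO = "scenario"
NUISANCE = ("urn", "bid_pre", "bid_post")

#: Modulator column names attached to scenario events.
MODULATORS = ("belief_update", "value_update", "expectancy_violation")


@dataclass
class EventTable:
    """Event rows (onset s, duration s, regressor name, modulator values)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        if (df["duration"] <= 0).any():
            raise ValueError("event durations must be positive")
        df.sort_values("onset", kind="stable", inplace=True, ignore_index=True)

    @property
    def modulator_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _CORE_COLUMNS]

    @property
    def end_time(self) -> float:
        return float((self.frame["onset"] + self.frame["duration"]).max())


def _boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_samples: int,
    fs: float,
) -> np.ndarray:
    t = np.arange(n_samples) / fs
    out = np.zeros(n_samples)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        out[(t >= onset) & (t < onset + dur)] += amp
    return out


def build_design(
    events: EventTable | pd.DataFrame,
    duration_s: float,
    sampling_rate: float,
    hrf: np.ndarray | None = None,
    modulated_regressor: str = SCENARIO,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Build the HRF-convolved design matrix for one recording.

    One column per named regressor; one column per modulator (centered and
    unit-scaled across the modulated regressor's events, multiplied into its
    boxcar before convolution).  All-zero or constant modulators are dropped
    with a warning; a rank-deficient design triggers a warning reporting the
    condition number.
    """
    if isinstance(events, pd.DataFrame):
        events = EventTable(events.copy())
    df = events.frame
    if events.end_time > duration_s + 1e-9:
        raise ValueError("events extend beyond the series duration")
    n = int(round(duration_s * sampling_rate))
    kernel = hrf if hrf is not None else double_gamma_hrf(sampling_rate)

    columns: dict[str, np.ndarray] = {}
    names = list(dict.fromkeys(df["regressor"]))
    for name in names:
        sub = df[df["regressor"] == name]
        box = _boxcar(
            sub["onset"].to_numpy(), sub["duration"].to_numpy(),
            np.ones(len(sub)), n, sampling_rate,
        )
        columns[name] = np.convolve(box, kernel)[:n]

    mod_rows = df[df["regressor"] == modulated_regressor]
    for mod in events.modulator_names:
        vals = mod_rows[mod].to_numpy(dtype=float)
        if len(vals) == 0 or np.isnan(vals).all():
            continue
        vals = np.nan_to_num(vals, nan=float(np.nanmean(vals)))
        sd = vals.std()
        if sd == 0:
            logger.warning("modulator %r constant/zero; column dropped", mod)
            continue
        scaled = (vals - vals.mean()) / sd
        box = _boxcar(
            mod_rows["onset"].to_numpy(), mod_rows["duration"].to_numpy(),
            scaled, n, sampling_rate,
        )
        columns[f"{modulated_regressor}:{mod}"] = np.convolve(box, kernel)[:n]

    X = pd.DataFrame(columns)
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    cond = np.linalg.cond(X.to_numpy())
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        logger.warning(
            "design matrix is rank deficient (rank %d < %d columns, cond %.3g)",
            rank, X.shape[1], cond,
        )
    return X


def session_events(
    plan: SessionPlan,
    trials: pd.DataFrame | None = None,
    seed: int = 0,
    mean_response_s: float = 2.5,
) -> EventTable:
    """Event table for one session, with seeded jitters per the task timing.

    Scenario events carry the model-quantity modulators (belief updating and
    expectancy violation); when a simulated trial table for this session is
    supplied, the value-updating modulator (ΔWTS) is attached as well and the
    bid-entry durations use plausible seeded response times.
    """
    rng = np.random.default_rng(seed)
    from urnbid.bayes import trial_quantities  # local import to avoid cycle

    lookup = None
    if trials is not None:
        lookup = trials.set_index(["gamble_index", "position"])

    def rt() -> float:
        return float(np.clip(rng.normal(mean_response_s, 0.8), 0.8, TIMING["bid_window"]))

    rows = []
    t = 30.0  # recording starts 30 s before the task
    for g_idx, gamble in enumerate(plan.gambles):
        rows.append({"onset": t, "duration": TIMING["urn_duration"], "regressor": "urn"})
        t += TIMING["urn_duration"]
        dur = rt()
        rows.append({"onset": t, "duration": dur, "regressor": "bid_pre"})
        t += TIMING["bid_window"]
        for scen in plan.scenarios_for(g_idx):
            t += rng.uniform(*TIMING["pre_scenario_jitter"])
            q = trial_quantities(gamble, scen.drawn_color)
            row = {
                "onset": t,
                "duration": TIMING["scenario_duration"],
                "regressor": SCENARIO,
                "belief_update": q.belief_update,
                "expectancy_violation": q.expectancy_violation,
                "value_update": np.nan,
            }
            if lookup is not None:
                try:
                    row["value_update"] = float(
                        lookup.loc[(g_idx, scen.position), "delta_wts"]
                    )
                except KeyError:
                    pass
            rows.append(row)
            t += TIMING["scenario_duration"]
            t += rng.uniform(*TIMING["pre_bid_jitter"])
            rows.append({"onset": t, "duration": rt(), "regressor": "bid_post"})
            t += TIMING["bid_window"]
    frame = pd.DataFrame(rows)
    if lookup is None or frame["value_update"].isna().all():
        frame = frame.drop(columns=["value_update"])
    return EventTable(frame)
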