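"""Brain–behavior linkage: channel betas versus behavioral deviation.

Relates subject-level channel GLM coefficients to the behavioral deviation
score |DEV| via Spearman (optionally semi-partial) correlations with FDR over
the selected-channel family, and quantifies, per subject or channel, the
relative influence of expectancy violation versus belief updating as

    index = |beta_ev| / (|beta_ev| + |beta_bu|),

which lies in [0, 1], with 1 meaning purely expectancy-violation-driven
activity.  A configurable coupling simulator generates subject channel betas
proportional to the agents' generative weights, making the linkage stage
testable by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

from urnbid.behavior import UndefinedTestError, correlate_covariate


def relative_influence(beta_ev: float, beta_bu: float) -> float:
    """Relative influence of expectancy violation over belief updating."""
    denom = abs(beta_ev) + abs(beta_bu)
    if denom == 0:
        raise UndefinedTestError("relative influence undefined when both betas are 0")
    return abs(beta_ev) / denom


def correlate_beta_dev(
    channel_betas: pd.DataFrame,
    abs_dev: pd.Series,
    controls: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of per-participant channel betas with |DEV|.

    ``channel_betas`` is wide (index participant, one column per selected
    channel); ``abs_dev`` is indexed by participant.  With ``controls`` the
    betas are rank-residualized on the control variables before correlating
    (semi-partial variant).  Returns one row per channel with rho, p and
    Benjamini–Hochberg q over the selected-channel family.
    """
    common = channel_betas.index.intersection(abs_dev.index)
    if len(common) < 5:
        raise UndefinedTestError("need at least 5 paired participants")
    betas = channel_betas.loc[common]
    dev = abs_dev.loc[common]
    ctrl = controls.loc[common] if controls is not None else None

    rows = []
    for ch in betas.columns:
        b = betas[ch].to_numpy(dtype=float)
        # semi-partial: residualize the channel betas (not |DEV|) on controls
        rho, p = correlate_covariate(
            dev.to_numpy(dtype=float), b,
            controls=ctrl.to_numpy(dtype=float) if ctrl is not None else None,
        )
        rows.append({"channel": ch, "rho": rho, "pvalue": p, "n": len(common)})
    out = pd.DataFrame(rows)
    if len(out) > 1:
        reject, q, _, _ = multipletests(out["pvalue"], alpha=alpha, method="fdr_bh")
        out["q"] = q
        out["significant"] = reject
    else:
        out["q"] = out["pvalue"]
        out["significant"] = out["q"] < alpha
    return out


def couple_channel_betas(
    covariates: pd.DataFrame,
    channels: list[str],
    ev_channels: list[str] | tuple[str, ...] = (),
    bu_channels: list[str] | tuple[str, ...] = (),
    gain: float = 10.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate subject-level channel betas coupled to agent weights.

    For channels in ``ev_channels`` the subject beta is ``gain`` times the
    agent's mean expectancy-violation weight plus noise; ``bu_channels``
    couple to the belief weight; all other channels are pure noise.  Input is
    the cohort covariate table (holds the generative profile fields); output
    is wide (participant x channel).
    """
    rng = np.random.default_rng(seed)
    idx = covariates["participant"]
    w_ev = 0.5 * (covariates["w_ev_pos"] + covariates["w_ev_neg"]).to_numpy()
    w_bu = covariates["w_belief"].to_numpy()
    out = {}
    for ch in channels:
        base = np.zeros(len(idx))
        if ch in ev_channels:
            base = base + gain * w_ev
        if ch in bu_channels:
            base = base + gain * w_bu
        out[ch] = base + rng.normal(0.0, noise_sd, size=len(idx))
    return pd.DataFrame(out, index=pd.Index(idx, name="participant"))
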