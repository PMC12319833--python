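"""Behavioral statistics for the gamble-bidding task.

Implements the analysis chain applied to the long-format trial table:

- per-participant category means of value updating (ΔWTS = postdraw minus
  predraw bid), with the option to merge the two non-normative mismatch
  categories,
- one-sample Wilcoxon signed-rank tests with rank-biserial effect sizes
  (exact null by dynamic programming up to n = 25, normal approximation with
  continuity and tie corrections beyond),
- deviation scores DEV = ΔWTS − predicted update (sign-flipped in
  negative-valence categories so positive DEV always means over-updating),
- a valence × normativity linear mixed model on per-cell means,
- process regressions of urn-wise ΔWTS on belief updating and expectancy
  violation, with optional backward elimination by likelihood-ratio test,
- age-group mixed models comparing two cohorts (updating, predraw values,
  and phase models),
- Spearman and semi-partial Spearman covariate correlations.

Mixed models are random-intercept fits via statsmodels MixedLM (REML by
default).  Wald F statistics use residual degrees of freedom; the result
metadata records ``df_method`` accordingly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from urnbid.task import TrialCategory

logger = logging.getLogger(__name__)

CATEGORY_ORDER = [c.value for c in TrialCategory]

#: Categories where the drawn color mismatches the winning color.
NEGATIVE_CATEGORIES = [
    TrialCategory.NORMATIVE_NEGATIVE.value,
    TrialCategory.NONNORMATIVE_NEGATIVE_RISKY_IN_AMBIGUOUS.value,
    TrialCategory.NONNORMATIVE_NEGATIVE_AMBIGUOUS_IN_RISKY.value,
]

MERGED_NONNORMATIVE_NEGATIVE = "nonnormative_negative_merged"


class UndefinedTestError(ValueError):
    """Raised when a test statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """One-sample Wilcoxon signed-rank test result."""

    statistic: float  # W+ (sum of ranks of positive differences)
    pvalue: float
    rank_biserial: float
    n_used: int  # non-zero differences entering the test
    n_zero: int  # differences equal to mu0, dropped
    method: str  # "exact" or "approx"


def _exact_signed_rank_cdf(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W+ over doubled (integer) midranks.

    Returns the probability mass over 2*W+ in {0, ..., sum(2r)} computed by
    the shift (convolution) algorithm; exact also under midrank ties.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_one_sample(
    values: Sequence[float],
    mu0: float = 0.0,
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped and ties receive midranks.  The null
    distribution is exact (sign-flip enumeration via dynamic programming) for
    up to ``exact_max_n`` non-zero differences, and a normal approximation
    with continuity correction beyond.  The rank-biserial effect size is
    (W+ − W−) / (W+ + W−).
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[~np.isnan(d)]
    nonzero = d[d != 0]
    n_zero = len(d) - len(nonzero)
    n = len(nonzero)
    if n == 0:
        raise UndefinedTestError("all values equal mu0; test undefined")

    ranks = stats.rankdata(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    total = float(ranks.sum())
    w_neg = total - w_pos
    rank_biserial = (w_pos - w_neg) / total

    if n <= exact_max_n:
        pmf = _exact_signed_rank_cdf(ranks)
        w2 = int(round(2 * w_pos))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mean = total / 2.0
        var = float((ranks**2).sum()) / 4.0
        diff = w_pos - mean
        cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
        z = (diff - cc) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "approx"
    return WilcoxonResult(
        statistic=w_pos,
        pvalue=p,
        rank_biserial=rank_biserial,
        n_used=n,
        n_zero=n_zero,
        method=method,
    )


# ---------------------------------------------------------------------------
# Category aggregation and deviation scores
# ---------------------------------------------------------------------------

def aggregate_categories(
    trials: pd.DataFrame,
    value: str = "delta_wts",
    merge_nonnormative_negative: bool = False,
) -> pd.DataFrame:
    """Per-participant x category means of ``value`` (missing trials excluded).

    With ``merge_nonnormative_negative`` the two non-normative mismatch
    categories (risky draws in ambiguous gambles, ambiguous draws in risky
    gambles) are pooled before averaging.  Empty cells yield NaN with a
    warning; the participant is retained.
    """
    df = trials.copy()
    if merge_nonnormative_negative:
        df["category"] = df["category"].replace(
            {
                TrialCategory.NONNORMATIVE_NEGATIVE_RISKY_IN_AMBIGUOUS.value: MERGED_NONNORMATIVE_NEGATIVE,
                TrialCategory.NONNORMATIVE_NEGATIVE_AMBIGUOUS_IN_RISKY.value: MERGED_NONNORMATIVE_NEGATIVE,
            }
        )
    cell = (
        df.dropna(subset=[value])
        .groupby(["participant", "category"], observed=True)[value]
        .mean()
    )
    wide = cell.unstack("category")
    if wide.isna().any().any():
        n_empty = int(wide.isna().sum().sum())
        logger.warning("%d empty participant x category cells (left as NaN)", n_empty)
    return wide


def category_summaries(
    trials: pd.DataFrame, value: str = "delta_wts"
) -> pd.DataFrame:
    """Wilcoxon tests of per-participant category means against zero.

    One row per trial category: group median of the per-participant means,
    signed-rank statistic, two-sided p, and rank-biserial effect size.
    """
    means = aggregate_categories(trials, value=value)
    rows = []
    for cat in CATEGORY_ORDER:
        if cat not in means.columns:
            continue
        vals = means[cat].dropna().to_numpy()
        res = wilcoxon_one_sample(vals)
        rows.append(
            {
                "category": cat,
                "n": len(vals),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "rank_biserial": res.rank_biserial,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def compute_dev(
    trials: pd.DataFrame,
    sign_flip_negative: bool = True,
) -> pd.DataFrame:
    """Per-participant x category deviation from the model prediction.

    DEV = ΔWTS − predicted update, averaged within participant x category.
    When ``sign_flip_negative`` the negative-valence (mismatch) categories are
    multiplied by −1, so DEV > 0 uniformly means over-updating and DEV < 0
    under-updating.  Returns a tidy frame with columns ``participant``,
    ``category``, ``dev``, ``abs_dev`` and ``sign_flipped``.
    """
    df = trials.dropna(subset=["delta_wts"]).copy()
    df["dev_trial"] = df["delta_wts"] - df["predicted_update"]
    cell = (
        df.groupby(["participant", "category"], observed=True)["dev_trial"]
        .mean()
        .rename("dev")
        .reset_index()
    )
    cell["abs_dev"] = cell["dev"].abs()
    if sign_flip_negative:
        neg = cell["category"].isin(NEGATIVE_CATEGORIES)
        cell.loc[neg, "dev"] *= -1.0
    cell["sign_flipped"] = sign_flip_negative
    return cell


def overall_abs_dev(trials: pd.DataFrame) -> pd.Series:
    """Overall per-participant |DEV|: mean absolute category-wise deviation."""
    cell = compute_dev(trials, sign_flip_negative=False)
    return cell.groupby("participant", observed=True)["abs_dev"].mean()


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Random-intercept linear mixed model fit summary."""

    formula: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    anova: pd.DataFrame  # one row per fixed term: F, df1, df2, p, eta_p2
    random_variance: float
    resid_variance: float
    converged: bool
    singular: bool
    metadata: dict = field(default_factory=dict)
    elimination_path: list = field(default_factory=list)
    contrasts: pd.DataFrame | None = None
    _result: object = field(default=None, repr=False)


def _term_wald_anova(res) -> pd.DataFrame:
    """Wald F tests per fixed-effect term with partial eta squared.

    Uses residual degrees of freedom in the denominator (df_method recorded
    by callers in metadata).
    """
    design_info = res.model.data.design_info
    k_fe = res.k_fe
    df2 = max(int(res.nobs) - k_fe, 1)
    rows = []
    for term, slc in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(*slc.indices(k_fe)))
        L = np.zeros((len(idx), res.params.shape[0]))
        for i, j in enumerate(idx):
            L[i, j] = 1.0
        wt = res.wald_test(L, use_f=True, scalar=True)
        F = float(np.squeeze(wt.statistic))
        df1 = len(idx)
        p = float(stats.f.sf(F, df1, df2))
        eta_p2 = (F * df1) / (F * df1 + df2)
        rows.append(
            {"term": term, "F": F, "df1": df1, "df2": df2, "pvalue": p, "eta_p2": eta_p2}
        )
    return pd.DataFrame(rows)


def fit_mixed_model(
    data: pd.DataFrame,
    formula: str,
    groups: str = "participant",
    reml: bool = True,
) -> MixedModelResult:
    """Fit a random-intercept LMM and package estimates and Wald F tests."""
    data = data.dropna(subset=[c for c in data.columns if data[c].dtype != object])
    res = _fit_mixedlm_raw(data, formula, groups, reml)
    group_var = float(np.squeeze(res.cov_re.to_numpy()))
    singular = group_var < 1e-8 * max(res.scale, 1e-12)
    if singular:
        logger.warning("singular fit (random-intercept variance ~ 0): %s", formula)
    fe = res.fe_params.index
    return MixedModelResult(
        formula=formula,
        params=res.fe_params,
        bse=res.bse.loc[fe],
        tvalues=res.tvalues.loc[fe],
        pvalues=res.pvalues.loc[fe],
        anova=_term_wald_anova(res),
        random_variance=group_var,
        resid_variance=float(res.scale),
        converged=bool(res.converged),
        singular=singular,
        metadata={"reml": reml, "df_method": "residual", "groups": groups},
        _result=res,
    )


def _fit_mixedlm_raw(data: pd.DataFrame, formula: str, groups: str, reml: bool):
    """MixedLM fit with the default optimizer, falling back to Powell."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[groups])
        try:
            return model.fit(reml=reml)
        except np.linalg.LinAlgError:
            return model.fit(reml=reml, method="powell")


def _loglik_ml(data: pd.DataFrame, formula: str, groups: str) -> tuple[float, int]:
    res = _fit_mixedlm_raw(data, formula, groups, reml=False)
    return float(res.llf), int(res.k_fe)


def backward_select(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    groups: str = "participant",
    alpha: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Backward elimination of fixed-effect terms by likelihood-ratio test.

    Terms are removed one at a time (least significant first, ML refits,
    respecting marginality: a main effect is not removable while an
    interaction containing it remains) until every remaining term is
    significant at ``alpha``.  Returns the surviving terms and the
    elimination path.
    """
    terms = list(terms)
    path: list[dict] = []

    def removable(t: str) -> bool:
        parts = set(t.split(":"))
        return not any(
            t != other and parts < set(other.split(":")) for other in terms
        )

    while terms:
        formula_full = f"{response} ~ {' + '.join(terms)}"
        llf_full, k_full = _loglik_ml(data, formula_full, groups)
        candidates = []
        for t in terms:
            if not removable(t):
                continue
            reduced = [u for u in terms if u != t]
            formula_red = f"{response} ~ {' + '.join(reduced)}" if reduced else f"{response} ~ 1"
            llf_red, k_red = _loglik_ml(data, formula_red, groups)
            lr = max(0.0, 2.0 * (llf_full - llf_red))
            df = max(k_full - k_red, 1)
            p = float(stats.chi2.sf(lr, df))
            candidates.append((p, t, lr, df))
        if not candidates:
            break
        p, worst, lr, df = max(candidates, key=lambda c: c[0])
        if p <= alpha:
            break
        terms.remove(worst)
        path.append({"removed": worst, "lr_stat": lr, "df": df, "pvalue": p})
    return terms, path


def valence_normativity_cells(
    trials: pd.DataFrame, flip_negative: bool = True
) -> pd.DataFrame:
    """Per-participant cell means in the valence x normativity layout.

    The two non-normative mismatch categories are merged first; negative
    cells are sign-flipped when requested so larger values mean stronger
    updating in every cell.  Carries ``age_group`` through when present.
    """
    means = aggregate_categories(trials, merge_nonnormative_negative=True)
    layout = {
        TrialCategory.NORMATIVE_POSITIVE.value: ("positive", "normative"),
        TrialCategory.NORMATIVE_NEGATIVE.value: ("negative", "normative"),
        TrialCategory.NONNORMATIVE_POSITIVE.value: ("positive", "nonnormative"),
        MERGED_NONNORMATIVE_NEGATIVE: ("negative", "nonnormative"),
    }
    rows = []
    for cat, (valence, normativity) in layout.items():
        if cat not in means.columns:
            continue
        for pid, v in means[cat].items():
            if np.isnan(v):
                continue
            val = -v if (flip_negative and valence == "negative") else v
            rows.append(
                {
                    "participant": pid,
                    "valence": valence,
                    "normativity": normativity,
                    "value": val,
                }
            )
    cells = pd.DataFrame(rows)
    if "age_group" in trials.columns:
        group_of = trials.drop_duplicates("participant").set_index("participant")[
            "age_group"
        ]
        cells["age_group"] = cells["participant"].map(group_of)
    return cells


def marginal_contrast(
    result: MixedModelResult, data: pd.DataFrame, factor: str, adjust: str = "holm"
) -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means for one factor.

    Marginal means average model predictions over the observed grid of the
    other fixed factors; contrast SEs come from the fixed-effect covariance.
    """
    res = result._result
    design_info = res.model.data.design_info
    from patsy import build_design_matrices

    factors = [c for c in data.columns if data[c].dtype == object and c in result.formula]
    others = [f for f in factors if f != factor]
    grid_other = (
        data[others].drop_duplicates() if others else pd.DataFrame([{}])
    )
    numeric = [
        c
        for c in data.columns
        if c in result.formula.split("~")[1] and data[c].dtype != object
    ]

    levels = sorted(data[factor].dropna().unique())
    X_rows = {}
    for lev in levels:
        grid = grid_other.copy()
        grid[factor] = lev
        for c in numeric:
            grid[c] = data[c].mean()
        (X,) = build_design_matrices([design_info], grid)
        X_rows[lev] = np.asarray(X).mean(axis=0)

    cov = res.cov_params().iloc[: res.k_fe, : res.k_fe].to_numpy()
    beta = res.fe_params.to_numpy()
    df2 = max(int(res.nobs) - res.k_fe, 1)
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            L = X_rows[a] - X_rows[b]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else np.inf * np.sign(est)
            p = float(2 * stats.t.sf(abs(t), df2))
            rows.append(
                {"contrast": f"{a} - {b}", "estimate": est, "se": se, "t": t, "pvalue": p}
            )
    out = pd.DataFrame(rows)
    if len(out) > 1 and adjust:
        out["pvalue_adj"] = multipletests(out["pvalue"], method=adjust)[1]
    else:
        out["pvalue_adj"] = out["pvalue"]
    return out


def fit_valence_normativity_lmm(
    trials_or_cells: pd.DataFrame, flip_negative: bool = True
) -> MixedModelResult:
    """Valence x normativity LMM on per-participant cell means.

    Fixed effects: valence, normativity, and their interaction; random
    intercept per participant; REML estimation.  Accepts either the raw trial
    table or a prebuilt cell table with columns participant/valence/
    normativity/value.
    """
    if "value" in trials_or_cells.columns and "valence" in trials_or_cells.columns:
        cells = trials_or_cells
    else:
        cells = valence_normativity_cells(trials_or_cells, flip_negative=flip_negative)
    if cells["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    result = fit_mixed_model(cells, "value ~ valence * normativity")
    result.contrasts = marginal_contrast(result, cells, "valence")
    return result


def urnwise_means(trials: pd.DataFrame, category: str | TrialCategory) -> pd.DataFrame:
    """Average ΔWTS and process predictors to participant x urn within a category."""
    cat = category.value if isinstance(category, TrialCategory) else category
    sub = trials[trials["category"] == cat].dropna(subset=["delta_wts"])
    if sub.empty:
        raise ValueError(f"no usable trials in category {cat!r}")
    agg = (
        sub.groupby(["participant", "urn"], observed=True)[
            ["delta_wts", "belief_update", "predicted_update", "expectancy_violation"]
        ]
        .mean()
        .reset_index()
    )
    return agg


def fit_process_lmm(
    trials: pd.DataFrame,
    category: str | TrialCategory,
    predictors: Iterable[str] = ("belief_update", "expectancy_violation"),
    stepwise: bool = False,
    belief_predictor: str = "belief_update",
    alpha: float = 0.05,
) -> MixedModelResult:
    """Process regression of urn-wise ΔWTS within one trial category.

    Predictors are the Bayesian belief-updating magnitude (KL by default;
    pass ``belief_predictor="predicted_update"`` to use the predicted EV
    change instead) and expectancy violation.  Constant predictors within the
    category are dropped with a warning.  With ``stepwise`` the fixed effects
    are simplified by backward likelihood-ratio elimination before the final
    REML fit.
    """
    data = urnwise_means(trials, category)
    terms = []
    for p in predictors:
        name = belief_predictor if p == "belief_update" else p
        if data[name].nunique() <= 1:
            logger.warning(
                "predictor %r constant within category %s; dropped", name, category
            )
            continue
        terms.append(name)
    if not terms:
        raise ValueError("no varying predictors in this category")
    path: list[dict] = []
    if stepwise:
        terms, path = backward_select(data, "delta_wts", terms, alpha=alpha)
    formula = (
        f"delta_wts ~ {' + '.join(terms)}" if terms else "delta_wts ~ 1"
    )
    result = fit_mixed_model(data, formula)
    result.elimination_path = path
    return result


def fit_age_group_lmms(
    trials: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> dict[str, MixedModelResult]:
    """The three age-comparison mixed models over a two-cohort trial table.

    - ``updating``: ΔWTS cell means ~ age_group * valence * normativity,
    - ``predraw``: mean predraw WTS ~ age_group * gamble_type,
    - ``phase``: mean WTS ~ age_group * gamble_type * phase,

    each with a participant random intercept, the reasoning covariate as a
    fixed control term when available, and Holm-adjusted post hoc contrasts.
    """
    if "age_group" not in trials.columns or trials["age_group"].nunique() < 2:
        raise ValueError("trial table must contain two age groups")

    cov_term = ""
    cov_map = None
    if covariates is not None and "covariate_score" in covariates.columns:
        cov_map = covariates.set_index("participant")["covariate_score"]
        cov_term = " + covariate_score"
    else:
        logger.warning("no covariate table; models fitted without the control term")

    results: dict[str, MixedModelResult] = {}

    cells = valence_normativity_cells(trials, flip_negative=True)
    if cov_map is not None:
        cells["covariate_score"] = cells["participant"].map(cov_map)
    m1 = fit_mixed_model(cells, f"value ~ age_group * valence * normativity{cov_term}")
    m1.contrasts = pd.concat(
        [
            marginal_contrast(m1, cells[cells["normativity"] == lev], "age_group")
            .assign(normativity=lev)
            for lev in ("normative", "nonnormative")
        ],
        ignore_index=True,
    )
    m1.contrasts["pvalue_adj"] = multipletests(m1.contrasts["pvalue"], method="holm")[1]
    results["updating"] = m1

    predraw = (
        trials.dropna(subset=["wts_pre"])
        .drop_duplicates(["participant", "gamble_index"])
        .groupby(["participant", "age_group", "gamble_type"], observed=True)["wts_pre"]
        .mean()
        .reset_index()
    )
    if cov_map is not None:
        predraw["covariate_score"] = predraw["participant"].map(cov_map)
    m2 = fit_mixed_model(predraw, f"wts_pre ~ age_group * gamble_type{cov_term}")
    m2.contrasts = pd.concat(
        [
            marginal_contrast(m2, predraw[predraw["gamble_type"] == lev], "age_group")
            .assign(gamble_type=lev)
            for lev in ("risky", "ambiguous")
        ],
        ignore_index=True,
    )
    m2.contrasts["pvalue_adj"] = multipletests(m2.contrasts["pvalue"], method="holm")[1]
    results["predraw"] = m2

    pre = predraw.rename(columns={"wts_pre": "wts"}).assign(phase="predraw")
    post = (
        trials.dropna(subset=["wts_post"])
        .groupby(["participant", "age_group", "gamble_type"], observed=True)["wts_post"]
        .mean()
        .reset_index()
        .rename(columns={"wts_post": "wts"})
        .assign(phase="postdraw")
    )
    phase = pd.concat([pre.drop(columns=["covariate_score"], errors="ignore"), post],
                      ignore_index=True)
    if cov_map is not None:
        phase["covariate_score"] = phase["participant"].map(cov_map)
    m3 = fit_mixed_model(phase, f"wts ~ age_group * gamble_type * phase{cov_term}")
    results["phase"] = m3
    return results


# ---------------------------------------------------------------------------
# Covariate correlations
# ---------------------------------------------------------------------------

def correlate_covariate(
    abs_dev: Sequence[float],
    covariate: Sequence[float],
    controls: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation between |DEV| and a covariate.

    With ``controls`` the semi-partial variant is used: all variables are
    rank-transformed, the covariate's ranks are residualized on the control
    ranks by least squares, and the correlation is computed between the
    |DEV| ranks and those residuals.
    """
    x = np.asarray(abs_dev, dtype=float)
    y = np.asarray(covariate, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if controls is not None:
        C = np.atleast_2d(np.asarray(controls, dtype=float))
        if C.shape[0] != len(x):
            C = C.T
        mask &= ~np.isnan(C).any(axis=1)
        C = C[mask]
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 5:
        raise UndefinedTestError("need at least 5 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedTestError("zero variance in one of the variables")

    if controls is None:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rC = np.column_stack([stats.rankdata(c) for c in C.T])
    design = np.column_stack([np.ones(n), rC])
    resid = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.std(resid) == 0:
        raise UndefinedTestError("covariate fully explained by controls")
    rho = float(np.corrcoef(rx, resid)[0, 1])
    t = rho * np.sqrt((n - 2) / max(1e-12, 1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p
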