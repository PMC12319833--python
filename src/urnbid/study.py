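"""End-to-end synthetic study: agents → behavior → fNIRS → report.

``run_full_study`` chains the stages the way the original analysis was run:
simulate one or two cohorts of bidding agents, compute the behavioral
statistics, simulate channel series whose modulator responses are coupled to
the agents' generative weights, fit the AR-IRLS GLM per subject and channel,
run the group-level FDR statistics, and correlate the significant channels'
betas with behavioral |DEV|.  Every stochastic stage is seeded from the run
seed; a manifest records versions, seeds and content hashes of all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from urnbid import behavior, brain_behavior
from urnbid.agents import CohortSpec, simulate_cohort
from urnbid.fnirs import SAMPLING_RATE, build_design, fit_ar_irls, group_level
from urnbid.fnirs.design import session_events
from urnbid.fnirs.montage import load_default_montage
from urnbid.fnirs.simulate import simulate_channels
from urnbid.io import write_json, write_manifest, write_table
from urnbid.task import TrialCategory, UrnComposition, build_session, default_urn_set

logger = logging.getLogger(__name__)


@dataclass
class FnirsConfig:
    """Scale and coupling of the simulated fNIRS stage."""

    n_channels: int = 8
    n_subjects: int | None = None  # None: all agents of the first cohort
    ev_channels: tuple[str, ...] = ("S11-D13",)  # expectancy-violation coupled
    bu_channels: tuple[str, ...] = ("S14-D14",)  # belief-updating coupled
    gain: float = 8.0
    beta_noise_sd: float = 0.3
    task_beta: float = 0.5
    ar: tuple[float, ...] = (0.6,)
    noise_sd: float = 0.4
    sampling_rate: float = SAMPLING_RATE


@dataclass
class RunConfig:
    """Configuration of a full synthetic study run."""

    seed: int = 0
    cohorts: list = field(default_factory=lambda: [{"preset": "old_like"}])
    urns: list | None = None  # [[nr, na], ...] or None for the default set
    fnirs: FnirsConfig = field(default_factory=FnirsConfig)
    fdr_family: tuple[str, ...] = ("channel", "chromophore", "regressor")
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        fnirs = cfg.pop("fnirs", {})
        if isinstance(fnirs, dict):
            fnirs = FnirsConfig(**{k: tuple(v) if isinstance(v, list) and k in
                                   ("ev_channels", "bu_channels", "ar") else v
                                   for k, v in fnirs.items()})
        fam = cfg.pop("fdr_family", None)
        obj = cls(fnirs=fnirs, **cfg)
        if fam is not None:
            obj.fdr_family = tuple(fam)
        return obj

    def urn_set(self) -> list[UrnComposition]:
        if self.urns is None:
            return default_urn_set()
        return [UrnComposition(int(nr), int(na)) for nr, na in self.urns]


def _cohort_spec(entry: dict, seed: int) -> CohortSpec:
    entry = dict(entry)
    preset = entry.pop("preset", None)
    if preset:
        return CohortSpec.preset(preset, seed=seed, **entry)
    return CohortSpec.from_dict({**entry, "seed": seed})


def analyze_behavior(
    trials: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> dict:
    """The behavioral analysis bundle for one (or two) cohorts."""
    out: dict = {}
    out["category_summaries"] = behavior.category_summaries(trials)
    out["dev"] = behavior.compute_dev(trials, sign_flip_negative=True)
    out["abs_dev"] = behavior.overall_abs_dev(trials).rename("abs_dev").reset_index()

    lmm = behavior.fit_valence_normativity_lmm(trials)
    out["valence_normativity"] = {
        "formula": lmm.formula,
        "anova": lmm.anova,
        "params": lmm.params,
        "contrasts": lmm.contrasts,
        "singular": lmm.singular,
    }

    process = []
    for cat in TrialCategory:
        try:
            res = behavior.fit_process_lmm(trials, cat, stepwise=False)
        except ValueError:
            continue
        for name in res.params.index:
            if name == "Intercept":
                continue
            process.append(
                {
                    "category": cat.value,
                    "predictor": name,
                    "beta": float(res.params[name]),
                    "se": float(res.bse[name]),
                    "pvalue": float(res.pvalues[name]),
                }
            )
    out["process_lmms"] = pd.DataFrame(process)

    if covariates is not None and "covariate_score" in covariates:
        merged = out["abs_dev"].merge(covariates, on="participant")
        try:
            rho, p = behavior.correlate_covariate(
                merged["abs_dev"], merged["covariate_score"]
            )
            out["covariate_correlation"] = {"rho": rho, "pvalue": p, "n": len(merged)}
        except behavior.UndefinedTestError as err:
            logger.warning("covariate correlation skipped (underpowered): %s", err)

    if "age_group" in trials.columns and trials["age_group"].nunique() > 1:
        age = behavior.fit_age_group_lmms(trials, covariates)
        out["age_models"] = {
            name: {"formula": m.formula, "anova": m.anova, "contrasts": m.contrasts}
            for name, m in age.items()
        }
    return out


def simulate_and_fit_fnirs(
    trials: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: FnirsConfig,
    urns: list[UrnComposition],
    seed: int,
    fdr_family: tuple[str, ...] = ("channel", "chromophore", "regressor"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate coupled channel series per subject and run the GLM chain.

    Returns (subject-level results, group-level results, per-subject
    modulator betas wide table).
    """
    montage = load_default_montage()
    wanted = list(cfg.ev_channels) + list(cfg.bu_channels)
    names = [c for c in wanted if c in montage.channel_names]
    names += [c for c in montage.channel_names if c not in names]
    channels = names[: cfg.n_channels]

    participants = list(covariates["participant"])
    if cfg.n_subjects is not None:
        participants = participants[: cfg.n_subjects]
    cov = covariates.set_index("participant").loc[participants].reset_index()

    true_mod = brain_behavior.couple_channel_betas(
        cov,
        channels,
        ev_channels=cfg.ev_channels,
        bu_channels=cfg.bu_channels,
        gain=cfg.gain,
        noise_sd=cfg.beta_noise_sd,
        seed=seed,
    )

    root = np.random.SeedSequence(seed)
    subject_rows = []
    for i, pid in enumerate(participants):
        sub = trials[trials["participant"] == pid]
        session_seed = int(sub["session_seed"].iloc[0])
        plan = build_session(urns=urns, seed=session_seed)
        events = session_events(plan, trials=sub, seed=session_seed)
        duration = events.end_time + 20.0
        X = build_design(events, duration, cfg.sampling_rate)

        betas = np.zeros((len(channels), X.shape[1]))
        cols = list(X.columns)
        if "scenario" in cols:
            betas[:, cols.index("scenario")] = cfg.task_beta
        for j, ch in enumerate(channels):
            for mod_col, coupled in (
                ("scenario:expectancy_violation", ch in cfg.ev_channels),
                ("scenario:belief_update", ch in cfg.bu_channels),
            ):
                if mod_col in cols and coupled:
                    betas[j, cols.index(mod_col)] = true_mod.loc[pid, ch]

        sseed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
        series = simulate_channels(X, betas, ar=cfg.ar, noise_sd=cfg.noise_sd, seed=sseed)
        for j, ch in enumerate(channels):
            res = fit_ar_irls(series[j], X, channel=ch)
            res.insert(0, "subject", pid)
            subject_rows.append(res)

    subject_results = pd.concat(subject_rows, ignore_index=True)
    fitted = subject_results[subject_results["regressor"] != "intercept"]
    group = group_level(fitted, family=fdr_family)
    return subject_results, group, true_mod


def brain_behavior_report(
    subject_results: pd.DataFrame,
    group: pd.DataFrame,
    trials: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Correlate significant modulator channels' betas with |DEV|."""
    abs_dev = behavior.overall_abs_dev(trials)
    out: dict = {"correlations": [], "relative_influence": []}
    sig = group[group["significant"] & group["regressor"].str.startswith("scenario:")]
    for _, row in sig.iterrows():
        sub = subject_results[
            (subject_results["channel"] == row["channel"])
            & (subject_results["regressor"] == row["regressor"])
        ]
        betas = sub.set_index("subject")["beta"]
        betas.index.name = "participant"
        wide = betas.to_frame(name=row["channel"])
        try:
            corr = brain_behavior.correlate_beta_dev(wide, abs_dev)
        except behavior.UndefinedTestError:
            continue
        corr["regressor"] = row["regressor"]
        out["correlations"].append(corr)

    # relative influence per channel carrying both modulators
    piv = subject_results[
        subject_results["regressor"].isin(
            ["scenario:expectancy_violation", "scenario:belief_update"]
        )
    ].pivot_table(index=["subject", "channel"], columns="regressor", values="beta")
    if piv.shape[1] == 2:
        ev = piv["scenario:expectancy_violation"]
        bu = piv["scenario:belief_update"]
        idx = (ev.abs() / (ev.abs() + bu.abs())).rename("relative_influence")
        out["relative_influence"] = idx.reset_index()
    out["correlations"] = (
        pd.concat(out["correlations"], ignore_index=True)
        if out["correlations"]
        else pd.DataFrame(columns=["channel", "rho", "pvalue", "n", "q", "significant"])
    )
    return out


def run_full_study(config: RunConfig) -> dict:
    """Execute all stages and write result tables, reports, and the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    urns = config.urn_set()
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(["cohorts", "fnirs"], root.spawn(2))
    }

    stage = "simulate-cohort"
    try:
        cohort_seeds = np.random.SeedSequence(stage_seeds["cohorts"]).spawn(
            len(config.cohorts)
        )
        all_trials, all_cov = [], []
        for entry, cseed in zip(config.cohorts, cohort_seeds):
            spec = _cohort_spec(entry, int(cseed.generate_state(1)[0] % 2**31))
            trials, cov = simulate_cohort(spec, urns=urns)
            all_trials.append(trials)
            all_cov.append(cov)
        trials = pd.concat(all_trials, ignore_index=True)
        covariates = pd.concat(all_cov, ignore_index=True)
        write_table(trials, out_dir / "trials.csv")
        write_table(covariates, out_dir / "covariates.csv")

        stage = "analyze-behavior"
        beh = analyze_behavior(trials, covariates)
        write_table(beh["category_summaries"], out_dir / "category_summaries.csv")
        write_table(beh["process_lmms"], out_dir / "process_lmms.csv")
        write_table(beh["abs_dev"], out_dir / "abs_dev.csv")
        write_json(
            {
                k: v
                for k, v in beh.items()
                if k in ("valence_normativity", "covariate_correlation", "age_models")
            },
            out_dir / "behavior_report.json",
        )

        stage = "simulate-fnirs/fit-glm"
        first_label = covariates["age_group"].iloc[0]
        first_cov = covariates[covariates["age_group"] == first_label]
        first_trials = trials[trials["age_group"] == first_label]
        subject_results, group, _ = simulate_and_fit_fnirs(
            first_trials, first_cov, config.fnirs, urns, stage_seeds["fnirs"],
            fdr_family=config.fdr_family,
        )
        write_table(subject_results, out_dir / "glm_subject.csv")
        write_table(group, out_dir / "glm_group.csv")

        stage = "report"
        report = brain_behavior_report(subject_results, group, first_trials, first_cov)
        write_table(report["correlations"], out_dir / "brain_behavior.csv")
        if len(report["relative_influence"]):
            write_table(report["relative_influence"], out_dir / "relative_influence.csv")
    except Exception:
        logger.exception("full study failed at stage %s (partial outputs in %s)",
                         stage, out_dir)
        raise

    manifest = write_manifest(
        out_dir, seeds={"run": config.seed, **stage_seeds}
    )
    return {
        "out_dir": str(out_dir),
        "manifest": str(manifest),
        "behavior": beh,
        "group": group,
        "report": report,
    }
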