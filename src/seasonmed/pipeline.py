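"""End-to-end study pipeline: descriptives, seasonality, symptom models, mediation.

``run_study`` reproduces the full analysis sequence on a cohort table
(synthetic or real-schema): participant descriptives; cosinor seasonality
of the brainstem volumes (adjusted for age and TBV); negative-binomial
regression of each symptom score on photoperiod (adjusted for age,
ethnicity, living area and Townsend score), with a Bonferroni family of
15 tests; hierarchical linear regression of each volume on photoperiod
(age and TBV blocks first); negative-binomial regression of each symptom
on each volume (family of 75); and, for the (mediator, outcome) pairs
that pass the classical mediation requirements, a BCa bootstrap of the
indirect effect.  Analyses run for all participants and within sex.

Outputs are written as one CSV per stage per group plus a plain-text run
log recording seeds and modelling choices; identical configurations and
seeds produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cosinor as _cosinor
from . import count_regression as _cr
from . import mediation as _med
from .errors import CohortValidationError
from .photoperiod import annotate_photoperiod
from .synthetic import STRUCTURES, SYMPTOM_ITEMS, WHOLE, read_cohort

__all__ = ["AnalysisConfig", "exclusion_filter", "run_study"]

log = logging.getLogger("seasonmed")

OUTCOMES = SYMPTOM_ITEMS + ("total_depressive",)
MEDIATION_OUTCOMES = ("low_mood", "anhedonia")
MEDIATORS = (WHOLE, "midbrain", "pons", "medulla")

SYMPTOM_COVARIATES = ("age", "ethnicity", "living_area", "townsend")
VOLUME_SYMPTOM_COVARIATES = ("age", "tbv", "ethnicity", "living_area", "townsend")
MEDIATION_COVARIATES = ("age", "ethnicity", "living_area", "townsend", "tbv")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    input: str | None = None
    outdir: str | None = None
    grouping: str = "by_sex"            # "all" or "by_sex" (runs all + each sex)
    outcomes: tuple[str, ...] = OUTCOMES
    mediators: tuple[str, ...] = MEDIATORS
    alpha: float = 0.05
    cosinor_alpha: float = 0.025
    bonferroni_symptoms: int = 15
    bonferroni_volume_symptoms: int = 75
    n_boot: int = 5000
    jackknife_groups: int = 100
    seed: int = 0
    cov_type: str = "HC1"
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.cosinor_alpha < 1:
            raise ValueError("alpha levels must be in (0, 1)")
        if self.bonferroni_symptoms < 1 or self.bonferroni_volume_symptoms < 1:
            raise ValueError("Bonferroni divisors must be >= 1")
        if self.grouping not in ("all", "by_sex"):
            raise ValueError("grouping must be 'all' or 'by_sex'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outcomes", "mediators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def exclusion_filter(
    raw: pd.DataFrame,
    image_ok_col: str = "image_quality_ok",
    mood_complete_col: str = "mood_complete",
) -> tuple[pd.DataFrame, dict]:
    """Apply the study's participant exclusions in order.

    Image-quality failures are removed first, then participants with
    incomplete mood measures; each participant is excluded at most once
    even if flagged for both.  Missing flag columns are treated as
    all-pass.  Returns the retained table and a step-by-step count log.
    """
    n0 = len(raw)
    keep = raw
    rec = {"initial": n0}
    if image_ok_col in raw.columns:
        keep = keep[keep[image_ok_col].astype(bool)]
    rec["excluded_image_quality"] = n0 - len(keep)
    n1 = len(keep)
    if mood_complete_col in raw.columns:
        keep = keep[keep[mood_complete_col].astype(bool)]
    rec["excluded_mood_incomplete"] = n1 - len(keep)
    rec["retained"] = len(keep)
    return keep.reset_index(drop=True), rec


def _descriptives(df: pd.DataFrame) -> pd.DataFrame:
    rows = [("n", float(len(df)), np.nan)]
    for col in ("age", *OUTCOMES, "townsend", "photoperiod",
                *STRUCTURES, "tbv", "gmv", "wmv"):
        rows.append((col, float(df[col].mean()), float(df[col].std())))
    for col in ("ethnicity", "living_area", "sex"):
        for level, cnt in df[col].value_counts().items():
            rows.append((f"{col}[{level}]", float(cnt), np.nan))
    return pd.DataFrame(rows, columns=["variable", "mean_or_count", "sd"])


def _cosinor_table(df, cfg) -> pd.DataFrame:
    month = np.array([d.month for d in df["scan_date"]])
    rows = []
    for s in STRUCTURES:
        fit = _cosinor.fit_cosinor(
            df[s], month, covariates={"age": df["age"], "tbv": df["tbv"]},
            alpha=cfg.cosinor_alpha, cov_type=cfg.cov_type,
        )
        rows.append({
            "outcome": s, "n": fit.n,
            "beta_cos": fit.beta, "se_beta": fit.se_beta, "p_beta": fit.p_beta,
            "gamma_sin": fit.gamma, "se_gamma": fit.se_gamma, "p_gamma": fit.p_gamma,
            "delta_aic": fit.delta_aic, "acrophase": fit.phi,
            "acrophase_month": fit.acrophase_month_label,
            "amplitude": fit.amplitude, "se_amplitude": fit.se_amplitude,
            "seasonal": fit.seasonal,
        })
    return pd.DataFrame(rows)


def _photoperiod_symptom_table(df, cfg) -> pd.DataFrame:
    adj = _cr.bonferroni(cfg.alpha, cfg.bonferroni_symptoms)
    cov = {c: df[c] for c in SYMPTOM_COVARIATES}
    rows = []
    for outc in cfg.outcomes:
        fit = _cr.fit_nb(df[outc], df["photoperiod"], covariates=cov,
                         predictor_name="photoperiod", cov_type=cfg.cov_type)
        rows.append({
            "outcome": outc, "n": fit.n, "b": fit.b, "se": fit.se,
            "irr": fit.irr, "p": fit.p, "dispersion": fit.dispersion,
            "significant": fit.p < cfg.alpha,
            "significant_bonferroni": fit.p < adj,
        })
    return pd.DataFrame(rows)


def _volume_photoperiod_table(df, cfg) -> pd.DataFrame:
    rows = []
    for s in STRUCTURES:
        fit = _cr.fit_volume_photoperiod(
            df[s], df["photoperiod"], blocks=[{"age": df["age"]}, {"tbv": df["tbv"]}]
        )
        rows.append({
            "volume": s, "n": fit.n, "mean": float(df[s].mean()),
            "sd": float(df[s].std()), "r": fit.r, "B": fit.B, "se": fit.se,
            "p": fit.p, "incremental_r2": fit.r2,
        })
    return pd.DataFrame(rows)


def _volume_symptom_table(df, cfg) -> pd.DataFrame:
    adj = _cr.bonferroni(cfg.alpha, cfg.bonferroni_volume_symptoms)
    cov = {c: df[c] for c in VOLUME_SYMPTOM_COVARIATES}
    rows = []
    for s in STRUCTURES:
        for outc in cfg.outcomes:
            fit = _cr.fit_nb(df[outc], df[s], covariates=cov,
                             predictor_name=s, cov_type=cfg.cov_type)
            rows.append({
                "volume": s, "outcome": outc, "n": fit.n, "b": fit.b,
                "se": fit.se, "irr": fit.irr, "p": fit.p,
                "significant": fit.p < cfg.alpha,
                "significant_bonferroni": fit.p < adj,
            })
    return pd.DataFrame(rows)


def _mediation_table(df, cfg, group_index: int) -> pd.DataFrame:
    rows = []
    for mi, mediator in enumerate(cfg.mediators):
        for oi, outc in enumerate(MEDIATION_OUTCOMES):
            paths = _med.fit_paths(df, "photoperiod", mediator, outc,
                                   covariates=MEDIATION_COVARIATES,
                                   cov_type=cfg.cov_type)
            checklist = _med.mediation_requirements(paths, alpha=cfg.alpha)
            row = {
                "mediator": mediator, "outcome": outc, "n": paths.n,
                "a": paths.a, "p_a": paths.p_a,
                "b": paths.b_path, "p_b": paths.p_b,
                "c": paths.c, "c_prime": paths.c_prime, "p_c_prime": paths.p_c_prime,
                "indirect": paths.indirect, "eligible": checklist.eligible,
            }
            if checklist.eligible:
                seed = int(np.random.SeedSequence(
                    [cfg.seed, group_index, mi, oi]).generate_state(1)[0] % (2**31))
                ci = _med.bca_bootstrap_indirect(
                    df, "photoperiod", mediator, outc,
                    covariates=MEDIATION_COVARIATES, n_boot=cfg.n_boot,
                    seed=seed, jackknife_groups=cfg.jackknife_groups,
                )
                row.update({
                    "boot_se": ci.boot_se, "ci_ll": ci.ll, "ci_ul": ci.ul,
                    "p_boot": ci.p_boot, "significant": ci.significant,
                    "boot_seed": seed,
                })
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: AnalysisConfig, table: pd.DataFrame | None = None) -> dict:
    """Run the full pipeline; return {name: DataFrame} and write CSVs.

    ``table`` may be passed directly (already-loaded cohort); otherwise
    ``config.input`` is read and validated.  When ``config.outdir`` is
    set, each table is written as ``<group>_<stage>.csv`` plus a
    ``run_log.txt``.
    """
    config.validate()
    if table is None:
        if config.input is None:
            raise ValueError("either config.input or a table is required")
        table = read_cohort(config.input)
    else:
        missing = [c for c in ("scan_date", "sex", "age", "tbv") if c not in table.columns]
        if missing:
            raise CohortValidationError(f"missing column(s): {', '.join(missing)}")
    df = annotate_photoperiod(table)

    groups = [("all", df)]
    if config.grouping == "by_sex":
        groups += [(sex, df[df["sex"] == sex].reset_index(drop=True))
                   for sex in ("female", "male")]

    bundle: dict[str, pd.DataFrame] = {}
    log_lines = [
        f"seed={config.seed}",
        f"cov_type={config.cov_type} (heteroskedasticity-robust sandwich SEs)",
        f"alpha={config.alpha} cosinor_alpha={config.cosinor_alpha}",
        f"bonferroni_families={config.bonferroni_symptoms},{config.bonferroni_volume_symptoms}",
        f"n_boot={config.n_boot} jackknife_groups={config.jackknife_groups}",
    ]
    for gi, (gname, gdf) in enumerate(groups):
        log.info("group %s: n=%d", gname, len(gdf))
        log_lines.append(f"group={gname} n={len(gdf)}")
        bundle[f"{gname}_descriptives"] = _descriptives(gdf)
        bundle[f"{gname}_cosinor"] = _cosinor_table(gdf, config)
        bundle[f"{gname}_photoperiod_symptoms"] = _photoperiod_symptom_table(gdf, config)
        bundle[f"{gname}_volume_photoperiod"] = _volume_photoperiod_table(gdf, config)
        bundle[f"{gname}_volume_symptoms"] = _volume_symptom_table(gdf, config)
        med = _mediation_table(gdf, config, gi)
        bundle[f"{gname}_mediation"] = med
        n_eligible = int(med["eligible"].sum()) if len(med) else 0
        log_lines.append(f"group={gname} mediation_pairs_eligible={n_eligible}")

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in bundle.items():
            frame.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return bundle
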