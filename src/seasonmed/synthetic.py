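"""Synthetic cohort generator with known seasonal and mediation structure.

Produces per-participant tables shaped like a population imaging cohort:
demographics, residence coordinates, scan date, four 0-3 depressive
symptom items (low mood, anhedonia, tenseness, tiredness) plus their 0-12
total, brainstem substructure volumes (midbrain, pons, medulla, superior
cerebellar peduncle) and the whole brainstem, and global volumes
(TBV/GMV/WMV, cm^3).

Structure generated, all with known ("truth") parameters:

* Each substructure volume is mean + extra seasonal cosine term
  (amplitude ``true_amplitude``, peak month ``true_acrophase_month``)
  + ``path_a`` * (photoperiod - 13 h) + age and TBV covariate effects
  + Gaussian noise.  The whole brainstem is the sum of the four
  substructures plus its own extra terms and noise, which guarantees
  substructure < whole.  Because photoperiod is itself sinusoidal in
  season, a nonzero ``path_a`` alone already produces a seasonal volume
  rhythm; the explicit cosine amplitude defaults to 0 so the two knobs do
  not double-count.
* Symptom items are drawn from a gamma-Poisson (NB2) count model with a
  log link: intercepts calibrated to the cohort item means per sex, and a
  photoperiod direct effect (``path_c_prime``) plus a mediator-volume
  effect (``path_b``) on the configured affected items, with sex-specific
  coefficients (female-only effects by default).  Counts are clipped to
  the 0-3 item range (the clip probability is small at the calibrated
  means).

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cosinor import amplitude as _amp_formula
from .errors import CohortValidationError, ConfigError
from .photoperiod import day_length

__all__ = [
    "PARTS", "WHOLE", "STRUCTURES", "SYMPTOM_ITEMS", "COLUMNS",
    "GeneratorConfig", "SyntheticTruth",
    "generate_cohort", "write_cohort", "read_cohort", "validate_cohort",
]

PARTS = ("midbrain", "pons", "medulla", "scp")
WHOLE = "whole_brainstem"
STRUCTURES = (WHOLE,) + PARTS
SYMPTOM_ITEMS = ("low_mood", "anhedonia", "tenseness", "tiredness")

COLUMNS = (
    "participant_id", "sex", "age", "scan_date", "latitude", "longitude",
    "ethnicity", "living_area", "townsend",
    "low_mood", "anhedonia", "tenseness", "tiredness", "total_depressive",
    "whole_brainstem", "midbrain", "pons", "medulla", "scp",
    "tbv", "gmv", "wmv",
)

#: reference photoperiod (hours) about which volume/symptom effects are centred
PHOTOPERIOD_REF = 13.0


def _default_volume_means():
    return {WHOLE: 25341.6, "midbrain": 6026.7, "pons": 14750.3,
            "medulla": 4321.4, "scp": 243.13}


def _default_volume_sd():
    # residual (noise) SDs, not marginal SDs: age/TBV/season explain the rest
    return {WHOLE: 800.0, "midbrain": 420.0, "pons": 1300.0,
            "medulla": 490.0, "scp": 26.0}


def _default_amplitude():
    return {s: 0.0 for s in STRUCTURES}


def _default_path_a():
    # mm^3 per hour of photoperiod; whole-brainstem entry is the extra
    # term beyond the sum of the substructures
    return {WHOLE: 0.0, "midbrain": 16.5, "pons": 60.7,
            "medulla": 27.5, "scp": 0.807}


def _default_age_slope():
    return {WHOLE: 0.0, "midbrain": -6.0, "pons": -15.0,
            "medulla": -4.5, "scp": -0.25}


def _default_tbv_slope():
    return {WHOLE: 0.0, "midbrain": 3.5, "pons": 8.5,
            "medulla": 2.5, "scp": 0.14}


def _default_item_means():
    return {
        "female": {"low_mood": 0.24, "anhedonia": 0.20, "tenseness": 0.26, "tiredness": 0.65},
        "male": {"low_mood": 0.17, "anhedonia": 0.18, "tenseness": 0.22, "tiredness": 0.49},
    }


def _default_ethnicity_probs():
    return {"white": 0.9396, "mixed": 0.0291, "asian": 0.0205,
            "chinese": 0.0032, "black": 0.0031, "other": 0.0045}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults emulate the real cohort."""

    n_participants: int = 9289
    female_fraction: float = 0.518
    age_range: tuple[float, float] = (44.0, 79.0)
    age_mean: float = 62.4
    age_sd: float = 7.4
    scan_date_range: tuple[str, str] = ("2014-05-01", "2016-12-31")
    latitude_range: tuple[float, float] = (53.0, 53.9)   # band around the scanning centre
    longitude_range: tuple[float, float] = (-2.6, -1.9)
    ethnicity_probs: dict = field(default_factory=_default_ethnicity_probs)
    urban_fraction: float = 0.9272
    townsend_mean: float = -2.01
    townsend_sd: float = 2.56
    tbv_mean: float = 1125.92     # cm^3
    tbv_sd: float = 109.43
    gmv_mean: float = 628.04
    gmv_sd: float = 55.03
    wmv_mean: float = 498.57
    wmv_sd: float = 59.3
    volume_means: dict = field(default_factory=_default_volume_means)
    volume_sd: dict = field(default_factory=_default_volume_sd)
    true_amplitude: dict = field(default_factory=_default_amplitude)
    true_acrophase_month: float = 7.0
    path_a: dict = field(default_factory=_default_path_a)
    age_slope: dict = field(default_factory=_default_age_slope)
    tbv_slope: dict = field(default_factory=_default_tbv_slope)
    mediator_structure: str = WHOLE
    # log-rate change per mm^3 of the mediator / per hour of photoperiod
    path_b: dict = field(default_factory=lambda: {"female": -4.7e-5, "male": 0.0})
    path_c_prime: dict = field(default_factory=lambda: {"female": -0.023, "male": 0.0})
    affected_items: tuple[str, ...] = ("low_mood", "anhedonia")
    item_means: dict = field(default_factory=_default_item_means)
    dispersion: float = 0.8       # NB2 alpha of the symptom count model
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 1.0 <= self.true_acrophase_month < 13.0:
            raise ConfigError("true_acrophase_month must be in [1, 13)")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be increasing")
        for name, d in (("volume_sd", self.volume_sd),):
            if any(v < 0 for v in d.values()):
                raise ConfigError(f"{name} entries must be >= 0")
        for s in STRUCTURES:
            for name, d in (("volume_means", self.volume_means),
                            ("volume_sd", self.volume_sd),
                            ("true_amplitude", self.true_amplitude),
                            ("path_a", self.path_a),
                            ("age_slope", self.age_slope),
                            ("tbv_slope", self.tbv_slope)):
                if s not in d:
                    raise ConfigError(f"{name} is missing structure {s!r}")
        if self.mediator_structure not in STRUCTURES:
            raise ConfigError(f"mediator_structure {self.mediator_structure!r} unknown")
        for sex in ("female", "male"):
            if sex not in self.path_b or sex not in self.path_c_prime:
                raise ConfigError(f"path_b/path_c_prime must have a {sex!r} entry")
        start, end = (_dt.date.fromisoformat(str(d)) for d in self.scan_date_range)
        if start > end:
            raise ConfigError("scan_date_range must be increasing")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters actually used, for recovery tests.

    ``amplitude_total``/``path_a_total`` fold the whole-brainstem extra
    terms together with the substructure sums.  ``beta_true``/
    ``gamma_true`` are the cosinor coefficients implied by the configured
    amplitudes: beta = A cos(theta0), gamma = A sin(theta0) with
    theta0 = 2*pi*(phi-1)/12, so sqrt(beta^2+gamma^2) = A exactly.
    """

    config: GeneratorConfig
    acrophase_month: float
    amplitude_total: dict
    path_a_total: dict
    beta_true: dict
    gamma_true: dict
    indirect: dict   # per sex: path_a_total[mediator] * path_b[sex]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config"]["scan_date_range"] = [str(x) for x in d["config"]["scan_date_range"]]
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _truth_from_config(cfg: GeneratorConfig) -> SyntheticTruth:
    theta0 = 2.0 * np.pi * (cfg.true_acrophase_month - 1.0) / 12.0
    amp_total = dict(cfg.true_amplitude)
    amp_total[WHOLE] = cfg.true_amplitude[WHOLE] + sum(cfg.true_amplitude[p] for p in PARTS)
    pa_total = dict(cfg.path_a)
    pa_total[WHOLE] = cfg.path_a[WHOLE] + sum(cfg.path_a[p] for p in PARTS)
    beta = {s: amp_total[s] * np.cos(theta0) for s in STRUCTURES}
    gamma = {s: amp_total[s] * np.sin(theta0) for s in STRUCTURES}
    for s in STRUCTURES:
        assert abs(_amp_formula(beta[s], gamma[s]) - amp_total[s]) < 1e-9
    indirect = {sex: pa_total[cfg.mediator_structure] * cfg.path_b[sex]
                for sex in ("female", "male")}
    return SyntheticTruth(
        config=cfg,
        acrophase_month=cfg.true_acrophase_month,
        amplitude_total=amp_total,
        path_a_total=pa_total,
        beta_true={k: float(v) for k, v in beta.items()},
        gamma_true={k: float(v) for k, v in gamma.items()},
        indirect={k: float(v) for k, v in indirect.items()},
    )


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort table with the configured seasonal/mediation structure."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")
    lo, hi = cfg.age_range
    a_std = (lo - cfg.age_mean) / cfg.age_sd
    b_std = (hi - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(a_std, b_std, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=rng)

    start, end = (_dt.date.fromisoformat(str(d)) for d in cfg.scan_date_range)
    offsets = rng.integers(0, (end - start).days + 1, n)
    scan_date = np.array([start + _dt.timedelta(days=int(o)) for o in offsets])
    latitude = rng.uniform(*cfg.latitude_range, n)
    longitude = rng.uniform(*cfg.longitude_range, n)

    eth_levels = list(cfg.ethnicity_probs)
    eth_p = np.array([cfg.ethnicity_probs[k] for k in eth_levels], dtype=float)
    ethnicity = rng.choice(eth_levels, size=n, p=eth_p / eth_p.sum())
    living = np.where(rng.random(n) < cfg.urban_fraction, "urban", "rural")
    townsend = rng.normal(cfg.townsend_mean, cfg.townsend_sd, n)

    tbv = np.maximum(rng.normal(cfg.tbv_mean, cfg.tbv_sd, n), 500.0)
    gmv = np.maximum(rng.normal(cfg.gmv_mean, cfg.gmv_sd, n), 200.0)
    wmv = np.maximum(rng.normal(cfg.wmv_mean, cfg.wmv_sd, n), 150.0)

    photoperiod = np.array([day_length(la, lo_, d)
                            for la, lo_, d in zip(latitude, longitude, scan_date)])
    month = np.array([d.month for d in scan_date])
    theta0 = 2.0 * np.pi * (cfg.true_acrophase_month - 1.0) / 12.0
    seasonal_shape = np.cos(2.0 * np.pi * (month - 1) / 12.0 - theta0)

    def _structural(s):
        return (
            cfg.true_amplitude[s] * seasonal_shape
            + cfg.path_a[s] * (photoperiod - PHOTOPERIOD_REF)
            + cfg.age_slope[s] * (age - cfg.age_mean)
            + cfg.tbv_slope[s] * (tbv - cfg.tbv_mean)
        )

    volumes = {}
    for s in PARTS:
        v = cfg.volume_means[s] + _structural(s) + rng.normal(0, cfg.volume_sd[s], n)
        volumes[s] = np.maximum(v, 1.0)
    volumes[WHOLE] = (
        sum(volumes[p] for p in PARTS)
        + (cfg.volume_means[WHOLE] - sum(cfg.volume_means[p] for p in PARTS))
        + _structural(WHOLE)
        + rng.normal(0, cfg.volume_sd[WHOLE], n)
    )

    mediator = volumes[cfg.mediator_structure]
    med_center = cfg.volume_means[cfg.mediator_structure]
    items = {}
    for item in SYMPTOM_ITEMS:
        log_mu = np.array([np.log(cfg.item_means[s][item]) for s in sex])
        if item in cfg.affected_items:
            cprime = np.array([cfg.path_c_prime[s] for s in sex])
            bpath = np.array([cfg.path_b[s] for s in sex])
            log_mu = log_mu + cprime * (photoperiod - PHOTOPERIOD_REF) \
                + bpath * (mediator - med_center)
        mu = np.exp(log_mu)
        if cfg.dispersion > 0:
            lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * mu)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        items[item] = np.minimum(counts, 3).astype(int)

    table = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "scan_date": scan_date,
        "latitude": latitude,
        "longitude": longitude,
        "ethnicity": ethnicity,
        "living_area": living,
        "townsend": townsend,
        **items,
        "total_depressive": sum(items[i] for i in SYMPTOM_ITEMS),
        **{s: volumes[s] for s in STRUCTURES},
        "tbv": tbv,
        "gmv": gmv,
        "wmv": wmv,
    })[list(COLUMNS)]
    return table, _truth_from_config(cfg)


def validate_cohort(table: pd.DataFrame) -> None:
    """Raise :class:`CohortValidationError` if the schema is violated."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise CohortValidationError(f"missing column(s): {', '.join(missing)}")
    for item in SYMPTOM_ITEMS:
        vals = table[item]
        if vals.isna().any() or not np.isin(np.asarray(vals), [0, 1, 2, 3]).all():
            bad = table.index[~np.isin(np.asarray(vals), [0, 1, 2, 3])][:1]
            raise CohortValidationError(
                f"column {item!r} has score outside 0-3 (row {int(bad[0])})"
            )
    totals = sum(np.asarray(table[i]) for i in SYMPTOM_ITEMS)
    if not np.array_equal(totals, np.asarray(table["total_depressive"])):
        raise CohortValidationError("total_depressive is not the sum of the four items")
    for s in STRUCTURES:
        if table[s].isna().any() or (np.asarray(table[s], dtype=float) <= 0).any():
            raise CohortValidationError(f"column {s!r} has missing or non-positive volume")
    whole = np.asarray(table[WHOLE], dtype=float)
    for s in PARTS:
        if (np.asarray(table[s], dtype=float) >= whole).any():
            raise CohortValidationError(f"substructure {s!r} not smaller than whole brainstem")
    if (whole >= np.asarray(table["tbv"], dtype=float) * 1000.0).any():
        raise CohortValidationError("whole brainstem not smaller than TBV")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (ISO-8601 dates, lowercase categories)."""
    out = table.copy()
    out["scan_date"] = [d.isoformat() if hasattr(d, "isoformat") else str(d)
                        for d in out["scan_date"]]
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise CohortValidationError(f"malformed cohort file: {exc}") from exc
    if "scan_date" not in table.columns:
        raise CohortValidationError("missing column(s): scan_date")
    dates = []
    for i, v in enumerate(table["scan_date"]):
        try:
            dates.append(_dt.date.fromisoformat(str(v)))
        except ValueError as exc:
            raise CohortValidationError(
                f"bad scan_date {v!r} at line {i + 2}"
            ) from exc
    table["scan_date"] = dates
    validate_cohort(table)
    return table
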