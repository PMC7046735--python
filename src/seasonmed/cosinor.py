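"""Single-harmonic cosinor (seasonal rhythm) regression with a 12-month period.

The model regresses an outcome on cosine and sine transforms of the month
of measurement,

    y = mu + beta * cos(2*pi*(M-1)/12) + gamma * sin(2*pi*(M-1)/12) + covariates + e,

so that the fitted seasonal component is a sinusoid with amplitude
A = sqrt(beta^2 + gamma^2) (half the peak-to-trough range) and acrophase
(month of the peak) phi = 12 * atan2(gamma, beta) / (2*pi) + 1, wrapped
into [1, 13).  January (M=1) is the phase origin, so a positive cosine
coefficient alone peaks in January and a positive sine coefficient alone
peaks in April.

Seasonality is declared when (1) the cosine and/or sine term is
significant (two-sided p below ``alpha``, default 0.025) with amplitude
significantly greater than zero (one-sided Wald test via the delta
method), and (2) the model's AIC is lower than the AIC of the same model
without the cosine/sine pair (delta_aic < 0).

Standard errors are heteroskedasticity-robust (HC1 sandwich) by default.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError, FitError

__all__ = [
    "CosinorFit",
    "encode_month",
    "amplitude",
    "acrophase",
    "month_label",
    "fit_cosinor",
    "seasonality_decision",
]


@dataclass
class CosinorFit:
    """Result of a cosinor regression on one outcome."""

    beta: float                 # cosine coefficient, outcome units
    gamma: float                # sine coefficient, outcome units
    se_beta: float
    se_gamma: float
    p_beta: float
    p_gamma: float
    amplitude: float            # sqrt(beta^2 + gamma^2)
    se_amplitude: float         # delta-method SE
    p_amplitude: float          # one-sided p for amplitude > 0
    phi: float                  # acrophase, real month in [1, 13)
    acrophase_month_label: str
    aic_full: float
    aic_reduced: float
    delta_aic: float            # aic_full - aic_reduced; negative favours seasonality
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    seasonal: bool = False
    alpha: float = 0.025
    cov_type: str = "HC1"
    n: int = 0


def encode_month(month):
    """Sine and cosine transforms of month of scan.

    Parameters
    ----------
    month : int or array of int in 1..12

    Returns
    -------
    (sin_term, cos_term)
        sin(2*pi*(M-1)/12) and cos(2*pi*(M-1)/12); their squares sum to 1.
    """
    m = np.asarray(month)
    if np.any((m < 1) | (m > 12)) or not np.issubdtype(m.dtype, np.integer):
        raise ValueError("month must be an integer in 1..12")
    angle = 2.0 * np.pi * (m - 1) / 12.0
    if np.isscalar(month):
        return float(np.sin(angle)), float(np.cos(angle))
    return np.sin(angle), np.cos(angle)


def amplitude(beta: float, gamma: float) -> float:
    """Cosinor amplitude A = sqrt(beta^2 + gamma^2) (half peak-to-trough)."""
    return math.hypot(beta, gamma)


def month_label(phi: float) -> str:
    """Calendar month name for a real-valued acrophase (round half up)."""
    m = int(math.floor(phi + 0.5))
    return calendar.month_name[(m - 1) % 12 + 1]


def acrophase(beta: float, gamma: float) -> tuple[float, str]:
    """Acrophase: the month at which the fitted sinusoid peaks.

    Uses the quadrant-aware arctangent atan2(gamma, beta) so that all four
    sign combinations of (beta, gamma) map to the correct month, and wraps
    the result into [1, 13).

    Returns
    -------
    (phi, label)
        Real month of the peak and its calendar-month name.
    """
    if beta == 0.0 and gamma == 0.0:
        raise DegenerateDataError("acrophase undefined for zero amplitude")
    angle = math.atan2(gamma, beta) % (2.0 * math.pi)
    phi = 12.0 * angle / (2.0 * math.pi) + 1.0
    if phi >= 13.0:
        phi -= 12.0
    return phi, month_label(phi)


def _as_covariate_frame(covariates, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    if isinstance(covariates, pd.DataFrame):
        return covariates.reset_index(drop=True)
    return pd.DataFrame({k: np.asarray(v) for k, v in covariates.items()})


def fit_cosinor(
    outcome,
    month,
    covariates=None,
    alpha: float = 0.025,
    cov_type: str = "HC1",
) -> CosinorFit:
    """Fit the cosinor model and apply the two-criterion seasonality test.

    Parameters
    ----------
    outcome : array-like
        Continuous outcome (e.g. a volume in mm^3).
    month : array-like of int in 1..12
        Month of measurement per observation.
    covariates : mapping or DataFrame, optional
        Adjustment covariates (e.g. age and total brain volume); entered
        in both the full and the reduced (no sine/cosine) model.
    alpha : float
        Significance level for the cosinor-term criterion (two-sided on
        each term; one-sided on the amplitude).
    cov_type : str
        statsmodels covariance type for the sandwich SEs.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    sin_t, cos_t = encode_month(np.asarray(month))
    cov = _as_covariate_frame(covariates, n)
    X = pd.DataFrame({"const": np.ones(n), "cos": cos_t, "sin": sin_t})
    for c in cov.columns:
        X[c] = np.asarray(cov[c], dtype=float)
    if n <= X.shape[1]:
        raise FitError(f"n={n} too small for {X.shape[1]} parameters")
    if len(np.unique(np.asarray(month))) < 3:
        raise FitError("months must span at least 3 distinct values")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitError("rank-deficient design matrix")

    full = sm.GLM(y, X, family=sm.families.Gaussian()).fit(cov_type=cov_type)
    reduced = sm.GLM(y, X.drop(columns=["cos", "sin"]), family=sm.families.Gaussian()).fit(
        cov_type=cov_type
    )

    beta, gamma = float(full.params["cos"]), float(full.params["sin"])
    V = full.cov_params().loc[["cos", "sin"], ["cos", "sin"]].to_numpy()
    amp = amplitude(beta, gamma)
    if amp > 0:
        grad = np.array([beta, gamma]) / amp
        se_amp = float(np.sqrt(grad @ V @ grad))
        p_amp = float(stats.norm.sf(amp / se_amp)) if se_amp > 0 else 0.0
        phi, label = acrophase(beta, gamma)
    else:
        se_amp, p_amp, phi, label = 0.0, 1.0, float("nan"), ""

    fit = CosinorFit(
        beta=beta,
        gamma=gamma,
        se_beta=float(full.bse["cos"]),
        se_gamma=float(full.bse["sin"]),
        p_beta=float(full.pvalues["cos"]),
        p_gamma=float(full.pvalues["sin"]),
        amplitude=amp,
        se_amplitude=se_amp,
        p_amplitude=p_amp,
        phi=phi,
        acrophase_month_label=label,
        aic_full=float(full.aic),
        aic_reduced=float(reduced.aic),
        delta_aic=float(full.aic - reduced.aic),
        covariate_coefficients={c: float(full.params[c]) for c in X.columns if c not in ("cos", "sin")},
        alpha=alpha,
        cov_type=cov_type,
        n=n,
    )
    fit.seasonal = seasonality_decision(fit)[0]
    return fit


def seasonality_decision(fit: CosinorFit) -> tuple[bool, dict]:
    """Apply the two seasonality criteria to a fitted cosinor model.

    Criterion 1: cosine and/or sine term significant at ``fit.alpha``
    (two-sided) AND amplitude significantly greater than zero (one-sided
    Wald at the same level).  Criterion 2: the cosinor model has a lower
    AIC than the covariate-only model (delta_aic < 0).  Both must hold.

    Returns the verdict and a per-criterion report.
    """
    terms_significant = fit.p_beta < fit.alpha or fit.p_gamma < fit.alpha
    amplitude_positive = fit.p_amplitude < fit.alpha
    aic_improved = fit.delta_aic < 0
    report = {
        "cosinor_terms_significant": terms_significant,
        "amplitude_gt_zero": amplitude_positive,
        "aic_improved": aic_improved,
        "alpha": fit.alpha,
        "p_beta": fit.p_beta,
        "p_gamma": fit.p_gamma,
        "p_amplitude": fit.p_amplitude,
        "delta_aic": fit.delta_aic,
    }
    return terms_significant and amplitude_positive and aic_improved, report
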