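"""Three-variable path mediation with product-of-coefficients indirect effects.

The model asks whether an exposure (photoperiod, hours) acts on a count
outcome (a symptom score) through a mediator (a brainstem volume, mm^3):

    a  : mediator on exposure, from a linear model (mm^3 per hour)
    b  : outcome on mediator, exposure held fixed, from a log-link count
         model (log-rate per mm^3)
    c' : outcome on exposure, mediator held fixed (direct effect)
    c  : outcome on exposure without the mediator (total effect)

The indirect effect is the product a*b.  Its confidence interval comes
from a nonparametric bias-corrected and accelerated (BCa) bootstrap:
participants are resampled with replacement, the a and b paths are refit
per resample, the bias-correction constant z0 is the normal quantile of
the fraction of resampled estimates below the full-sample estimate, and
the acceleration constant comes from the skewness of (delete-group)
jackknife estimates.  A two-sided bootstrap p-value is defined as the
smallest 1 - level at which the BCa interval excludes zero.

Count outcomes use the NB2 negative-binomial model by default; an
identity-link Gaussian mode (``family="gaussian"``) exists as a
linear-path oracle in which c = c' + a*b holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .count_regression import _fit_count_ml, build_design, _validate_counts, nb2_point_refit
from .errors import BootstrapError, DegenerateDataError, FitError

__all__ = [
    "PathModel",
    "BootstrapCI",
    "RequirementsChecklist",
    "fit_paths",
    "mediation_requirements",
    "bca_interval",
    "bca_bootstrap_indirect",
]


@dataclass
class PathModel:
    """Fitted paths of one exposure -> mediator -> outcome triple."""

    exposure: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...]
    a: float
    se_a: float
    p_a: float
    b_path: float
    se_b: float
    p_b: float
    c: float
    se_c: float
    p_c: float
    c_prime: float
    se_c_prime: float
    p_c_prime: float
    indirect: float          # a * b_path
    family: str = "nb"
    n: int = 0


@dataclass
class RequirementsChecklist:
    """Outcome of the classical mediation eligibility checks."""

    exposure_mediator: bool       # a-path significant
    mediator_outcome: bool        # b-path significant
    attenuation: bool             # |c'| < |c|
    direct_nonsignificant: bool   # exposure effect no longer significant
    eligible: bool
    alpha: float = 0.05


@dataclass
class BootstrapCI:
    """BCa bootstrap interval for the indirect effect."""

    estimate: float
    n_boot: int
    level: float
    ll: float
    ul: float
    z0: float
    accel: float
    p_boot: float
    significant: bool
    seed: int | None = None
    n_failed: int = 0
    boot_se: float = 0.0


def _design_frames(table: pd.DataFrame, exposure, mediator, outcome, covariates):
    n = len(table)
    cov = table[list(covariates)] if covariates else None
    Xcov = build_design(cov, n)
    x = np.asarray(table[exposure], dtype=float)
    m = np.asarray(table[mediator], dtype=float)
    y = np.asarray(table[outcome], dtype=float)
    return y, x, m, Xcov


def _paths_from_arrays(y, x, m, Xcov, family: str, warm=None, cov_type="nonrobust"):
    """Fit the a and b paths only; fast core shared with the bootstrap.

    Returns (a, b, warm_params) where warm_params seeds the next NB fit.
    """
    Xm = np.column_stack([Xcov, x])          # mediator model design
    coef, *_ = np.linalg.lstsq(Xm, m, rcond=None)
    a = float(coef[-1])
    Xy = np.column_stack([Xcov, x, m])       # outcome model design
    if family == "gaussian":
        coefy, *_ = np.linalg.lstsq(Xy, y, rcond=None)
        return a, float(coefy[-1]), None
    if family == "nb" and warm is not None:
        # fast warm-start Newton refit: point estimates are all a resample needs
        params = nb2_point_refit(y, Xy, warm)
        b = float(params[-2])
        if not np.isfinite(b):
            raise FitError("mediator coefficient not identified in refit")
        return a, b, params
    params, _, _, _, _ = _fit_count_ml(y, Xy, model=family, start_params=warm,
                                       cov_type="nonrobust")
    return a, float(params[-1 if family == "poisson" else -2]), params


def fit_paths(
    table: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates=(),
    family: str = "nb",
    cov_type: str = "HC1",
) -> PathModel:
    """Fit all four paths (a, b, c, c') on the full sample.

    ``family`` selects the outcome model: "nb" (NB2, default), "poisson",
    or "gaussian" (identity link; linear-path oracle mode).  Any grouping
    (e.g. by sex) is done by the caller before this is invoked.
    """
    y, x, m, Xcov = _design_frames(table, exposure, mediator, outcome, covariates)
    if np.std(m) == 0:
        raise DegenerateDataError(f"mediator {mediator!r} is constant")
    n = len(y)

    # a-path: linear model of mediator on exposure + covariates
    Xa = Xcov.copy()
    Xa[exposure] = x
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_a = sm.OLS(m, Xa).fit(cov_type=cov_type)
    a, se_a, p_a = (float(res_a.params[exposure]), float(res_a.bse[exposure]),
                    float(res_a.pvalues[exposure]))

    def _outcome_model(with_mediator: bool):
        cols = list(Xcov.columns) + [exposure] + ([mediator] if with_mediator else [])
        X = np.column_stack([Xcov, x, m] if with_mediator else [Xcov, x])
        if family == "gaussian":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.OLS(y, pd.DataFrame(X, columns=cols)).fit(cov_type=cov_type)
            params = np.asarray(res.params)
            ses = np.asarray(res.bse)
            ps = np.asarray(res.pvalues)
            return params, ses, ps, cols
        _validate_counts(y)
        params, cov, _, _, converged = _fit_count_ml(y, X, model=family, cov_type=cov_type)
        if cov is None:
            raise FitError("outcome model covariance unavailable")
        ses = np.sqrt(np.diag(cov))
        z = params / np.where(ses > 0, ses, np.inf)
        ps = 2 * stats.norm.sf(np.abs(z))
        return params, ses, ps, cols + ([] if family == "gaussian" else ["alpha"])

    params_f, ses_f, ps_f, cols_f = _outcome_model(True)
    jx, jm = cols_f.index(exposure), cols_f.index(mediator)
    params_t, ses_t, ps_t, cols_t = _outcome_model(False)
    jc = cols_t.index(exposure)

    b = float(params_f[jm])
    return PathModel(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        covariates=tuple(covariates),
        a=a, se_a=se_a, p_a=p_a,
        b_path=b, se_b=float(ses_f[jm]), p_b=float(ps_f[jm]),
        c=float(params_t[jc]), se_c=float(ses_t[jc]), p_c=float(ps_t[jc]),
        c_prime=float(params_f[jx]), se_c_prime=float(ses_f[jx]),
        p_c_prime=float(ps_f[jx]),
        indirect=a * b,
        family=family,
        n=n,
    )


def mediation_requirements(paths: PathModel, alpha: float = 0.05) -> RequirementsChecklist:
    """Classical eligibility checks before formally testing an indirect effect.

    Requires (1) exposure-mediator association (a-path significant), (2)
    mediator-outcome association (b-path significant), and (3) attenuation
    of the exposure effect once the mediator is added (|c'| < |c|).
    Whether the direct effect also loses significance is reported but not
    required, since with large samples a genuine partial mediation can
    leave a significant direct effect.
    """
    req1 = paths.p_a < alpha
    req2 = paths.p_b < alpha
    attenuated = abs(paths.c_prime) < abs(paths.c)
    nonsig = paths.p_c_prime >= alpha
    return RequirementsChecklist(
        exposure_mediator=req1,
        mediator_outcome=req2,
        attenuation=attenuated,
        direct_nonsignificant=nonsig,
        eligible=bool(req1 and req2 and attenuated),
        alpha=alpha,
    )


def bca_interval(theta_hat: float, boot: np.ndarray, jack: np.ndarray | None,
                 level: float = 0.95, z0: float | None = None,
                 accel: float | None = None) -> tuple[float, float, float, float]:
    """BCa-adjusted percentile interval from a bootstrap distribution.

    Parameters
    ----------
    theta_hat : float
        Full-sample point estimate.
    boot : array
        Bootstrap replicate estimates.
    jack : array or None
        Jackknife (leave-one/group-out) estimates for the acceleration;
        required unless ``accel`` is given.
    z0, accel : float, optional
        Override the bias-correction / acceleration constants (passing
        0.0 for both reduces the interval to the plain percentile one).

    Returns (ll, ul, z0, accel).
    """
    boot = np.asarray(boot, dtype=float)
    B = len(boot)
    if B == 0:
        raise BootstrapError("empty bootstrap distribution")
    if np.all(boot == boot[0]):
        return float(boot[0]), float(boot[0]), 0.0, 0.0
    if z0 is None:
        frac = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / B
        frac = np.clip(frac, 1.0 / (B + 1), B / (B + 1))
        z0 = float(stats.norm.ppf(frac))
    if accel is None:
        if jack is None:
            raise ValueError("jackknife estimates required when accel is not given")
        jack = np.asarray(jack, dtype=float)
        d = jack.mean() - jack
        denom = np.sum(d * d) ** 1.5
        accel = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0
    alpha = 1.0 - level
    lo, hi = alpha / 2.0, 1.0 - alpha / 2.0
    adj = []
    for q in (lo, hi):
        zq = stats.norm.ppf(q)
        num = z0 + zq
        adj.append(float(stats.norm.cdf(z0 + num / (1.0 - accel * num))))
    ll, ul = np.quantile(boot, adj[0]), np.quantile(boot, adj[1])
    return float(ll), float(ul), float(z0), float(accel)


def _bca_pvalue(boot: np.ndarray, z0: float, accel: float) -> float:
    """Two-sided p: smallest 1-level at which the BCa interval excludes 0."""
    B = len(boot)
    G0 = (np.sum(boot < 0.0) + 0.5 * np.sum(boot == 0.0)) / B
    G0 = np.clip(G0, 1.0 / (B + 1), B / (B + 1))
    w = stats.norm.ppf(G0)
    # invert the BCa quantile map at zero: w = z0 + (z0+z)/(1-a(z0+z))
    u = (w - z0) / (1.0 + accel * (w - z0))
    z = u - z0
    p_one = stats.norm.cdf(z)
    return float(2.0 * min(p_one, 1.0 - p_one))


def bca_bootstrap_indirect(
    table: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates=(),
    family: str = "nb",
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    jackknife_groups: int | None = 100,
    max_failure_fraction: float = 0.10,
) -> BootstrapCI:
    """BCa bootstrap confidence interval for the indirect effect a*b.

    Participants (rows) are resampled with replacement ``n_boot`` times;
    the a and b paths are refit per resample (warm-started from the
    full-sample fit).  ``jackknife_groups`` controls the delete-group
    jackknife used for the acceleration constant (None = leave-one-out).
    Deterministic given ``seed``.
    """
    y, x, m, Xcov = _design_frames(table, exposure, mediator, outcome, covariates)
    n = len(y)
    Xc = Xcov.to_numpy()
    a_hat, b_hat, warm = _paths_from_arrays(y, x, m, Xc, family)
    theta_hat = a_hat * b_hat

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    failed = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            a_s, b_s, _ = _paths_from_arrays(y[idx], x[idx], m[idx], Xc[idx], family,
                                             warm=warm)
            boot[kept] = a_s * b_s
            kept += 1
        except Exception:
            failed += 1
    if failed > max_failure_fraction * n_boot:
        raise BootstrapError(f"{failed} of {n_boot} bootstrap resamples failed")
    boot = boot[:kept]

    g = n if jackknife_groups is None else min(jackknife_groups, n)
    jack = np.empty(g)
    groups = np.arange(n) % g
    for k in range(g):
        keep = groups != k
        a_j, b_j, _ = _paths_from_arrays(y[keep], x[keep], m[keep], Xc[keep], family,
                                         warm=warm)
        jack[k] = a_j * b_j

    ll, ul, z0, accel = bca_interval(theta_hat, boot, jack, level=level)
    p = _bca_pvalue(boot, z0, accel) if not np.all(boot == boot[0]) else 1.0
    return BootstrapCI(
        estimate=float(theta_hat),
        n_boot=n_boot,
        level=level,
        ll=ll,
        ul=ul,
        z0=z0,
        accel=accel,
        p_boot=p,
        significant=bool(ll > 0.0 or ul < 0.0),
        seed=seed,
        n_failed=failed,
        boot_se=float(np.std(boot, ddof=1)) if kept > 1 else 0.0,
    )
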