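"""Count-outcome regression of symptom scores and volume/photoperiod models.

Symptom items (0-3 frequency codes) and the total score (0-12) are
modelled as unbounded counts with a log link, matching how PHQ-style
items are analysed when they are overdispersed: a negative-binomial (NB2)
model with maximum-likelihood dispersion, heteroskedasticity-robust (HC1)
standard errors, and incidence rate ratios IRR = exp(b).

Also provided: an overdispersion check (variance/mean ratio plus a
boundary-corrected likelihood-ratio test of NB against Poisson), a
hierarchical (blocked) linear regression of volumes on photoperiod with
incremental R^2, and the Bonferroni adjustment.

Categorical covariates (e.g. ethnicity, urban/rural living area) enter as
indicator contrasts with the most frequent category as the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

from .errors import DegenerateDataError, FitError

__all__ = [
    "NBFit",
    "LinFit",
    "OverdispersionResult",
    "build_design",
    "fit_nb",
    "overdispersion_check",
    "fit_volume_photoperiod",
    "bonferroni",
]


@dataclass
class NBFit:
    """Negative-binomial regression summary for one predictor of interest."""

    b: float            # log-rate coefficient of the predictor
    se: float           # robust SE
    irr: float          # exp(b)
    p: float
    dispersion: float   # NB2 alpha (0 for the Poisson special case)
    n: int
    covariate_set: tuple[str, ...] = ()
    params: dict[str, float] = field(default_factory=dict)
    cov_type: str = "HC1"
    converged: bool = True


@dataclass
class LinFit:
    """Hierarchical linear regression summary for photoperiod on a volume."""

    r: float            # standardized association, sign(B) * sqrt(incremental R^2)
    B: float            # regression coefficient, outcome units per hour
    se: float
    p: float
    r2: float           # incremental R^2 attributable to photoperiod
    r2_total: float
    block_structure: tuple[tuple[str, ...], ...] = ()
    block_r2: tuple[float, ...] = ()
    n: int = 0


@dataclass
class OverdispersionResult:
    ratio: float            # variance / mean of the raw outcome
    lr_stat: float          # 2 * (llf_NB - llf_Poisson), floored at 0
    p: float                # boundary-corrected (0.5 * chi2_1) p-value
    overdispersed: bool


def build_design(covariates, n: int, add_const: bool = True) -> pd.DataFrame:
    """Numeric design matrix from a mapping/DataFrame of covariates.

    Object/category columns become indicator contrasts dropping the most
    frequent level (the reference).  Numeric columns pass through.
    """
    X = pd.DataFrame(index=range(n))
    if add_const:
        X["const"] = 1.0
    if covariates is None:
        return X
    cov = covariates if isinstance(covariates, pd.DataFrame) else pd.DataFrame(dict(covariates))
    cov = cov.reset_index(drop=True)
    for c in cov.columns:
        col = cov[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = col.value_counts().idxmax()
            for level in sorted(v for v in col.unique() if v != ref):
                X[f"{c}[{level}]"] = (col == level).astype(float).to_numpy()
        else:
            X[c] = np.asarray(col, dtype=float)
    return X


def _scale_design(X: np.ndarray):
    """Center/scale non-constant columns; return scaled X and the maps back.

    Raw covariates such as mm^3 volumes make the NB Newton steps overflow;
    the fit runs on standardized columns and coefficients/covariance are
    mapped back to the original scale afterwards.
    """
    n, k = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd < 1e-12
    mu[const] = 0.0
    sd[const] = 1.0
    Xs = (X - mu) / sd
    Xs[:, const] = X[:, const]
    return Xs, mu, sd, const


def _unscale_params(params, cov, mu, sd, const, k):
    """Map (coef..., alpha) from the scaled design back to raw units."""
    # beta_raw_j = beta_s_j / sd_j ; the constant column absorbs the shifts
    J = np.zeros((len(params), len(params)))
    iconst = int(np.flatnonzero(const)[0]) if const.any() else None
    for j in range(k):
        if const[j]:
            J[j, j] = 1.0
        else:
            J[j, j] = 1.0 / sd[j]
    if iconst is not None:
        for j in range(k):
            if not const[j]:
                J[iconst, j] = -mu[j] / sd[j]
    for j in range(k, len(params)):  # dispersion parameter(s) unchanged
        J[j, j] = 1.0
    raw = J @ params
    raw_cov = J @ cov @ J.T if cov is not None else None
    return raw, raw_cov


def _separated_columns(y, X) -> list[int]:
    """Indicator columns whose members all have zero outcome.

    The ML coefficient of such a contrast is unbounded (the level
    perfectly predicts a zero count), which derails the NB likelihood;
    those columns are excluded from the fit and reported as NaN.
    """
    drop = []
    for j in range(X.shape[1]):
        col = X[:, j]
        uniq = np.unique(col)
        if len(uniq) == 2 and uniq[0] == 0.0 and uniq[1] == 1.0:
            if y[col == 1.0].sum() == 0:
                drop.append(j)
    return drop


def _dropped_columns(y, X) -> list[int]:
    """Columns that must leave the design before a count-model fit.

    Separated indicator levels (see :func:`_separated_columns`) plus
    degenerate columns (e.g. an indicator level absent from a bootstrap
    resample), keeping a single constant column as the intercept.
    """
    dropped = set(_separated_columns(y, X))
    seen_const = False
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            if X[0, j] != 0.0 and not seen_const:
                seen_const = True
            else:
                dropped.add(j)
    return sorted(dropped)


def _fit_count_ml(y, X, model: str = "nb", start_params=None, cov_type: str = "HC1"):
    """Fit an NB2 or Poisson count model on a scaled design.

    Returns (params, cov, llf, alpha, converged) on the raw scale, where
    ``alpha`` is the NB2 dispersion (0 for Poisson).  Entries for
    separated indicator columns are NaN.
    """
    y = np.asarray(y, dtype=float)
    Xfull = np.asarray(X, dtype=float)
    nfull, kfull = Xfull.shape
    dropped = _dropped_columns(y, Xfull)
    if start_params is not None:
        start_params = np.nan_to_num(np.asarray(start_params, dtype=float))
    if dropped:
        keep = [j for j in range(kfull) if j not in dropped]
        params, cov, llf, alpha, conv = _fit_count_ml(
            y, Xfull[:, keep], model=model,
            start_params=None if start_params is None else np.concatenate(
                [np.asarray(start_params)[keep], np.asarray(start_params)[kfull:]]),
            cov_type=cov_type,
        )
        extra = len(params) - len(keep)          # trailing dispersion slot(s)
        full_idx = keep + list(range(kfull, kfull + extra))
        out_p = np.full(kfull + extra, np.nan)
        out_p[full_idx] = params
        out_c = None
        if cov is not None:
            out_c = np.full((kfull + extra, kfull + extra), np.nan)
            out_c[np.ix_(full_idx, full_idx)] = cov
        return out_p, out_c, llf, alpha, conv
    Xr = Xfull
    n, k = Xr.shape
    Xs, mu, sd, const = _scale_design(Xr)

    fit_kw = {} if cov_type == "nonrobust" else {"cov_type": cov_type}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if model == "poisson":
            res = Poisson(y, Xs).fit(disp=0, maxiter=200, **fit_kw)
            params_s = np.asarray(res.params)
            cov_s = np.asarray(res.cov_params())
            raw, raw_cov = _unscale_params(params_s, cov_s, mu, sd, const, k)
            return raw, raw_cov, float(res.llf), 0.0, bool(res.mle_retvals.get("converged", True))

        pois = None
        if start_params is None:
            pois = Poisson(y, Xs).fit(disp=0, maxiter=200, **fit_kw)
            start = np.append(np.asarray(pois.params), 0.1)
        else:
            start = np.asarray(start_params, dtype=float).copy()
            start[:k] = start[:k] * sd[:k]
            if const.any():
                icon = int(np.flatnonzero(const)[0])
                start[icon] = start[icon] + np.sum(
                    np.asarray(start_params[:k]) * mu[:k]
                )
            start[-1] = max(start[-1], 1e-3)
        mod = NegativeBinomial(y, Xs, loglike_method="nb2")
        res = None
        for method, kwargs in (("newton", {}), ("bfgs", {"maxiter": 500})):
            try:
                cand = mod.fit(start_params=start, method=method, disp=0,
                               warn_convergence=False, **fit_kw, **kwargs)
            except Exception:
                continue
            if np.all(np.isfinite(cand.params)) and cand.params[-1] > 0:
                res = cand
                if cand.mle_retvals.get("converged", False):
                    break
        if res is None or not np.all(np.isfinite(res.params)) or res.params[-1] <= 1e-8:
            # dispersion on the boundary: the Poisson fit is the MLE limit
            if pois is None:
                pois = Poisson(y, Xs).fit(disp=0, maxiter=200, **fit_kw)
            params_s = np.append(np.asarray(pois.params), 0.0)
            cov_p = np.asarray(pois.cov_params())
            cov_s = np.zeros((k + 1, k + 1))
            cov_s[:k, :k] = cov_p
            raw, raw_cov = _unscale_params(params_s, cov_s, mu, sd, const, k)
            return raw, raw_cov, float(pois.llf), 0.0, True
        try:
            cov_s = np.asarray(res.cov_params())
        except Exception:
            cov_s = None
        if cov_s is None or not np.all(np.isfinite(cov_s)):
            cov_s = None
        raw, raw_cov = _unscale_params(
            np.asarray(res.params), cov_s, mu, sd, const, k
        )
        return raw, raw_cov, float(res.llf), float(raw[-1]), bool(
            res.mle_retvals.get("converged", False)
        )


def _nb2_point_fit(y, X, start, max_cycles: int = 60, tol: float = 1e-9):
    """Warm-start NB2 maximum-likelihood point estimation (no covariance).

    Block Newton on the regression coefficients alternating with a 1-D
    Newton step for log(alpha).  Used for the thousands of bootstrap
    refits, where the statsmodels overhead dominates; the full-sample
    fits (and all reported covariances) still come from statsmodels, and
    a unit test pins this solver to the statsmodels optimum.
    """
    from scipy.special import psi

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.array(start[:k], dtype=float)
    la = float(np.log(np.clip(start[k] if len(start) > k else 0.5, 1e-6, 1e2)))
    la_lo, la_hi = np.log(1e-6), np.log(1e2)

    # counts take few distinct values (0-3 items), so the digamma sum
    # collapses to a handful of evaluations
    ymax = int(y.max())
    ycounts = np.bincount(y.astype(int), minlength=ymax + 1) if ymax <= 64 else None
    yvals = np.arange(ymax + 1, dtype=float)

    def dll_dla(la_val, mu):
        a = np.exp(-la_val)            # a = 1/alpha
        if ycounts is not None:
            psi_sum = float(ycounts @ psi(yvals + a))
        else:
            psi_sum = psi(y + a).sum()
        dll_da = (psi_sum - n * psi(a) + n * np.log(a) + n
                  - np.log(a + mu).sum() - ((a + y) / (a + mu)).sum())
        return -a * dll_da

    for _ in range(max_cycles):
        a = np.exp(-la)
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        s = a * (y - mu) / (a + mu)
        w = a * mu * (a + y) / (a + mu) ** 2
        g = X.T @ s
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular design in count-model refit") from exc
        beta = beta + step
        mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
        f0 = dll_dla(la, mu)
        h = 1e-4
        fp = (dll_dla(la + h, mu) - dll_dla(la - h, mu)) / (2 * h)
        dla = -f0 / fp if fp < 0 else np.sign(f0) * 0.5
        dla = float(np.clip(dla, -1.0, 1.0))
        la = float(np.clip(la + dla, la_lo, la_hi))
        if not np.all(np.isfinite(beta)) or not np.isfinite(la):
            raise FitError("count-model refit diverged")
        if max(np.max(np.abs(step)), abs(dla)) < tol * (1.0 + np.max(np.abs(beta))):
            break
    return np.append(beta, np.exp(la))


def nb2_point_refit(y, X, warm) -> np.ndarray:
    """Raw-scale NB2 point estimates [coef..., alpha] with NaN for columns
    dropped by the separation/degeneracy guard.  ``warm`` is a raw-scale
    parameter vector, typically from a full-sample statsmodels fit."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    keep = [j for j in range(k) if j not in _dropped_columns(y, X)]
    Xk = X[:, keep]
    Xs, mu, sd, const = _scale_design(Xk)
    warm = np.nan_to_num(np.asarray(warm, dtype=float))
    beta_raw = warm[keep]
    start = beta_raw * sd
    if const.any():
        icon = int(np.flatnonzero(const)[0])
        start[icon] = beta_raw[icon] + float(np.sum(beta_raw * mu))
    start = np.append(start, warm[-1] if len(warm) > k else 0.5)
    params_s = _nb2_point_fit(y, Xs, start)
    out = np.full(k + 1, np.nan)
    beta_s = params_s[:-1]
    beta_back = beta_s / sd
    if const.any():
        icon = int(np.flatnonzero(const)[0])
        nc = ~const
        beta_back[icon] = beta_s[icon] - float(np.sum(beta_s[nc] * mu[nc] / sd[nc]))
    out[np.asarray(keep)] = beta_back
    out[-1] = params_s[-1]
    return out


def _validate_counts(outcome) -> np.ndarray:
    y = np.asarray(outcome)
    yf = np.asarray(y, dtype=float)
    if np.any(yf < 0) or np.any(yf != np.round(yf)):
        raise ValueError("count outcome must contain non-negative integers")
    return yf


def fit_nb(
    outcome,
    predictor,
    covariates=None,
    predictor_name: str = "predictor",
    cov_type: str = "HC1",
    dispersion: float | None = None,
) -> NBFit:
    """Negative-binomial (log-link) regression of a count outcome.

    Parameters
    ----------
    outcome : array-like of non-negative integers
    predictor : array-like
        The exposure of interest (e.g. photoperiod in hours); its
        coefficient ``b``, robust SE, IRR = exp(b) and p-value are
        reported.
    covariates : mapping or DataFrame, optional
        Adjustment covariates; categoricals are expanded to indicators.
    dispersion : float, optional
        If 0, fit a Poisson model (the NB2 limit); if None (default),
        estimate the NB2 dispersion by maximum likelihood.
    """
    y = _validate_counts(outcome)
    n = len(y)
    X = build_design(covariates, n)
    X.insert(1, predictor_name, np.asarray(predictor, dtype=float))
    if n <= X.shape[1]:
        raise FitError(f"n={n} too small for {X.shape[1]} parameters")
    model = "poisson" if dispersion == 0 else "nb"
    params, cov, _llf, alpha, converged = _fit_count_ml(y, X.to_numpy(), model=model,
                                                        cov_type=cov_type)
    if cov is None:
        raise FitError("negative binomial fit did not converge "
                       "(no usable covariance); check for degenerate predictors")
    names = list(X.columns) + ([] if model == "poisson" else ["alpha"])
    j = names.index(predictor_name)
    b = float(params[j])
    if not np.isfinite(b):
        raise FitError(f"coefficient of {predictor_name!r} is not identified")
    se = float(np.sqrt(cov[j, j]))
    z = b / se if se > 0 else np.inf * np.sign(b)
    return NBFit(
        b=b,
        se=se,
        irr=float(np.exp(b)),
        p=float(2 * stats.norm.sf(abs(z))),
        dispersion=float(alpha),
        n=n,
        covariate_set=tuple(c for c in X.columns if c not in ("const", predictor_name)),
        params={nm: float(v) for nm, v in zip(names, params)},
        cov_type=cov_type,
        converged=converged,
    )


def overdispersion_check(outcome, covariates=None, alpha_level: float = 0.05) -> OverdispersionResult:
    """Check whether a count outcome is overdispersed relative to Poisson.

    Reports the raw variance/mean ratio and a likelihood-ratio test of the
    NB2 model against the nested Poisson model (same covariates).  Because
    the dispersion parameter is tested on the boundary of its space, the
    p-value uses the 0.5*chi-square(1) mixture.  The verdict is True when
    the LR test rejects and the variance exceeds the mean.
    """
    y = _validate_counts(outcome)
    if np.all(y == 0):
        raise DegenerateDataError("all-zero outcome: dispersion undefined")
    mean = float(np.mean(y))
    var = float(np.var(y, ddof=1))
    ratio = var / mean
    if var == 0:
        return OverdispersionResult(ratio=0.0, lr_stat=0.0, p=1.0, overdispersed=False)
    X = build_design(covariates, len(y))
    _, _, llf_p, _, _ = _fit_count_ml(y, X.to_numpy(), model="poisson", cov_type="nonrobust")
    _, _, llf_nb, disp, _ = _fit_count_ml(y, X.to_numpy(), model="nb", cov_type="nonrobust")
    lr = max(0.0, 2.0 * (llf_nb - llf_p))
    p = 0.5 * float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    return OverdispersionResult(
        ratio=ratio,
        lr_stat=lr,
        p=p,
        overdispersed=bool(p < alpha_level and ratio > 1.0),
    )


def fit_volume_photoperiod(volume, photoperiod, blocks) -> LinFit:
    """Hierarchical (blocked) linear regression of a volume on photoperiod.

    Covariate blocks are entered in order (e.g. [["age"], ["tbv"]]) and
    photoperiod is entered last; the reported B (mm^3/hour), SE and p come
    from the final model, the incremental R^2 is the gain from adding
    photoperiod, and r = sign(B) * sqrt(incremental R^2) is the
    standardized association on the Pearson scale.

    ``blocks`` is an ordered sequence of mappings/DataFrames (one per
    block).
    """
    y = np.asarray(volume, dtype=float)
    n = len(y)
    if not blocks:
        raise ValueError("blocks must be a non-empty ordered sequence")
    X = build_design(None, n)
    block_names: list[tuple[str, ...]] = []
    block_r2: list[float] = []
    for blk in blocks:
        Xb = build_design(blk, n, add_const=False)
        block_names.append(tuple(Xb.columns))
        for c in Xb.columns:
            X[c] = Xb[c]
        res = sm.OLS(y, X).fit()
        block_r2.append(float(res.rsquared))
    r2_before = block_r2[-1]
    X["photoperiod"] = np.asarray(photoperiod, dtype=float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitError("collinear design: photoperiod block is rank deficient")
    final = sm.OLS(y, X).fit()
    r2_total = float(final.rsquared)
    r2_inc = max(0.0, r2_total - r2_before)
    B = float(final.params["photoperiod"])
    return LinFit(
        r=float(np.sign(B) * np.sqrt(r2_inc)) if B != 0 else 0.0,
        B=B,
        se=float(final.bse["photoperiod"]),
        p=float(final.pvalues["photoperiod"]),
        r2=r2_inc,
        r2_total=r2_total,
        block_structure=tuple(block_names),
        block_r2=tuple(block_r2),
        n=n,
    )


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
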