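"""Negative-binomial symptom models, overdispersion, blocked regression, Bonferroni."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import seasonmed as sm
from seasonmed.errors import DegenerateDataError, FitError


def _nb_counts(rng, mu, alpha, n):
    lam = rng.gamma(1.0 / alpha, alpha * mu, n) if alpha > 0 else np.full(n, mu)
    return rng.poisson(lam)


# printed coefficient/IRR pairs from the source cohort's symptom models
@pytest.mark.parametrize("b, irr", [(-0.022, 0.978), (-0.025, 0.975), (-0.013, 0.987)])
def test_irr_matches_reported_three_decimals(b, irr):
    assert round(math.exp(b), 3) == irr


def test_fitted_irr_is_exactly_exp_b(female_cohort):
    df, _ = female_cohort
    fit = sm.fit_nb(df["low_mood"], df["photoperiod"],
                    covariates={"age": df["age"], "townsend": df["townsend"]},
                    predictor_name="photoperiod")
    assert fit.irr == math.exp(fit.b)
    assert fit.irr > 0
    assert fit.dispersion >= 0


def test_recovers_generating_photoperiod_effect(female_cohort):
    """The female direct photoperiod effect is recovered within 2 robust SEs."""
    df, truth = female_cohort
    fit = sm.fit_nb(df["anhedonia"], df["photoperiod"],
                    covariates={"age": df["age"], "ethnicity": df["ethnicity"],
                                "living_area": df["living_area"],
                                "townsend": df["townsend"]},
                    predictor_name="photoperiod")
    # generated effect = direct path + mediated volume path
    implied = truth.config.path_c_prime["female"] + truth.indirect["female"]
    assert abs(fit.b - implied) < 2 * fit.se


def test_outcome_validation():
    with pytest.raises(ValueError, match="non-negative integers"):
        sm.fit_nb([-1, 0, 1], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="non-negative integers"):
        sm.fit_nb([0.5, 1.0, 2.0], [1.0, 2.0, 3.0])


def test_zero_dispersion_limit_matches_poisson(rng):
    n = 1500
    x = rng.normal(13, 3, n)
    y = rng.poisson(np.exp(-1.2 - 0.03 * (x - 13)))
    nb0 = sm.fit_nb(y, x, dispersion=0)
    import statsmodels.api as smapi
    X = np.column_stack([np.ones(n), x])
    pois = smapi.GLM(y, X, family=smapi.families.Poisson()).fit()
    assert nb0.b == pytest.approx(float(pois.params[1]), abs=1e-6)
    assert nb0.dispersion == 0.0


def test_robust_and_model_ses_agree_when_correctly_specified(rng):
    """HC sandwich and model-based SEs within ~10% on well-specified NB data."""
    n = 3000
    x = rng.normal(0, 1, n)
    y = _nb_counts(rng, np.exp(-1.0 + 0.2 * x), 0.8, n)
    robust = sm.fit_nb(y, x, cov_type="HC1")
    model = sm.fit_nb(y, x, cov_type="nonrobust")
    assert robust.se / model.se == pytest.approx(1.0, abs=0.10)
    assert robust.b == pytest.approx(model.b, rel=1e-8)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_nb_coefficients_cross_checked_against_glm_nb(tmp_path, rng):
    """Independent oracle: MASS::glm.nb on the same data agrees on b and dispersion."""
    n = 600
    x = rng.normal(13, 3, n)
    z = rng.normal(0, 1, n)
    y = _nb_counts(rng, np.exp(-1.0 - 0.05 * (x - 13) + 0.3 * z), 0.6, n)
    csv = tmp_path / "d.csv"
    pd.DataFrame({"y": y, "x": x, "z": z}).to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(MASS))
        d <- read.csv("{csv}")
        m <- glm.nb(y ~ x + z, data = d)
        cat(coef(m)[["x"]], 1/m$theta, sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                         check=True)
    b_r, alpha_r = (float(v) for v in out.stdout.split())
    fit = sm.fit_nb(y, x, covariates={"z": z})
    assert fit.b == pytest.approx(b_r, abs=5e-4)
    assert fit.dispersion == pytest.approx(alpha_r, rel=0.05)


def test_fast_refit_matches_the_full_maximum_likelihood_fit(rng):
    """The warm-start Newton refitter used in the bootstrap lands on the
    same NB2 optimum as the full statsmodels fit."""
    from seasonmed.count_regression import _fit_count_ml, nb2_point_refit
    n = 1200
    X = np.column_stack([np.ones(n), rng.normal(13, 3, n),
                         rng.normal(25000, 2000, n)])
    mu = np.exp(-1.3 - 0.02 * (X[:, 1] - 13) - 5e-5 * (X[:, 2] - 25000))
    y = np.minimum(rng.poisson(rng.gamma(1 / 0.8, 0.8 * mu)), 3)
    ref, _, _, _, _ = _fit_count_ml(y, X, model="nb", cov_type="nonrobust")
    fast = nb2_point_refit(y, X, ref * 1.1)   # perturbed warm start
    assert np.max(np.abs(fast - ref)) < 1e-8


def test_overdispersion_detected_and_not_fabricated(rng):
    n = 2000
    nb_hits = pois_hits = 0
    reps = 60
    for _ in range(reps):
        y_nb = _nb_counts(rng, np.full(n, 0.6), 1.5, n)
        nb_hits += sm.overdispersion_check(y_nb).overdispersed
        y_p = rng.poisson(0.6, n)
        pois_hits += sm.overdispersion_check(y_p).overdispersed
    assert nb_hits >= 0.95 * reps          # power under strong overdispersion
    assert pois_hits <= 0.15 * reps        # near-nominal false positives


def test_overdispersion_degenerate_inputs():
    res = sm.overdispersion_check(np.full(100, 2))
    assert res.ratio == 0.0 and not res.overdispersed
    with pytest.raises(DegenerateDataError):
        sm.overdispersion_check(np.zeros(100, dtype=int))


def test_hierarchical_regression_recovers_photoperiod_slope(female_cohort):
    df, truth = female_cohort
    fit = sm.fit_volume_photoperiod(
        df["whole_brainstem"], df["photoperiod"],
        blocks=[{"age": df["age"]}, {"tbv": df["tbv"]}],
    )
    assert abs(fit.B - truth.path_a_total["whole_brainstem"]) < 2 * fit.se
    assert fit.r > 0 and fit.r**2 == pytest.approx(fit.r2, abs=1e-12)
    # total R^2 is non-decreasing as blocks are added
    assert fit.block_r2[0] <= fit.block_r2[1] <= fit.r2_total


def test_hierarchical_regression_null_when_photoperiod_is_permuted(female_cohort, rng):
    df, _ = female_cohort
    shuffled = rng.permutation(np.asarray(df["photoperiod"]))
    fit = sm.fit_volume_photoperiod(
        df["whole_brainstem"], shuffled,
        blocks=[{"age": df["age"]}, {"tbv": df["tbv"]}],
    )
    assert fit.r2 < 0.005
    assert fit.p > 0.001


def test_noiseless_linear_volume_gives_unit_correlation(rng):
    n = 300
    photo = rng.uniform(7, 17, n)
    age = rng.uniform(45, 79, n)     # no effect on the outcome
    fit = sm.fit_volume_photoperiod(2.0 * photo, photo, blocks=[{"age": age}])
    # the age block soaks up a sliver of in-sample variance by chance,
    # so the incremental r falls a hair short of exactly 1
    assert fit.r == pytest.approx(1.0, abs=1e-2)
    assert fit.p < 1e-12
    assert fit.B == pytest.approx(2.0, abs=1e-8)


def test_collinear_design_raises(rng):
    photo = rng.uniform(7, 17, 100)
    with pytest.raises(FitError, match="collinear"):
        sm.fit_volume_photoperiod(2 * photo, photo, blocks=[{"copy": photo}])


def test_bonferroni_families():
    assert sm.bonferroni(0.05, 15) == pytest.approx(0.05 / 15)   # prints as 0.003
    assert sm.bonferroni(0.05, 75) == pytest.approx(0.05 / 75)   # prints as 0.0006
    assert sm.bonferroni(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        sm.bonferroni(0.05, 0)
    with pytest.raises(ValueError):
        sm.bonferroni(1.5, 3)
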