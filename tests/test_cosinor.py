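"""Cosinor machinery: month encoding, amplitude/acrophase, fit and verdict."""


import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seasonmed as sm
from seasonmed.cosinor import CosinorFit, month_label
from seasonmed.errors import DegenerateDataError, FitError

# printed cosine/sine coefficient pairs and amplitudes from the source cohort
TABLE2_ROWS = [
    (-441.75, 166.20, 471.9),   # all participants, whole brainstem
    (-115.98, 43.30, 123.8),    # all participants, medulla
    (-422.66, 204.09, 469.3),   # females, whole brainstem
    (-251.40, 120.82, 278.9),   # females, pons
    (-110.33, 50.40, 121.3),    # females, medulla
    (-57.93, 31.27, 65.8),      # females, midbrain
    (-479.60, 131.53, 497.3),   # males, whole brainstem
    (-125.91, 36.83, 131.2),    # males, medulla
]


@pytest.mark.parametrize("m, expected", [(1, (0.0, 1.0)), (4, (1.0, 0.0)), (7, (0.0, -1.0))])
def test_encode_month_quarter_cycle_values(m, expected):
    sin_t, cos_t = sm.encode_month(m)
    assert sin_t == pytest.approx(expected[0], abs=1e-12)
    assert cos_t == pytest.approx(expected[1], abs=1e-12)


@given(m=st.integers(min_value=1, max_value=12))
def test_encode_month_is_on_the_unit_circle(m):
    sin_t, cos_t = sm.encode_month(m)
    assert sin_t**2 + cos_t**2 == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("m", [0, 13, -1])
def test_encode_month_rejects_out_of_range(m):
    with pytest.raises(ValueError):
        sm.encode_month(m)


@pytest.mark.parametrize("beta, gamma, expected", TABLE2_ROWS)
def test_amplitude_reproduces_reported_values(beta, gamma, expected):
    assert sm.amplitude(beta, gamma) == pytest.approx(expected, abs=0.3)


@given(beta=st.floats(-1e3, 1e3), gamma=st.floats(-1e3, 1e3))
def test_amplitude_nonnegative_and_sign_invariant(beta, gamma):
    a = sm.amplitude(beta, gamma)
    assert a >= 0.0
    assert sm.amplitude(-beta, -gamma) == a


def test_acrophase_cardinal_directions():
    phi, label = sm.acrophase(1.0, 0.0)
    assert phi == pytest.approx(1.0) and label == "January"   # cosine peak at M=1
    phi, label = sm.acrophase(0.0, 1.0)
    assert phi == pytest.approx(4.0) and label == "April"     # quarter cycle later


def test_acrophase_reported_female_peak_is_early_summer():
    phi, label = sm.acrophase(-422.66, 204.09)
    assert label in ("May", "June", "July")   # printed label June, +-1 month
    assert phi == pytest.approx(6.14, abs=0.01)


def test_acrophase_undefined_at_zero_amplitude():
    with pytest.raises(DegenerateDataError):
        sm.acrophase(0.0, 0.0)


def test_acrophase_is_the_argmax_of_the_fitted_sinusoid():
    rng = np.random.default_rng(3)
    for beta, gamma in rng.normal(0, 100, (20, 2)):
        phi, _ = sm.acrophase(beta, gamma)
        grid = np.linspace(1.0, 13.0, 20001)[:-1]
        curve = beta * np.cos(2 * np.pi * (grid - 1) / 12) + gamma * np.sin(
            2 * np.pi * (grid - 1) / 12)
        best = grid[np.argmax(curve)]
        # compare on the circle
        diff = abs(best - phi) % 12.0
        assert min(diff, 12.0 - diff) < 0.01


def _noiseless_cohort(amplitude=470.0, phi=7.0, n_per_month=20, mean=100.0):
    months = np.tile(np.arange(1, 13), n_per_month)
    theta0 = 2 * np.pi * (phi - 1) / 12
    y = mean + amplitude * np.cos(2 * np.pi * (months - 1) / 12 - theta0)
    return y, months, theta0


def test_fit_recovers_noiseless_sinusoid_exactly():
    y, months, theta0 = _noiseless_cohort()
    fit = sm.fit_cosinor(y, months)
    assert fit.beta == pytest.approx(470.0 * np.cos(theta0), abs=1e-8)
    assert fit.gamma == pytest.approx(470.0 * np.sin(theta0), abs=1e-8)
    assert fit.amplitude == pytest.approx(470.0, abs=1e-8)
    assert fit.phi == pytest.approx(7.0, abs=1e-6)
    assert fit.acrophase_month_label == "July"


def test_amplitude_is_half_the_peak_to_trough_range():
    y, months, _ = _noiseless_cohort(amplitude=123.0, phi=3.7)
    fit = sm.fit_cosinor(y, months)
    grid = np.linspace(1, 13, 10001)
    curve = fit.beta * np.cos(2 * np.pi * (grid - 1) / 12) + fit.gamma * np.sin(
        2 * np.pi * (grid - 1) / 12)
    assert fit.amplitude == pytest.approx((curve.max() - curve.min()) / 2, rel=1e-9)


@given(shift=st.integers(min_value=0, max_value=11))
def test_acrophase_is_equivariant_under_month_shifts(shift):
    y, months, _ = _noiseless_cohort(amplitude=80.0, phi=2.0)
    shifted = ((months - 1 + shift) % 12) + 1
    fit = sm.fit_cosinor(y, shifted)
    expected = (2.0 - 1 + shift) % 12 + 1
    diff = abs(fit.phi - expected) % 12.0
    assert min(diff, 12.0 - diff) < 1e-6


def test_zero_effect_covariate_does_not_change_the_verdict():
    y, months, _ = _noiseless_cohort()
    rng = np.random.default_rng(0)
    cov = {"age": rng.uniform(45, 79, len(y))}
    plain = sm.fit_cosinor(y + rng.normal(0, 5.0, len(y)), months)
    adjusted = sm.fit_cosinor(y + rng.normal(0, 5.0, len(y)), months, covariates=cov)
    assert plain.seasonal == adjusted.seasonal is True


def test_fit_requires_enough_months_and_observations():
    with pytest.raises(FitError):
        sm.fit_cosinor([1.0, 2.0, 3.0, 4.0], [1, 1, 2, 2])
    with pytest.raises(FitError):
        sm.fit_cosinor([1.0, 2.0, 3.0], [1, 5, 9])


def test_amplitude_estimate_concentrates_with_sample_size():
    """Bias of the amplitude estimate shrinks from n=500 to n=5000."""
    errors = {}
    for n in (500, 5000):
        errs = []
        for seed in range(4):
            cfg = sm.GeneratorConfig(
                n_participants=n, seed=200 + seed,
                true_amplitude={"whole_brainstem": 470.0, "midbrain": 0.0,
                                "pons": 0.0, "medulla": 0.0, "scp": 0.0},
                path_a={k: 0.0 for k in sm.synthetic.STRUCTURES},
            )
            tab, _ = sm.generate_cohort(cfg)
            months = [d.month for d in tab["scan_date"]]
            fit = sm.fit_cosinor(tab["whole_brainstem"], months,
                                 covariates={"age": tab["age"], "tbv": tab["tbv"]})
            errs.append(abs(fit.amplitude - 470.0))
        errors[n] = np.mean(errs)
    assert errors[5000] < errors[500]


def _fit_stub(p_beta, p_gamma, p_amp, delta_aic):
    return CosinorFit(
        beta=1.0, gamma=1.0, se_beta=1.0, se_gamma=1.0,
        p_beta=p_beta, p_gamma=p_gamma, amplitude=1.4, se_amplitude=0.2,
        p_amplitude=p_amp, phi=2.0, acrophase_month_label=month_label(2.0),
        aic_full=0.0, aic_reduced=-delta_aic, delta_aic=delta_aic,
    )


def test_seasonality_requires_both_criteria():
    ok, report = sm.seasonality_decision(_fit_stub(1e-4, 0.5, 1e-4, -10.0))
    assert ok and report["aic_improved"]
    # significant terms but AIC worse: both criteria are required
    ok, _ = sm.seasonality_decision(_fit_stub(1e-4, 1e-4, 1e-4, +3.0))
    assert not ok
    # AIC better but terms not significant
    ok, _ = sm.seasonality_decision(_fit_stub(0.5, 0.5, 0.5, -3.0))
    assert not ok
    # terms significant, AIC better, but amplitude not distinguishable from 0
    ok, _ = sm.seasonality_decision(_fit_stub(1e-4, 0.5, 0.20, -3.0))
    assert not ok
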