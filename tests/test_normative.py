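"""Normative mixed model, prediction intervals and deviations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from darkadapt import (
    NormativeModel,
    compute_deviations,
    fit_normative_model,
    predict_interval,
)
from darkadapt.exceptions import (
    ConfigurationError,
    DegenerateDesignError,
    InsufficientDataError,
    StateError,
)

ECCS = (2.0, 4.0, 6.0)


def simulate_healthy(
    n_subjects=35,
    intercept=10.0,
    age_slope=1.0,
    ecc_offsets=(0.0, -1.0, -2.0),
    between_sd=2.0,
    residual_sd=2.0,
    seed=0,
    ages=None,
):
    """Direct parametric draw from the normative model's own assumptions."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        age = float(rng.uniform(20, 80)) if ages is None else ages[i]
        b = rng.normal(0, between_sd)
        for ecc, off in zip(ECCS, ecc_offsets):
            rit = (
                intercept
                + age_slope * age / 10.0
                + off
                + b
                + rng.normal(0, residual_sd)
            )
            rows.append(
                {
                    "subject_id": f"H{i:03d}",
                    "group": "healthy",
                    "age": age,
                    "eccentricity_deg": ecc,
                    "RIT": rit,
                    "rit_censored": False,
                }
            )
    return pd.DataFrame(rows)


class TestFitNormativeModel:
    def test_age_slope_recovered_within_interval(self):
        df = simulate_healthy(seed=1)
        model = fit_normative_model(df, "RIT")
        lo = model.age_slope - 1.96 * model.age_slope_se
        hi = model.age_slope + 1.96 * model.age_slope_se
        assert lo <= 1.0 <= hi
        assert model.between_sd == pytest.approx(2.0, abs=1.0)
        assert model.residual_sd == pytest.approx(2.0, abs=0.8)
        assert model.ecc_offsets[4.0] == pytest.approx(-1.0, abs=1.0)

    def test_zero_noise_recovers_fixed_effects_exactly(self):
        df = simulate_healthy(between_sd=0.0, residual_sd=0.0, seed=2)
        model = fit_normative_model(df, "RIT")
        assert model.intercept == pytest.approx(10.0, rel=1e-6)
        assert model.age_slope == pytest.approx(1.0, rel=1e-6)
        assert model.ecc_offsets[6.0] == pytest.approx(-2.0, rel=1e-6)
        assert model.between_sd == 0.0 and model.residual_sd == 0.0

    def test_single_eccentricity_stratum_fits(self):
        df = simulate_healthy(seed=3)
        df = df[df["eccentricity_deg"] == 4.0]
        model = fit_normative_model(df, "RIT")
        assert model.ecc_offsets == {}
        assert np.isfinite(model.age_slope)

    def test_degenerate_design_rejected(self):
        df = simulate_healthy(seed=4)
        df = df[df["eccentricity_deg"] == 2.0].copy()
        df["age"] = 50.0
        with pytest.raises(DegenerateDesignError):
            fit_normative_model(df, "RIT")

    def test_too_few_subjects_rejected(self):
        df = simulate_healthy(n_subjects=5, seed=5)
        with pytest.raises(InsufficientDataError):
            fit_normative_model(df, "RIT")

    def test_model_json_round_trip(self):
        model = fit_normative_model(simulate_healthy(seed=6), "RIT")
        back = NormativeModel.from_json(model.to_json())
        assert back.intercept == pytest.approx(model.intercept)
        assert back.ecc_offsets == model.ecc_offsets


class TestPredictInterval:
    def _model(self, between=2.0, resid=2.0):
        return NormativeModel(
            outcome_name="RIT",
            intercept=10.0,
            age_slope=1.0,
            ecc_offsets={4.0: -1.0, 6.0: -2.0},
            between_sd=between,
            residual_sd=resid,
            n_subjects=35,
            n_loci=105,
            age_range=(20.0, 80.0),
            fitted=True,
        )

    def test_closed_form_interval(self):
        lo, med, hi = predict_interval(self._model(), age=60.0, eccentricity_deg=2.0)
        assert med == pytest.approx(16.0)
        half = norm.ppf(0.975) * np.sqrt(8.0)
        assert hi - med == pytest.approx(half, abs=1e-9)
        assert med - lo == pytest.approx(half, abs=1e-9)

    def test_zero_variance_collapses_to_point(self):
        lo, med, hi = predict_interval(
            self._model(between=0.0, resid=0.0), age=60.0, eccentricity_deg=2.0
        )
        assert lo == med == hi == pytest.approx(16.0)

    def test_width_constant_in_age_and_eccentricity(self):
        m = self._model()
        widths = {
            (a, e): np.subtract(*predict_interval(m, a, e)[::-2])
            for a in (30.0, 50.0, 70.0)
            for e in ECCS
        }
        vals = list(widths.values())
        assert np.allclose(vals, vals[0])

    def test_unfitted_model_rejected(self):
        m = self._model()
        m.fitted = False
        with pytest.raises(StateError):
            predict_interval(m, 50.0, 2.0)

    def test_coverage_of_fresh_healthy_loci(self):
        # train on enough subjects that variance-component sampling error
        # does not dominate the coverage of the interval construction
        train = simulate_healthy(n_subjects=200, seed=7)
        model = fit_normative_model(train, "RIT")
        fresh = simulate_healthy(n_subjects=334, seed=8)  # ~1000 loci
        inside = 0
        for _, r in fresh.iterrows():
            lo, _, hi = predict_interval(model, r["age"], r["eccentricity_deg"])
            inside += lo <= r["RIT"] <= hi
        assert inside / len(fresh) == pytest.approx(0.95, abs=0.02)


class TestComputeDeviations:
    def _models(self):
        kw = dict(n_subjects=35, n_loci=105, age_range=(20.0, 80.0), fitted=True)
        return {
            "RIT": NormativeModel("RIT", 10.0, 1.0, {}, 2.0, 2.0, **kw),
            "FT": NormativeModel("FT", -2.0, 0.0, {}, 0.1, 0.1, **kw),
        }

    def _outcomes(self, rit=16.0, ft=-2.0, censored=False):
        return pd.DataFrame(
            [
                {
                    "subject_id": "X",
                    "group": "AMD",
                    "age": 60.0,
                    "eccentricity_deg": 2.0,
                    "RIT": rit,
                    "FT": ft,
                    "rit_censored": censored,
                }
            ]
        )

    def test_observation_at_median_is_normal(self):
        dev = compute_deviations(self._outcomes(), self._models())
        r = dev[dev["outcome_name"] == "RIT"].iloc[0]
        assert r["deviation"] == pytest.approx(0.0)
        assert not r["abnormal"]

    def test_censored_rit_delay_is_lower_bound_and_abnormal(self):
        dev = compute_deviations(self._outcomes(rit=60.0, censored=True), self._models())
        r = dev[dev["outcome_name"] == "RIT"].iloc[0]
        assert r["deviation"] == pytest.approx(44.0)  # observed 60 - predicted 16
        assert r["abnormal"] and r["censored"]

    def test_threshold_deviation_sign_convention(self):
        # elevated threshold (observed above predicted) => negative deviation
        dev = compute_deviations(self._outcomes(ft=-1.0), self._models())
        r = dev[dev["outcome_name"] == "FT"].iloc[0]
        assert r["deviation"] == pytest.approx(-1.0)
        assert r["abnormal"]  # far outside the narrow band

    def test_missing_model_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_deviations(self._outcomes(), {"RIT": NormativeModel("RIT")})

    def test_healthy_flag_rate_near_nominal(self):
        train = simulate_healthy(seed=9)
        model = fit_normative_model(train, "RIT")
        dev = compute_deviations(train, {"RIT": model})
        assert dev["abnormal"].mean() == pytest.approx(0.05, abs=0.03)

    def test_healthy_deviations_centered_per_stratum(self):
        train = simulate_healthy(seed=10)
        model = fit_normative_model(train, "RIT")
        dev = compute_deviations(train, {"RIT": model})
        med = dev.groupby("eccentricity_deg")["deviation"].median()
        assert np.all(np.abs(med) < 1.0)
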