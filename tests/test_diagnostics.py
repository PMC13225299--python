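"""Covariate-adjusted ROC and structure-function regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from darkadapt import covariate_adjusted_roc, pooled_auc, structure_function_fit
from darkadapt.exceptions import CollinearityError, InsufficientDataError


def binormal_cohort(n=500, delta=1.0, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    marker = np.concatenate([rng.normal(0, sigma, n), rng.normal(delta, sigma, n)])
    disease = np.repeat([False, True], n)
    covariate = rng.uniform(40, 80, 2 * n)  # independent of both
    return marker, disease, covariate


class TestCovariateAdjustedROC:
    def test_null_case_gives_half(self):
        marker, disease, cov = binormal_cohort(n=200, delta=0.0, seed=1)
        r = covariate_adjusted_roc(marker, disease, cov, n_boot=50, seed=1)
        assert r.aauc == pytest.approx(0.5, abs=0.03)

    def test_binormal_closed_form(self):
        marker, disease, cov = binormal_cohort(n=500, delta=1.0, seed=2)
        r = covariate_adjusted_roc(marker, disease, cov, n_boot=50, seed=2)
        assert r.aauc == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.02)

    def test_confounded_null_is_conservative_vs_pooled(self):
        # marker depends on age only; diseased are 20 years older
        rng = np.random.default_rng(3)
        n = 300
        age = np.concatenate([rng.normal(50, 10, n), rng.normal(70, 10, n)])
        disease = np.repeat([False, True], n)
        marker = 0.5 * age / 10.0 + rng.normal(0, 1, 2 * n)
        assert pooled_auc(marker, disease) > 0.60
        r = covariate_adjusted_roc(marker, disease, age, n_boot=50, seed=3)
        assert r.aauc == pytest.approx(0.5, abs=0.04)

    def test_saturation_at_complete_separation(self):
        marker, disease, cov = binormal_cohort(n=200, delta=10.0, seed=4)
        r = covariate_adjusted_roc(marker, disease, cov, n_boot=20, seed=4)
        assert r.aauc >= 0.999

    def test_curve_is_monotone_and_area_consistent(self):
        marker, disease, cov = binormal_cohort(n=100, delta=0.8, seed=5)
        r = covariate_adjusted_roc(marker, disease, cov, n_boot=20, seed=5)
        assert np.all(np.diff(r.tpf) >= 0)
        # the exact area and the trapezoidal integral of the reported
        # curve agree to within half a grid cell of the 101-point grid
        assert r.aauc == pytest.approx(np.trapezoid(r.tpf, r.fpf_grid), abs=0.005)
        assert r.ci_low <= r.aauc <= r.ci_high

    def test_agrees_with_pooled_when_no_confounding(self):
        marker, disease, cov = binormal_cohort(n=400, delta=1.0, seed=6)
        r = covariate_adjusted_roc(marker, disease, cov, n_boot=20, seed=6)
        assert r.aauc == pytest.approx(pooled_auc(marker, disease), abs=0.03)

    def test_affine_marker_invariance(self):
        marker, disease, cov = binormal_cohort(n=150, delta=1.0, seed=7)
        r1 = covariate_adjusted_roc(marker, disease, cov, n_boot=10, seed=7)
        r2 = covariate_adjusted_roc(3.0 * marker + 5.0, disease, cov, n_boot=10, seed=7)
        assert r1.aauc == pytest.approx(r2.aauc, abs=1e-12)

    def test_bootstrap_reproducible_and_widens_with_small_n(self):
        widths = {}
        for n in (30, 100, 300):
            marker, disease, cov = binormal_cohort(n=n, delta=1.0, seed=8)
            r = covariate_adjusted_roc(marker, disease, cov, n_boot=200, seed=9)
            r2 = covariate_adjusted_roc(marker, disease, cov, n_boot=200, seed=9)
            assert (r.ci_low, r.ci_high) == (r2.ci_low, r2.ci_high)
            widths[n] = r.ci_high - r.ci_low
        assert widths[30] > widths[100] > widths[300]

    def test_direction_flips_for_lower_is_diseased(self):
        marker, disease, cov = binormal_cohort(n=200, delta=-1.0, seed=10)
        r = covariate_adjusted_roc(
            marker, disease, cov, direction="lower_is_diseased", n_boot=10, seed=10
        )
        assert r.aauc == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.04)

    def test_small_class_rejected(self):
        marker, disease, cov = binormal_cohort(n=5, seed=11)
        with pytest.raises(InsufficientDataError):
            covariate_adjusted_roc(marker, disease, cov, n_boot=10)


def regression_cohort(
    n=70,
    sdd_effect=20.0,
    eamd_effect=5.0,
    iamd_effect=25.0,
    late_effect=15.0,
    age_effect=2.0,
    resid_sd=5.0,
    seed=0,
):
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    for i in range(n):
        amd = i >= half
        age = rng.uniform(48, 86) if amd else rng.uniform(22, 80)
        sdd = int(amd and rng.random() < 0.3)
        study = (
            str(rng.choice(["eAMD", "iAMD", "lateAMD"], p=[0.31, 0.57, 0.12]))
            if amd
            else "none"
        )
        # includes a unilateral-disease fraction so fellow-eye terms are
        # not aliased with study-eye terms
        fellow = (
            str(rng.choice(["none", "eAMD", "iAMD", "lateAMD"], p=[0.1, 0.27, 0.45, 0.18]))
            if amd
            else "none"
        )
        rit = (
            1.0
            + sdd_effect * sdd
            + {"none": 0.0, "eAMD": eamd_effect, "iAMD": iamd_effect, "lateAMD": late_effect}[study]
            + age_effect * age / 10.0
            + rng.normal(0, resid_sd)
        )
        rows.append(
            {
                "subject_id": f"P{i}",
                "eccentricity_deg": 2.0,
                "age": age,
                "SDD": sdd,
                "study_dx": study,
                "fellow_dx": fellow,
                "RIT": rit,
            }
        )
    return pd.DataFrame(rows)


class TestStructureFunctionFit:
    def test_zero_noise_exact_coefficients(self):
        df = regression_cohort(resid_sd=0.0, seed=1)
        res = structure_function_fit(df)[2.0]
        tab = res.table.set_index("term")["estimate"]
        assert tab["SDD"] == pytest.approx(20.0, abs=1e-8)
        assert tab["study_dx[iAMD]"] == pytest.approx(25.0, abs=1e-8)
        assert tab["age_dec"] == pytest.approx(2.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0)

    def test_r2_bounds_and_adjustment(self):
        res = structure_function_fit(regression_cohort(seed=2))[2.0]
        assert 0.0 <= res.r2_adj <= res.r2 <= 1.0
        assert res.n == 70

    def test_injected_effects_inside_wald_intervals_mostly(self):
        hits = {"SDD": 0, "study_dx[iAMD]": 0}
        trials = {k: 0 for k in hits}
        for rep in range(60):
            res = structure_function_fit(regression_cohort(seed=100 + rep))[2.0]
            tab = res.table.set_index("term")
            for term, true in (("SDD", 20.0), ("study_dx[iAMD]", 25.0)):
                if term in tab.index:
                    trials[term] += 1
                    hits[term] += tab.loc[term, "ci_low"] <= true <= tab.loc[term, "ci_high"]
        for term in hits:
            assert hits[term] / trials[term] >= 0.85  # ~95% nominal coverage

    def test_aliased_design_rejected_with_names(self):
        df = regression_cohort(seed=3)
        df["fellow_dx"] = df["study_dx"]
        with pytest.raises(CollinearityError) as err:
            structure_function_fit(df)
        assert any("fellow" in c for c in err.value.aliased)
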