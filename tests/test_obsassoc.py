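"""Trait preparation, dilution correction, observational regressions,
nonlinearity assessment and Cox models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telocausal import obsassoc
from telocausal.exceptions import DataError


class TestPrepareTrait:
    def test_normal_sample_passes_through(self, rng):
        x = rng.standard_normal(5000)
        out = obsassoc.prepare_trait(x)
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)
        # no log: rank order of raw values preserved linearly
        assert np.corrcoef(np.clip(x, *np.percentile(x, [0.5, 99.5])), out)[0, 1] > 0.999999

    def test_extreme_outlier_winsorized(self, rng):
        x = np.concatenate([rng.standard_normal(999), [100.0]])
        hi = np.percentile(x, 99.5)
        clipped = np.clip(x, np.percentile(x, 0.5), hi)
        out = obsassoc.prepare_trait(x)
        # the outlier is pulled to the 99.5th percentile before scaling
        assert out.max() == pytest.approx((clipped.max() - clipped.mean()) / clipped.std())
        assert out.max() < 5

    def test_lognormal_triggers_log_and_reduces_skew(self, rng):
        x = np.exp(rng.standard_normal(5000) * 1.2)
        pre_skew = abs(stats.skew(x))
        out = obsassoc.prepare_trait(x)
        assert abs(stats.skew(out)) < pre_skew
        assert abs(stats.skew(out)) < 0.5  # log-normal becomes ~normal

    def test_winsorization_idempotent(self, rng):
        x = rng.standard_normal(2000)
        once = obsassoc.prepare_trait(x)
        twice = obsassoc.prepare_trait(once)
        assert np.allclose(once, twice, atol=0.02)

    def test_constant_rejected(self):
        with pytest.raises(DataError):
            obsassoc.prepare_trait(np.ones(100))


class TestDilutionRatio:
    def test_identical_pairs_ratio_one(self, rng):
        x = rng.standard_normal(500)
        assert obsassoc.estimate_dilution_ratio(x, x) == pytest.approx(1.0)

    def test_independent_pairs_ratio_zero(self, rng):
        a, b = rng.standard_normal(20_000), rng.standard_normal(20_000)
        assert obsassoc.estimate_dilution_ratio(a, b) == pytest.approx(0.0, abs=0.03)

    def test_few_pairs_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            obsassoc.estimate_dilution_ratio(rng.standard_normal(5), rng.standard_normal(5))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            obsassoc.estimate_dilution_ratio([1.0], [1.0])

    def test_generator_target_recovered(self, demo_cohort):
        _, cohort, _ = demo_cohort
        rep = cohort.dropna(subset=["ltl_repeat"])
        ratio = obsassoc.estimate_dilution_ratio(rep["ltl_measured"], rep["ltl_repeat"])
        assert ratio == pytest.approx(0.68, abs=0.04)  # 2000 pairs


def _toy_cohort(rng, n=20_000, beta=0.05):
    z = rng.standard_normal(n)
    return pd.DataFrame({
        "ltl_measured": z,
        "age": rng.uniform(40, 70, n),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "ethnic_group": rng.integers(0, 3, n).astype(str),
        "wbc": rng.normal(7, 1, n),
        "y": beta * z + rng.standard_normal(n),
    })


class TestAssociate:
    def test_null_trait(self, rng):
        cohort = _toy_cohort(rng, beta=0.0)
        res = obsassoc.associate(cohort, "y")
        assert abs(res.beta) < 3 * res.se
        assert res.partial_r2 < 1e-3

    def test_continuous_recovery_and_usual_correction(self, rng):
        cohort = _toy_cohort(rng, beta=0.05)
        res = obsassoc.associate(cohort, "y", dilution_ratio=0.68)
        assert res.beta == pytest.approx(0.05, abs=3 * res.se)
        assert res.beta_usual == pytest.approx(res.beta / 0.68)
        assert res.partial_r2 == pytest.approx(0.05**2 / (1 + 0.05**2), rel=0.4)

    def test_binary_odds_ratio_recovery(self, rng):
        n = 100_000
        z = rng.standard_normal(n)
        logit_p = -2.0 + np.log(1.2) * z
        y = (rng.random(n) < 1 / (1 + np.exp(-logit_p))).astype(int)
        cohort = _toy_cohort(rng, n)
        cohort["d"] = y
        cohort["ltl_measured"] = z
        res = obsassoc.associate(cohort, "d", kind="binary")
        assert res.beta == pytest.approx(np.log(1.2), abs=3 * res.se)

    def test_dilution_correction_commutes_with_scaling(self, rng):
        """Correcting then standardizing the exposure equals standardizing
        then correcting."""
        cohort = _toy_cohort(rng, n=5000, beta=0.05)
        res1 = obsassoc.associate(cohort, "y", dilution_ratio=0.68)
        scaled = cohort.copy()
        scaled["ltl_measured"] = scaled["ltl_measured"] / scaled["ltl_measured"].std()
        res2 = obsassoc.associate(scaled, "y", dilution_ratio=0.68)
        assert res1.beta_usual / res1.beta == pytest.approx(res2.beta_usual / res2.beta)


class TestNonlinearity:
    def test_linear_truth_selects_linear(self, rng):
        n = 4000
        z = rng.standard_normal(n)
        cohort = pd.DataFrame({"ltl_measured": z, "y": 0.3 * z + rng.standard_normal(n)})
        quad_p, powers = obsassoc.nonlinearity(cohort, "y")
        assert quad_p > 0.001
        assert powers == (1.0,)

    def test_u_shape_detected(self, rng):
        n = 10_000
        z = rng.standard_normal(n)
        cohort = pd.DataFrame({"ltl_measured": z, "y": 0.3 * z**2 + rng.standard_normal(n)})
        quad_p, powers = obsassoc.nonlinearity(cohort, "y")
        assert quad_p < 1e-6
        assert powers != (1.0,)  # FP beats the linear model


class TestCoxIncident:
    @staticmethod
    def _survival_cohort(rng, n, log_hr, followup=12.0, exposure_col="ltl_measured",
                         lam=1.0):
        """Exponential survival with hazard 0.02·exp(log_hr·true LTL);
        exposure observed with reliability lam (shared-error calibration)."""
        t_true = rng.standard_normal(n)
        s = lam / (1 + lam)
        shared = rng.standard_normal(n)
        err = np.sqrt(max(1 - lam * lam, 0)) * (
            np.sqrt(s) * shared + np.sqrt(1 - s) * rng.standard_normal(n))
        z = lam * t_true + err
        t = rng.exponential(1.0, n) / (0.02 * np.exp(log_hr * t_true))
        event = t < followup
        return pd.DataFrame({
            exposure_col: z,
            "age": rng.uniform(40, 70, n),
            "wbc": rng.normal(7, 1, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "ethnic_group": rng.integers(0, 2, n).astype(str),
            "d_prevalent": 0,
            "d_incident": event.astype(int),
            "d_time": np.where(event, t, followup),
        })

    def test_null_hazard(self, rng):
        cohort = self._survival_cohort(rng, 10_000, 0.0)
        res = obsassoc.cox_incident(cohort, "d", dilution_ratio=1.0, ph_check=False)
        assert res.ci[0] < 1.0 < res.ci[1]

    def test_attenuation_and_correction(self, rng):
        """Measured-LTL log-HR attenuates by the reliability; dividing by the
        dilution ratio restores the generating effect."""
        lam = 0.68
        cohort = self._survival_cohort(rng, 60_000, -0.3, lam=lam)
        res = obsassoc.cox_incident(cohort, "d", dilution_ratio=lam, ph_check=False)
        assert res.log_hr_measured == pytest.approx(-0.3 * lam, abs=3 * res.se_measured)
        assert np.log(res.hr) == pytest.approx(-0.3, abs=3 * res.se_measured / lam)

    def test_prevalent_cases_excluded(self, rng):
        cohort = self._survival_cohort(rng, 2000, 0.0)
        cohort.loc[:99, "d_prevalent"] = 1
        res = obsassoc.cox_incident(cohort, "d", dilution_ratio=1.0, ph_check=False)
        assert res.n_at_risk == 1900

    def test_time_varying_hazard_ratio_detected(self, rng):
        """log-HR a + b·t: the PH interaction flags it and the reported
        baseline/10-year HRs bracket the generating values."""
        n = 15_000
        z = rng.standard_normal(n)
        a, b, h0 = -0.4, 0.08, 0.03
        # inversion of H(t) = h0·exp(a z)·(exp(b z t) − 1)/(b z)
        e = rng.exponential(1.0, n)
        bz = b * z
        t = np.where(np.abs(bz) > 1e-12,
                     np.log1p(bz * e / (h0 * np.exp(a * z))) / bz,
                     e / (h0 * np.exp(a * z)))
        followup = 12.0
        event = t < followup
        cohort = pd.DataFrame({
            "ltl_measured": z,
            "age": rng.uniform(40, 70, n),
            "wbc": rng.normal(7, 1, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "ethnic_group": "0",
            "d_prevalent": 0,
            "d_incident": event.astype(int),
            "d_time": np.where(event, t, followup),
        })
        res = obsassoc.cox_incident(cohort, "d", dilution_ratio=1.0, ph_step=2.0)
        assert res.ph_interaction_p < 0.05
        assert np.log(res.hr_baseline) == pytest.approx(a, abs=0.15)
        assert np.log(res.hr_10y) == pytest.approx(a + 10 * b, abs=0.3)

    def test_matches_poisson_rate_ratio_oracle(self, rng):
        """Under exponential PH data the Cox partial-likelihood estimate
        agrees with a Poisson log-rate-ratio fit with log-time offset."""
        import statsmodels.api as sm

        cohort = self._survival_cohort(rng, 20_000, -0.2)
        res = obsassoc.cox_incident(cohort, "d", dilution_ratio=1.0,
                                    strata=("sex",), covariates=(), ph_check=False)
        X = np.column_stack([np.ones(len(cohort)), cohort["ltl_measured"],
                             (cohort["sex"] == "male").astype(float)])
        pois = sm.GLM(cohort["d_incident"], X, family=sm.families.Poisson(),
                      offset=np.log(cohort["d_time"])).fit()
        assert res.log_hr_measured == pytest.approx(pois.params.iloc[1], abs=0.02)
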