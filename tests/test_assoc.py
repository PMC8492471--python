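"""Association scan, joint conditional modelling, BH threshold, variance
explained and relatedness exclusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telocausal import assoc, syncohort
from telocausal.exceptions import ConfigurationError, ModelError

from conftest import binomial_dosages


def _brute_force_bh(p_values, q):
    """Literal step-up enumeration: largest p with p_(k) <= k q / m."""
    p = sorted(p_values)
    m = len(p)
    best = 0.0
    for k, pk in enumerate(p, start=1):
        if pk <= k * q / m:
            best = pk
    return best


def _brute_force_mis_size(nodes, edges):
    """Maximum independent set size by exhaustive subset enumeration."""
    best = 0
    nodes = list(nodes)
    for r in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, r):
            s = set(subset)
            if not any(a in s and b in s for a, b in edges):
                return r
    return best


class TestVariantScan:
    def test_recovers_injected_effect(self, rng):
        n = 100_000
        geno = binomial_dosages(rng, n, [0.3, 0.2, 0.4])
        y = 0.05 * geno.dosages[:, 0] + rng.standard_normal(n)
        res = assoc.variant_scan(geno, y)
        assert res.loc[res["variant_id"] == "rs1", "beta"].iloc[0] == pytest.approx(0.05, abs=0.01)

    def test_null_p_values_uniform(self, rng):
        n, m = 2000, 1000
        geno = binomial_dosages(rng, n, rng.uniform(0.05, 0.5, m))
        y = rng.standard_normal(n)  # independent of all dosages
        res = assoc.variant_scan(geno, y)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_variant_skipped(self, rng, caplog):
        geno = binomial_dosages(rng, 500, [0.3, 0.3])
        geno.dosages[:, 1] = 0.0
        geno.variants.loc[1, "eaf"] = 0.002  # passes MAF filter, fails variance
        with caplog.at_level("WARNING"):
            res = assoc.variant_scan(geno, rng.standard_normal(500))
        assert res["variant_id"].tolist() == ["rs1"]
        assert "monomorphic" in caplog.text

    def test_maf_and_info_prefilter(self, rng):
        geno = binomial_dosages(rng, 500, [0.3, 0.0005, 0.3])
        geno.variants.loc[2, "info"] = 0.1
        res = assoc.variant_scan(geno, rng.standard_normal(500))
        assert res["variant_id"].tolist() == ["rs1"]

    def test_covariate_adjustment_matches_joint_ols(self, rng):
        """Partialled-out scan equals the full OLS coefficient."""
        import statsmodels.api as sm

        n = 2000
        geno = binomial_dosages(rng, n, [0.3])
        cov = rng.standard_normal((n, 3))
        y = 0.1 * geno.dosages[:, 0] + cov @ [0.2, -0.1, 0.3] + rng.standard_normal(n)
        res = assoc.variant_scan(geno, y, cov)
        X = np.column_stack([np.ones(n), cov, geno.dosages[:, 0]])
        fit = sm.OLS(y, X).fit()
        assert res["beta"].iloc[0] == pytest.approx(fit.params[-1], abs=1e-10)
        assert res["se"].iloc[0] == pytest.approx(fit.bse[-1], abs=1e-10)


class TestJointConditional:
    def test_orthogonal_signals_keep_marginal_betas(self, rng):
        n = 20_000
        geno = binomial_dosages(rng, n, [0.3, 0.4])
        y = 0.08 * geno.dosages[:, 0] + 0.06 * geno.dosages[:, 1] + rng.standard_normal(n) * 0.3
        marginal = assoc.variant_scan(geno, y)
        joint = assoc.joint_conditional(geno, ["rs1", "rs2"], y, threshold=1e-4)
        assert sorted(joint.table["variant_id"]) == ["rs1", "rs2"]
        merged = joint.table.merge(marginal, on="variant_id", suffixes=("_j", "_m"))
        assert np.allclose(merged["beta_j"], merged["beta_m"], atol=0.01)

    def test_noiseless_orthogonal_equals_marginal_exactly(self, rng):
        n = 5000
        geno = binomial_dosages(rng, n, [0.3, 0.4])
        # decorrelate the second column from the first (orthogonal after
        # centering, which is what matters with an intercept in the model)
        g0c = geno.dosages[:, 0] - geno.dosages[:, 0].mean()
        geno.dosages[:, 1] -= g0c * (geno.dosages[:, 1] @ g0c) / (g0c @ g0c)
        y = 0.08 * geno.dosages[:, 0] + 0.06 * geno.dosages[:, 1]
        marginal = assoc.variant_scan(geno, y)
        joint = assoc.joint_conditional(geno, ["rs1", "rs2"], y, threshold=0.999)
        merged = joint.table.merge(marginal, on="variant_id", suffixes=("_j", "_m"))
        # noiseless orthogonal input: conditional betas equal marginal betas
        assert np.abs(merged["beta_j"] - merged["beta_m"]).max() < 1e-6

    def test_collinear_pair_keeps_one(self, rng):
        n = 2000
        geno = binomial_dosages(rng, n, [0.3, 0.3])
        geno.dosages[:, 1] = geno.dosages[:, 0]  # r² = 1
        y = 0.2 * geno.dosages[:, 0] + rng.standard_normal(n) * 0.1
        joint = assoc.joint_conditional(geno, ["rs1", "rs2"], y, threshold=1e-4)
        assert len(joint.table) == 1
        assert joint.table["variant_id"].iloc[0] == "rs1"  # later position dropped

    def test_shadow_variant_dropped(self, rng):
        """A non-causal variant in LD (r²≈0.5) with a true signal loses its
        conditional significance; the survivor set is admissible under an
        exhaustive subset oracle."""
        n = 20_000
        g0 = rng.binomial(2, 0.4, n).astype(float)
        # shadow shares half its variance with the causal variant
        mix = rng.random(n) < 0.7
        shadow = np.where(mix, g0, rng.binomial(2, 0.4, n)).astype(float)
        geno = binomial_dosages(rng, n, [0.4, 0.4])
        geno.dosages[:, 0], geno.dosages[:, 1] = g0, shadow
        y = 0.1 * g0 + rng.standard_normal(n)
        thr = 1e-6
        joint = assoc.joint_conditional(geno, ["rs1", "rs2"], y, threshold=thr)
        assert joint.table["variant_id"].tolist() == ["rs1"]

        # oracle: among all non-empty subsets, {rs1} must be admissible
        # (all conditional P < thr) and {rs1, rs2} must not be
        def subset_ps(ids):
            cols = {"rs1": g0, "rs2": shadow}
            X = np.column_stack([np.ones(n)] + [cols[i] for i in ids])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            df = n - X.shape[1]
            cov = (resid @ resid / df) * np.linalg.inv(X.T @ X)
            t = coef[1:] / np.sqrt(np.diag(cov)[1:])
            return 2 * stats.t.sf(np.abs(t), df)

        assert (subset_ps(["rs1"]) < thr).all()
        assert not (subset_ps(["rs1", "rs2"]) < thr).all()

    def test_empty_candidates(self, rng):
        geno = binomial_dosages(rng, 100, [0.3])
        joint = assoc.joint_conditional(geno, [], rng.standard_normal(100))
        assert joint.table.empty


class TestFdrThreshold:
    @pytest.mark.parametrize("p, q, expected", [
        ([0.001, 0.01, 0.02, 0.9], 0.05, 0.02),
        ([1.0, 1.0, 1.0], 0.05, 0.0),
        ([0.004], 0.01, 0.004),
    ])
    def test_examples(self, p, q, expected):
        assert assoc.derive_fdr_threshold(p, q) == pytest.approx(expected)

    def test_invalid_q(self):
        with pytest.raises(ConfigurationError):
            assoc.derive_fdr_threshold([0.1], 1.5)

    def test_matches_step_up_enumeration(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            assert assoc.derive_fdr_threshold(p, q) == pytest.approx(
                _brute_force_bh(p, q), abs=0.0)


class TestVarianceExplained:
    def test_single_variant_closed_form(self, rng):
        n, maf, beta = 100_000, 0.3, 0.1
        geno = binomial_dosages(rng, n, [maf])
        y = beta * geno.dosages[:, 0] + rng.standard_normal(n) * np.sqrt(
            1 - 2 * maf * (1 - maf) * beta**2)
        dr2 = assoc.variance_explained(geno, ["rs1"], y)
        assert dr2 == pytest.approx(2 * maf * (1 - maf) * beta**2, rel=0.10)

    def test_monotone_in_variant_set(self, demo_cohort):
        _, cohort, geno = demo_cohort
        ids = geno.variants["variant_id"].tolist()
        y = cohort["ltl_measured"]
        prev = 0.0
        for k in (1, 5, 15, 30, 40):
            dr2 = assoc.variance_explained(geno, ids[:k], y)
            assert dr2 >= prev - 1e-12
            prev = dr2

    def test_too_many_variants_rejected(self, rng):
        geno = binomial_dosages(rng, 5, rng.uniform(0.1, 0.5, 8))
        with pytest.raises(ModelError):
            assoc.variance_explained(geno, geno.variants["variant_id"].tolist(),
                                     np.zeros(5))


class TestUnrelatedSubset:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["id_a", "id_b", "k"])

    def test_single_related_pair_drops_one(self):
        drop = assoc.unrelated_subset(self._pairs([("A", "B", 0.1)]))
        assert len(drop) == 1 and drop < {"A", "B"}

    def test_below_threshold_untouched(self):
        assert assoc.unrelated_subset(self._pairs([("A", "B", 0.05)])) == set()

    def test_triangle_drops_two(self):
        drop = assoc.unrelated_subset(self._pairs(
            [("A", "B", 0.2), ("B", "C", 0.2), ("A", "C", 0.2)]))
        assert len(drop) == 2

    def test_chain_keeps_endpoints(self):
        drop = assoc.unrelated_subset(self._pairs([("A", "B", 0.2), ("B", "C", 0.2)]))
        assert drop == {"B"}

    def test_matches_brute_force_mis_on_random_graphs(self, rng):
        for trial in range(40):
            n_nodes = int(rng.integers(4, 13))
            nodes = [f"N{i}" for i in range(n_nodes)]
            edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                     if rng.random() < 0.3]
            if not edges:
                continue
            pairs = self._pairs([(a, b, 0.2) for a, b in edges])
            drop = assoc.unrelated_subset(pairs, seed=trial)
            # no remaining pair related
            assert all(a in drop or b in drop for a, b in edges)
            # removal is minimal: kept set is a maximum independent set
            kept = n_nodes - len(drop)
            assert kept == _brute_force_mis_size(nodes, edges)

    def test_seeded_choice_reproducible(self):
        pairs = self._pairs([("A", "B", 0.2)])
        assert assoc.unrelated_subset(pairs, seed=1) == assoc.unrelated_subset(pairs, seed=1)
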