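import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from shallowseq import (SimConfig, bh_adjust, estimate_dispersions, nb_exact_pvalue,
                        nb_exact_test, simulate_experiment, size_factors)

from conftest import make_experiment


def nb_pvalue_oracle(k_a, k_b, s_a, s_b, q, alpha, ssq_a=None, ssq_b=None):
    """Independent enumeration oracle via scipy.stats.nbinom/poisson pmfs."""
    ssq_a = s_a**2 if ssq_a is None else ssq_a
    ssq_b = s_b**2 if ssq_b is None else ssq_b
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0

    def pmf(k, mu, var):
        if var <= mu:
            return stats.poisson.pmf(k, mu)
        p = mu / var
        n = mu * p / (1 - p)
        return stats.nbinom.pmf(k, n, p)

    mu_a, mu_b = q * s_a, q * s_b
    var_a = mu_a + alpha * q**2 * ssq_a
    var_b = mu_b + alpha * q**2 * ssq_b
    probs = [pmf(a, mu_a, var_a) * pmf(k_s - a, mu_b, var_b) for a in range(k_s + 1)]
    obs = probs[k_a]
    num = sum(p for p in probs if p <= obs * (1 + 1e-7))
    return min(1.0, num / sum(probs))


class TestEstimateDispersions:
    @staticmethod
    def design(samples):
        return pd.DataFrame(
            [(s.rsplit("_", 1)[0], s.rsplit("_", 1)[1]) for s in samples],
            index=samples, columns=["condition", "replicate"])

    def test_variance_equal_mean_gives_zero_raw(self):
        # within-condition variance of (1,3) is 2 = mean -> raw dispersion 0
        counts = pd.DataFrame({"A_1": [1], "A_2": [3], "B_1": [1], "B_2": [3]},
                              index=["g0"])
        factors = pd.Series(1.0, index=counts.columns)
        model = estimate_dispersions(counts, factors, self.design(counts.columns))
        assert model.raw_dispersion["g0"] == 0.0

    def test_poisson_counts_give_small_dispersion(self):
        """phi=0 simulation: the fitted trend intercept stays near zero."""
        medians, intercepts = [], []
        for seed in range(5):
            cfg = SimConfig(n_genes=2000, depth_per_replicate=2_000_000,
                            dispersion=0.0, frac_de=0, n_focal=0, n_tf=0, seed=seed)
            exp, _ = simulate_experiment(cfg)
            f = size_factors(exp.counts)
            model = estimate_dispersions(exp.counts, f, exp.design)
            medians.append(float(model.final_dispersion.median()))
            intercepts.append(model.fitted_a0)
        assert np.median(medians) < 0.01
        assert abs(np.median(intercepts)) < 0.01

    def test_nb_dispersion_recovered_at_phi_01(self):
        """phi=0.1 simulation: median final dispersion within [0.05, 0.2]."""
        medians = []
        for seed in range(5):
            cfg = SimConfig(n_genes=2000, depth_per_replicate=4_000_000,
                            dispersion=0.1, frac_de=0, n_focal=0, n_tf=0, seed=seed)
            exp, _ = simulate_experiment(cfg)
            f = size_factors(exp.counts)
            model = estimate_dispersions(exp.counts, f, exp.design)
            medians.append(float(model.final_dispersion.median()))
        assert 0.05 <= np.median(medians) <= 0.2

    def test_final_never_below_fitted_trend(self, random_experiment):
        f = size_factors(random_experiment.counts)
        for sharing in ("fit", "max"):
            model = estimate_dispersions(random_experiment.counts, f,
                                         random_experiment.design, sharing=sharing)
            q = random_experiment.counts.div(f, axis=1).mean(axis=1)
            ok = q > 0
            assert (model.final_dispersion[ok] >= model.fitted_at(q[ok]) - 1e-12).all()
            assert (model.final_dispersion >= 0).all()

    def test_max_sharing_dominates_fit(self, random_experiment):
        f = size_factors(random_experiment.counts)
        m_fit = estimate_dispersions(random_experiment.counts, f,
                                     random_experiment.design, sharing="fit")
        m_max = estimate_dispersions(random_experiment.counts, f,
                                     random_experiment.design, sharing="max")
        assert (m_max.final_dispersion >= m_fit.final_dispersion - 1e-12).all()

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"A_1": [5], "B_1": [9]}, index=["g0"])
        factors = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="2 replicates"):
            estimate_dispersions(counts, factors, self.design(counts.columns))


class TestNbExactPvalue:
    def test_symmetric_split_has_pvalue_one(self):
        assert nb_exact_pvalue(25, 25, 2.0, 2.0, 12.5, 0.1) == 1.0

    def test_zero_total_has_pvalue_one(self):
        assert nb_exact_pvalue(0, 0, 2.0, 2.0, 0.0, 0.1) == 1.0

    @pytest.mark.parametrize("k_a,k_b", [(0, 12), (3, 9), (10, 40), (7, 7)])
    def test_poisson_limit_matches_binomial_exact_test(self, k_a, k_b):
        got = nb_exact_pvalue(k_a, k_b, 2.0, 2.0, (k_a + k_b) / 4.0, 0.0)
        oracle = stats.binomtest(k_a, k_a + k_b, 0.5).pvalue
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_matches_enumeration_oracle_for_small_totals(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            k_s = int(rng.integers(1, 51))
            k_a = int(rng.integers(0, k_s + 1))
            s_a, s_b = rng.uniform(0.5, 3.0, size=2)
            alpha = float(rng.choice([0.0, 0.01, 0.1, 0.5]))
            q = (k_a + (k_s - k_a)) / (s_a + s_b)
            got = nb_exact_pvalue(k_a, k_s - k_a, s_a, s_b, q, alpha,
                                  ssq_a=s_a**2 / 2, ssq_b=s_b**2 / 2)
            want = nb_pvalue_oracle(k_a, k_s - k_a, s_a, s_b, q, alpha,
                                    ssq_a=s_a**2 / 2, ssq_b=s_b**2 / 2)
            assert got == pytest.approx(want, rel=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_pvalue(-1, 3, 1.0, 1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            nb_exact_pvalue(1, 3, 1.0, 1.0, 1.0, -0.1)
        with pytest.raises(ValueError):
            nb_exact_pvalue(1, 3, 0.0, 1.0, 1.0, 0.1)

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_pvalues_in_unit_interval_and_symmetric(self, k_a, k_b):
        q = (k_a + k_b) / 4.0
        p = nb_exact_pvalue(k_a, k_b, 2.0, 2.0, q, 0.05)
        p_swapped = nb_exact_pvalue(k_b, k_a, 2.0, 2.0, q, 0.05)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(p_swapped, rel=1e-9)


class TestBhAdjust:
    def test_textbook_vector(self):
        got = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    def test_matches_step_up_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(size=1000)
        got = bh_adjust(p)
        # brute-force step-up definition
        order = np.argsort(p)
        m = len(p)
        oracle = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
            oracle[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(got, oracle, rtol=1e-12)
        sm = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, sm, rtol=1e-10)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.2]))


class TestNbExactTest:
    def test_planted_gene_called_and_zero_gene_excluded(self, tiny_experiment):
        res = nb_exact_test(tiny_experiment)
        assert "g1" not in res.index
        assert bool(res.loc["g0", "called"])
        assert res.loc["g0", "log2fc"] > 3

    def test_called_iff_padj_below_alpha(self, random_experiment):
        res = nb_exact_test(random_experiment, alpha=0.2)
        np.testing.assert_array_equal(res["called"], res["padj"] < 0.2)

    def test_pvalues_in_unit_interval_padj_at_least_p(self, random_experiment):
        res = nb_exact_test(random_experiment)
        assert ((res["pval"] > 0) & (res["pval"] <= 1)).all()
        assert (res["padj"] >= res["pval"] - 1e-15).all()

    def test_condition_swap_leaves_pvalues_unchanged(self, random_experiment):
        from shallowseq import CountExperiment
        res = nb_exact_test(random_experiment)
        # put condition B first so it becomes the numerator
        order = ["B_1", "B_2", "A_1", "A_2"]
        swapped = CountExperiment(random_experiment.counts[order],
                                  random_experiment.lengths,
                                  random_experiment.design.loc[order])
        res2 = nb_exact_test(swapped)
        np.testing.assert_allclose(res["pval"], res2["pval"], rtol=1e-9)
        np.testing.assert_allclose(res["log2fc"], -res2["log2fc"], rtol=1e-9)

    def test_type_i_error_near_nominal_on_null_data(self):
        """All-null phi=0.05 data: raw p<0.05 fraction ~ 0.05 (3 SE), small scale."""
        fracs = []
        for seed in range(4):
            cfg = SimConfig(n_genes=3000, depth_per_replicate=3_000_000,
                            frac_de=0, n_focal=0, n_tf=0, seed=seed)
            exp, _ = simulate_experiment(cfg)
            res = nb_exact_test(exp)
            fracs.append(float((res["pval"] < 0.05).mean()))
        se = np.sqrt(0.05 * 0.95 / (3000 * len(fracs)))
        assert abs(np.mean(fracs) - 0.05) <= 3 * se + 0.01
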