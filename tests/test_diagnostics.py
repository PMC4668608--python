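"""Gelman-Rubin, DIC, posterior predictive coverage and effect summaries."""

import numpy as np
import pytest

from sharedcar.diagnostics import (
    dic,
    gelman_rubin,
    gelman_rubin_table,
    ppc_coverage,
    relative_weights,
    summarize_effects,
)
from sharedcar.model import ModelSpec
from sharedcar.spatial_graph import grid_graph
from sharedcar.synthetic import Covariate, CovariateSchema

from conftest import make_cohort, manual_samples


class TestGelmanRubin:
    def test_identical_chains_exactly_one(self):
        chain = np.random.default_rng(0).standard_normal((1, 500))
        s = manual_samples({"x": np.vstack([chain, chain])[:, :, None].reshape(2, 500)})
        assert gelman_rubin(s)["x"] == 1.0

    def test_same_distribution_below_105(self):
        rng = np.random.default_rng(1)
        s = manual_samples({"x": rng.standard_normal((2, 5000))})
        assert gelman_rubin(s)["x"] < 1.05

    def test_separated_chains_large(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        assert gelman_rubin(manual_samples({"x": chains}))["x"] > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(manual_samples({"x": np.zeros((1, 100))}))

    def test_matches_reference_implementation(self):
        """Cross-check against arviz's split-free (identity) formulation by
        handing both the same pre-split chains."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        for shift in (0.0, 0.08, 0.5):
            chains = rng.standard_normal((2, 1000))
            chains[1] += shift
            mine = gelman_rubin(manual_samples({"x": chains}))["x"]
            ref = float(az.rhat(az.convert_to_dataset(chains), method="identity")["x"])
            assert mine == pytest.approx(max(ref, 1.0), abs=1e-6)

    def test_table_covers_vector_parameters(self):
        rng = np.random.default_rng(4)
        s = manual_samples({"beta": rng.standard_normal((2, 200, 3, 2))})
        tab = gelman_rubin_table(s)
        assert len(tab) == 6
        assert tab.parameter.str.startswith("beta[").all()


def _null_model_samples(alpha_draws, graph):
    """Samples for an intercept-only model (p = 0) on a given graph."""
    m = len(alpha_draws)
    na = graph.n_areas
    draws = {
        "alpha": np.tile(np.asarray(alpha_draws)[None, :, None], (1, 1, 3)),
        "beta": np.zeros((1, m, 0, 3)),
        "u": np.zeros((1, m, na, 3)),
        "s": np.zeros((1, m, na, 3)),
        "phi": np.zeros((1, m, na)),
        "log_delta": np.zeros((1, m, 3)),
    }
    return manual_samples(draws, design_columns=[], area_ids=list(graph.area_ids))


@pytest.fixture
def intercept_setup():
    g = grid_graph(2, 2)
    mini = CovariateSchema((Covariate("xbin", ("a", "b"), "a", (1, 1)),))
    y = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1]])
    cohort = make_cohort(y, ["a1", "a2", "a3"], covariates={"xbin": ["a", "a", "a"]})
    return g, mini, cohort


class TestDic:
    def test_single_draw_pd_zero(self, intercept_setup):
        g, mini, cohort = intercept_setup
        s = _null_model_samples([0.4], g)
        spec = ModelSpec.from_variant("A0")
        d, dbar, pd_ = dic(s, spec, cohort, g, schema=mini, drop=("xbin",))
        assert pd_ == pytest.approx(0.0, abs=1e-12)
        assert d == pytest.approx(dbar)

    def test_decomposition_identity(self, intercept_setup):
        g, mini, cohort = intercept_setup
        s = _null_model_samples([-0.5, 0.1, 0.9, 0.2], g)
        d, dbar, pd_ = dic(s, ModelSpec.from_variant("A0"), cohort, g,
                           schema=mini, drop=("xbin",))
        assert d - dbar - pd_ == pytest.approx(0.0, abs=1e-9)

    def test_two_symmetric_draws_quadratic_excess(self, intercept_setup):
        """For draws a +/- eps in an intercept-only model, pD approaches the
        quadratic excess eps^2 * D''(a)/2 with D'' = 2 * sum p(1-p)."""
        from scipy.special import expit

        g, mini, cohort = intercept_setup
        a, eps = 0.3, 1e-3
        s = _null_model_samples([a - eps, a + eps], g)
        _, dbar, pd_ = dic(s, ModelSpec.from_variant("A0"), cohort, g,
                           schema=mini, drop=("xbin",))
        p = expit(a)
        oracle = eps**2 * (2 * 9 * p * (1 - p)) / 2  # 9 Bernoulli cells
        assert pd_ == pytest.approx(oracle, rel=1e-4)

    def test_empty_samples_rejected(self, intercept_setup):
        g, mini, cohort = intercept_setup
        s = _null_model_samples([0.1], g)
        s.draws = {k: v[:, :0] for k, v in s.draws.items()}
        with pytest.raises(ValueError, match="empty"):
            dic(s, ModelSpec.from_variant("A0"), cohort, g, schema=mini, drop=("xbin",))


class TestPpcCoverage:
    def test_degenerate_half_probability_covers_everything(self, intercept_setup):
        g, mini, cohort = intercept_setup
        s = _null_model_samples(np.zeros(150), g)  # p = 0.5 everywhere
        cov = ppc_coverage(s, ModelSpec.from_variant("A0"), cohort, g,
                           schema=mini, drop=("xbin",), seed=1)
        assert cov == 1.0

    def test_near_certain_probability_misses_observed_zero(self, intercept_setup):
        g, mini, cohort = intercept_setup
        s = _null_model_samples(np.full(150, 7.0), g)  # p ~ 0.999
        cov = ppc_coverage(s, ModelSpec.from_variant("A0"), cohort, g,
                           schema=mini, drop=("xbin",), seed=1)
        # the observed zeros fall outside the central 95 % of replicates
        n_zero = (cohort.outcomes == 0).sum()
        assert cov == pytest.approx(1.0 - n_zero / 9.0)

    def test_requires_enough_draws(self, intercept_setup):
        g, mini, cohort = intercept_setup
        s = _null_model_samples(np.zeros(50), g)
        with pytest.raises(ValueError, match="100"):
            ppc_coverage(s, ModelSpec.from_variant("A0"), cohort, g,
                         schema=mini, drop=("xbin",))

    def test_empty_cohort_rejected(self, intercept_setup):
        g, mini, _ = intercept_setup
        empty = make_cohort(np.zeros((0, 3), dtype=int), [], covariates={"xbin": []})
        s = _null_model_samples(np.zeros(150), g)
        with pytest.raises(ValueError, match="empty"):
            ppc_coverage(s, ModelSpec.from_variant("A0"), empty, g,
                         schema=mini, drop=("xbin",))


class TestSummarizeEffects:
    def test_zero_draws_give_unit_or_not_substantive(self):
        s = manual_samples(
            {"beta": np.zeros((2, 50, 1, 3))}, design_columns=["tract=4-<6h"]
        )
        tab = summarize_effects(s)
        assert (tab.or_median == 1.0).all()
        assert (tab.cri_low == 1.0).all() and (tab.cri_high == 1.0).all()
        assert not tab.substantive.any()  # interval touching unity includes it

    def test_concentrated_draws(self):
        rng = np.random.default_rng(5)
        draws = np.log(0.41) + 1e-4 * rng.standard_normal((2, 500, 1, 3))
        s = manual_samples({"beta": draws}, design_columns=["tract=4-<6h"])
        tab = summarize_effects(s)
        assert tab.or_median.iloc[0] == pytest.approx(0.41, rel=1e-3)
        assert tab.substantive.all()

    def test_median_commutes_with_exp_for_odd_draws(self):
        rng = np.random.default_rng(6)
        draws = rng.standard_normal((1, 251, 1, 3))
        s = manual_samples({"beta": draws}, design_columns=["c"])
        tab = summarize_effects(s)
        flat = draws.reshape(251, 3)
        assert tab.or_median.to_numpy() == pytest.approx(np.exp(np.median(flat, axis=0)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        draws = rng.standard_normal((1, 400, 2, 3))
        s1 = manual_samples({"beta": draws}, design_columns=["c1", "c2"])
        perm = rng.permutation(400)
        s2 = manual_samples({"beta": draws[:, perm]}, design_columns=["c1", "c2"])
        num = ["or_median", "cri_low", "cri_high"]
        t1, t2 = summarize_effects(s1), summarize_effects(s2)
        assert t1[num].to_numpy() == pytest.approx(t2[num].to_numpy())
        assert (t1.substantive == t2.substantive).all()


class TestRelativeWeights:
    def test_unit_weights(self):
        s = manual_samples({"log_delta": np.zeros((2, 50, 3))})
        tab = relative_weights(s)
        assert (tab["median"] == 1.0).all()
        assert not tab.substantive.any()

    def test_cyclic_product_identity(self):
        rng = np.random.default_rng(8)
        ld = rng.standard_normal((2, 300, 3))
        ld -= ld.mean(axis=2, keepdims=True)
        s = manual_samples({"log_delta": ld})
        flat = s.stacked("log_delta")
        r21 = np.exp(flat[:, 1] - flat[:, 0])
        r32 = np.exp(flat[:, 2] - flat[:, 1])
        r13 = np.exp(flat[:, 0] - flat[:, 2])
        assert r21 * r32 * r13 == pytest.approx(np.ones(len(flat)))

    def test_concentrated_ratio(self):
        delta = np.array([1.25, 0.8, 1.0])
        ld = np.tile(np.log(delta), (2, 120, 1))
        tab = relative_weights(manual_samples({"log_delta": ld}))
        row = tab[tab.ratio == "delta_chemotherapy/delta_radiotherapy"].iloc[0]
        assert row["median"] == pytest.approx(0.64)

    def test_variant_without_shared_component(self):
        s = manual_samples({"beta": np.zeros((2, 20, 1, 3))}, design_columns=["c"])
        with pytest.raises(ValueError, match="shared"):
            relative_weights(s)
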