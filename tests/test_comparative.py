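import numpy as np
import pandas as pd
import pytest

from cochlevo import comparative, synthetic_data
from cochlevo.comparative import (
    AncestralBM,
    PagelLambda,
    ancestral_ml_bm,
    bm_covariance,
    bm_loglik,
    bm_loglik_dense,
    fit_lambda,
    lambda_rescale,
    pic_contrasts,
)
from cochlevo.exceptions import CochlevoError
from cochlevo.phylo_io import read_newick


class TestBMCovariance:
    def test_cherry_identity(self, cherry):
        assert np.allclose(bm_covariance(cherry), np.eye(2))

    def test_three_tip_shared_paths(self, three_tip):
        C = bm_covariance(three_tip)
        idx = {lab: i for i, lab in enumerate(three_tip.labels)}
        expected = np.zeros((3, 3))
        expected[idx["A"], idx["A"]] = expected[idx["B"], idx["B"]] = 2.0
        expected[idx["C"], idx["C"]] = 2.0
        expected[idx["A"], idx["B"]] = expected[idx["B"], idx["A"]] = 1.0
        assert np.allclose(C, expected)

    def test_lambda_zero_is_star(self, three_tip):
        C = bm_covariance(three_tip, lam=0.0)
        assert np.allclose(C, np.diag([2.0, 2.0, 2.0]))

    def test_lambda_scales_offdiagonal_only(self, three_tip):
        C1 = bm_covariance(three_tip, lam=1.0)
        Ch = bm_covariance(three_tip, lam=0.5)
        assert np.allclose(np.diag(Ch), np.diag(C1))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(Ch[off], 0.5 * C1[off])

    def test_lambda_rescale_matches_covariance(self, yule50):
        lam = 0.37
        C_direct = bm_covariance(yule50, lam=lam)
        C_tree = bm_covariance(lambda_rescale(yule50, lam))
        assert np.allclose(C_direct, C_tree, atol=1e-10)


class TestPIC:
    def test_cherry_contrast(self):
        tree = read_newick("(A:1,B:1);")
        cs = pic_contrasts(tree, pd.Series({"A": 0.0, "B": 2.0}))
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2))
        assert cs.root_estimate == pytest.approx(1.0)

    def test_symmetric_four_tip_means(self, four_tip_symmetric):
        x = pd.Series({"A": 1.0, "B": 3.0, "C": 5.0, "D": 7.0})
        cs = pic_contrasts(four_tip_symmetric, x)
        assert sorted(cs.node_estimates) == pytest.approx([2.0, 4.0, 6.0])
        assert cs.root_estimate == pytest.approx(4.0)

    def test_constant_trait_gives_zero_contrasts(self, yule50):
        cs = pic_contrasts(yule50, np.full(50, 3.14))
        assert np.allclose(cs.contrasts, 0.0)
        assert np.allclose(cs.node_estimates, 3.14)

    def test_contrast_count_on_binary_tree(self, yule50):
        cs = pic_contrasts(yule50, np.random.default_rng(0).normal(size=50))
        assert cs.n_contrasts == 49

    def test_unmatched_taxa_error(self, cherry):
        with pytest.raises(CochlevoError):
            pic_contrasts(cherry, pd.Series({"A": 1.0, "Z": 2.0}))

    def test_sigma2_estimator_unbiased(self, yule50):
        # mean of squared standardized contrasts is unbiased for sigma2
        sigma2 = 0.7
        ests = [
            pic_contrasts(
                yule50,
                synthetic_data.simulate_bm_traits(yule50, sigma2, seed=s)[0],
            ).sigma2_hat()
            for s in range(1000)
        ]
        assert np.mean(ests) == pytest.approx(sigma2, rel=0.05)


class TestAncestralStates:
    def test_two_tip_gls_root(self):
        # (A:1,B:3), x=(0,4): root = (0/1 + 4/3)/(1 + 1/3) = 1.0
        tree = read_newick("(A:1,B:3);")
        anc = ancestral_ml_bm(tree, pd.Series({"A": 0.0, "B": 4.0}))
        assert anc.root_estimate == pytest.approx(1.0)

    def test_symmetric_tree_root_matches_pic(self, four_tip_symmetric):
        x = pd.Series({"A": 1.0, "B": 3.0, "C": 5.0, "D": 7.0})
        anc = ancestral_ml_bm(four_tip_symmetric, x)
        assert anc.root_estimate == pytest.approx(4.0)

    def test_constant_trait(self, yule50):
        anc = ancestral_ml_bm(yule50, np.full(50, 2.5))
        assert np.allclose(anc.estimates, 2.5)
        assert np.allclose(anc.std_errors, 0.0, atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_message_passing_equals_dense_gls(self, seed):
        # two independent routes: O(n) belief propagation vs dense GLS
        tree = synthetic_data.simulate_yule_tree(
            8 + 7 * seed % 40 + 8, 1.0, seed=seed)
        x, _ = synthetic_data.simulate_bm_traits(tree, 1.0, seed=seed + 100)
        a_pic = AncestralBM(tree, x).fit(method="pic")
        a_ml = AncestralBM(tree, x).fit(method="ml")
        assert a_pic.estimates == pytest.approx(a_ml.estimates, abs=1e-8)
        assert a_pic.std_errors == pytest.approx(a_ml.std_errors, abs=1e-8)

    def test_root_recovery_on_average(self, yule50):
        roots = [
            ancestral_ml_bm(
                yule50,
                synthetic_data.simulate_bm_traits(
                    yule50, 1.0, root_state=5.0, seed=s)[0],
                method="pic").root_estimate
            for s in range(200)
        ]
        assert np.mean(roots) == pytest.approx(5.0, abs=0.25)


class TestBMLikelihood:
    @pytest.mark.parametrize("seed", range(6))
    def test_contrast_equals_dense_evaluation(self, seed):
        tree = synthetic_data.simulate_yule_tree(20 + seed, 1.0, seed=seed)
        x, _ = synthetic_data.simulate_bm_traits(tree, 0.5, seed=seed)
        ll_c, s2_c, mu_c = bm_loglik(tree, x)
        ll_d, s2_d, mu_d = bm_loglik_dense(tree, x)
        assert ll_c == pytest.approx(ll_d, abs=1e-8)
        assert s2_c == pytest.approx(s2_d, abs=1e-10)
        assert mu_c == pytest.approx(mu_d, abs=1e-10)

    def test_lambda_one_transform_is_identity(self, yule50):
        x, _ = synthetic_data.simulate_bm_traits(yule50, 1.0, seed=1)
        ll_plain = bm_loglik(yule50, x)[0]
        ll_transformed = bm_loglik(lambda_rescale(yule50, 1.0), x)[0]
        assert ll_plain == pytest.approx(ll_transformed, abs=1e-12)


class TestPagelLambda:
    def test_profile_peak_beats_boundaries(self, yule50):
        x, _ = synthetic_data.simulate_bm_traits(yule50, 1.0, seed=7)
        fit = fit_lambda(yule50, x)
        assert fit.loglik >= fit.loglik_0 - 1e-9
        assert fit.loglik >= fit.loglik_1 - 1e-9
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert 0.0 <= fit.p_vs_0 <= 1.0 and 0.0 <= fit.p_vs_1 <= 1.0

    def test_bm_trait_high_lambda(self, yule50):
        x, _ = synthetic_data.simulate_bm_traits(yule50, 1.0, seed=3)
        fit = fit_lambda(yule50, x)
        assert fit.lambda_hat > 0.7
        assert fit.p_vs_0 < 0.05  # strong signal easily distinguished from star

    def test_iid_trait_low_lambda(self, yule50):
        rng = np.random.default_rng(11)
        fit = fit_lambda(yule50, rng.normal(size=50))
        assert fit.lambda_hat < 0.3
        assert fit.p_vs_1 < 0.05

    def test_small_tree_warns(self):
        tree = read_newick("((A:1,B:1):1,C:2):0;")
        with pytest.warns(UserWarning, match="tips"):
            PagelLambda(tree, np.array([0.0, 1.0, 2.0]))

    def test_summary_mentions_lambda(self, yule50):
        x, _ = synthetic_data.simulate_bm_traits(yule50, 1.0, seed=5)
        assert "lambda_hat" in fit_lambda(yule50, x).summary()


def test_traitgram_renders(yule50):
    import matplotlib
    matplotlib.use("Agg")
    x, _ = synthetic_data.simulate_bm_traits(yule50, 1.0, seed=2)
    ax = comparative.plot_traitgram(yule50, x)
    assert ax.get_xlabel() == "trait value"
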