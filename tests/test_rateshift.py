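import numpy as np
import pytest

from cochlevo import synthetic_data
from cochlevo.comparative import pic_contrasts
from cochlevo.exceptions import CochlevoError
from cochlevo.rateshift import (
    DEFAULT_MOVE_WEIGHTS,
    RateShiftModel,
    RateShiftPosterior,
    _Chain,
    rjmcmc_rates,
    shift_summary,
)


@pytest.fixture(scope="module")
def balanced32():
    return synthetic_data.balanced_tree(32, 10.0)


def _clade_node(tree, size):
    return next(v for v in range(tree.n_tips, tree.n_nodes)
                if len(tree.clade_tips(v)) == size)


class TestValidation:
    def test_too_few_tips(self):
        tree = synthetic_data.simulate_yule_tree(4, 1.0, seed=0)
        with pytest.raises(CochlevoError, match="tips"):
            RateShiftModel(tree, np.arange(4.0))

    def test_zero_variance_trait(self, balanced32):
        with pytest.raises(CochlevoError, match="variance"):
            RateShiftModel(balanced32, np.zeros(32))


class TestSingleRateReduction:
    def test_posterior_rate_matches_ml_sigma2(self, balanced32):
        # with birth/death/relocate disabled the sampler is a single-rate BM
        # model; its posterior mean rate must sit near the contrast ML rate
        x, _ = synthetic_data.simulate_bm_traits(balanced32, 0.05, seed=3)
        post = RateShiftModel(balanced32, x).fit(
            generations=40_000, sample_interval=40, seed=0,
            move_weights={"rate": 1.0})
        sigma2_ml = pic_contrasts(balanced32, x).sigma2_hat()
        assert np.allclose(post.branch_rates[:-1], post.branch_rates[0])
        assert post.branch_rates[0] == pytest.approx(sigma2_ml, rel=0.10)
        assert post.mean_n_shifts == 0.0


class _ScriptedRng:
    """Deterministic stand-in driving a specific proposal."""

    def __init__(self, integers=(), normals=()):
        self._ints = list(integers)
        self._norms = list(normals)

    def integers(self, n):
        return self._ints.pop(0)

    def normal(self, loc, scale):
        return loc + scale * self._norms.pop(0)


class TestDetailedBalance:
    def test_birth_death_log_ratios_are_antisymmetric(self, balanced32):
        x, _ = synthetic_data.simulate_bm_traits(balanced32, 0.05, seed=1)
        cs = pic_contrasts(balanced32, x)
        chain = _Chain(balanced32, x, 1.0, float(np.log(cs.sigma2_hat())), 2.0,
                       DEFAULT_MOVE_WEIGHTS, 0.5)
        logr_birth, (shifts, base, ll) = chain.propose_birth(
            _ScriptedRng(integers=[4], normals=[0.7]))
        (node,) = shifts
        chain.shifts, chain.base_log_rate, chain.loglik = shifts, base, ll
        idx = list(chain.shifts).index(node)
        logr_death, _ = chain.propose_death(_ScriptedRng(integers=[idx]))
        assert logr_birth == pytest.approx(-logr_death, abs=1e-10)

    def test_relocate_log_ratio_is_pure_likelihood(self, balanced32):
        x, _ = synthetic_data.simulate_bm_traits(balanced32, 0.05, seed=2)
        cs = pic_contrasts(balanced32, x)
        chain = _Chain(balanced32, x, 1.0, float(np.log(cs.sigma2_hat())), 2.0,
                       DEFAULT_MOVE_WEIGHTS, 0.5)
        node = chain.eligible[3]
        chain.shifts = {node: chain.mu0 + 1.0}
        chain.loglik = chain._loglik_with(chain.shifts, chain.base_log_rate)
        logr_fwd, (shifts, base, ll) = chain.propose_relocate(
            _ScriptedRng(integers=[0, 5]))
        (target,) = shifts
        chain.shifts, chain.loglik = shifts, ll
        back = [v for v in chain.eligible if v not in shifts].index(node)
        logr_rev, (shifts2, _, _) = chain.propose_relocate(
            _ScriptedRng(integers=[0, back]))
        assert set(shifts2) == {node}
        assert logr_fwd == pytest.approx(-logr_rev, abs=1e-10)


class TestDetection:
    def test_null_data_produce_no_significant_shift(self, balanced32):
        x, _ = synthetic_data.simulate_bm_traits(balanced32, 0.05, seed=40)
        post = RateShiftModel(balanced32, x).fit(
            generations=60_000, sample_interval=100, seed=0)
        assert post.shift_prob.max() < 0.95
        assert post.significant_shifts(0.95) == {}

    def test_hot_clade_detected_and_faster(self, balanced64):
        node = _clade_node(balanced64, 16)
        x, _ = synthetic_data.simulate_bm_traits(
            balanced64, 0.05, seed=41, rate_multipliers={node: 10.0})
        post = RateShiftModel(balanced64, x).fit(
            generations=80_000, sample_interval=100, seed=1)
        assert post.shift_prob[node] > 0.5
        inside = post.branch_rates[balanced64.clade_tips(node)].mean()
        outside = np.median(np.delete(post.branch_rates, balanced64.root))
        assert inside > outside

    def test_detection_power_increases_with_rate_multiplier(self, balanced32):
        node = _clade_node(balanced32, 8)
        probs = []
        for mult in (1.0, 2.0, 5.0, 10.0):
            per_seed = []
            for seed in range(3):
                x, _ = synthetic_data.simulate_bm_traits(
                    balanced32, 0.05, seed=50 + seed,
                    rate_multipliers={node: mult})
                post = RateShiftModel(balanced32, x).fit(
                    generations=50_000, sample_interval=100, seed=seed)
                per_seed.append(post.shift_prob[node])
            probs.append(np.mean(per_seed))
        assert probs[0] < 0.5
        assert probs[-1] > probs[0]
        for lo, hi in zip(probs, probs[1:]):
            assert hi >= lo - 0.05  # monotone up to Monte-Carlo noise

    def test_two_chains_correlate(self, balanced32):
        node = _clade_node(balanced32, 8)
        x, _ = synthetic_data.simulate_bm_traits(
            balanced32, 0.05, seed=60, rate_multipliers={node: 10.0})
        a = rjmcmc_rates(balanced32, x, generations=60_000,
                         sample_interval=100, seed=1)
        b = rjmcmc_rates(balanced32, x, generations=60_000,
                         sample_interval=100, seed=2)
        internal = np.arange(balanced32.n_tips, balanced32.n_nodes)
        r = np.corrcoef(a.shift_prob[internal], b.shift_prob[internal])[0, 1]
        assert r > 0.95

    def test_seed_determinism(self, balanced32):
        x, _ = synthetic_data.simulate_bm_traits(balanced32, 0.05, seed=61)
        a = rjmcmc_rates(balanced32, x, generations=10_000,
                         sample_interval=100, seed=9)
        b = rjmcmc_rates(balanced32, x, generations=10_000,
                         sample_interval=100, seed=9)
        assert np.array_equal(a.shift_prob, b.shift_prob)
        assert np.array_equal(a.branch_rates, b.branch_rates)


class TestShiftSummary:
    def _posterior(self, tree, probs, rates):
        return RateShiftPosterior(
            tree=tree, branch_rates=rates, relative_rates=rates / np.median(rates),
            shift_prob=probs, generations=1, sample_interval=1,
            burnin_fraction=0.0, seed=0, n_samples=1, acceptance={},
            mean_n_shifts=0.0)

    def test_all_below_threshold_empty(self, balanced32):
        probs = np.full(balanced32.n_nodes, 0.95)  # not strictly greater
        rates = np.ones(balanced32.n_nodes)
        assert shift_summary(self._posterior(balanced32, probs, rates)) == {}

    def test_decrease_direction(self, balanced32):
        node = _clade_node(balanced32, 8)
        probs = np.zeros(balanced32.n_nodes)
        probs[node] = 0.96
        rates = np.ones(balanced32.n_nodes)
        for v in balanced32.clade_tips(node):
            rates[v] = 0.1
        out = shift_summary(self._posterior(balanced32, probs, rates))
        assert out == {node: "decrease"}

    def test_threshold_one_always_empty(self, balanced32):
        probs = np.ones(balanced32.n_nodes)
        rates = np.ones(balanced32.n_nodes)
        post = self._posterior(balanced32, probs, rates)
        assert shift_summary(post, threshold=1.0) == {}

    def test_sample_count_contract(self, balanced32):
        x, _ = synthetic_data.simulate_bm_traits(balanced32, 0.05, seed=70)
        post = rjmcmc_rates(balanced32, x, generations=10_000,
                            sample_interval=100, burnin_fraction=0.25, seed=0)
        assert post.n_samples == 75
        assert "rjMCMC" in post.summary()
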