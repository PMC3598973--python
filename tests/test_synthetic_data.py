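import numpy as np
import pytest

from cochlevo import morphometry, phylo_io
from cochlevo.allometry import fit_ols
from cochlevo.exceptions import ConfigError
from cochlevo.synthetic_data import (
    SimulationConfig,
    balanced_tree,
    generate_spiral_path,
    generate_study_dataset,
    rescale_tree_depth,
    simulate_bm_traits,
    simulate_yule_tree,
)


class TestYuleTree:
    def test_two_tips_is_cherry(self):
        tree = simulate_yule_tree(2, 1.0, seed=0)
        assert tree.n_tips == 2
        assert phylo_io.is_ultrametric(tree)

    def test_hundred_tips_structure(self):
        tree = simulate_yule_tree(100, 1.0, seed=1)
        assert tree.n_tips == 100
        assert tree.n_nodes - tree.n_tips == 99
        assert tree.is_binary()
        assert phylo_io.is_ultrametric(tree, rel_tol=1e-9)

    def test_seed_reproducibility(self):
        a = simulate_yule_tree(30, 2.0, seed=7)
        b = simulate_yule_tree(30, 2.0, seed=7)
        assert np.array_equal(a.lengths, b.lengths)

    def test_mean_root_height_matches_yule_expectation(self):
        n, rate = 12, 1.5
        heights = [simulate_yule_tree(n, rate, seed=s).total_depth()
                   for s in range(1000)]
        expected = sum(1.0 / (rate * k) for k in range(2, n + 1))
        assert np.mean(heights) == pytest.approx(expected, rel=0.1)

    @pytest.mark.parametrize("n,rate", [(1, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_parameters(self, n, rate):
        with pytest.raises(ConfigError):
            simulate_yule_tree(n, rate, seed=0)

    def test_seed_mandatory(self):
        with pytest.raises(ConfigError):
            simulate_yule_tree(5, 1.0)


class TestBMTraits:
    def test_zero_rate_returns_root_state(self, yule50):
        x, states = simulate_bm_traits(yule50, 0.0, root_state=3.0, seed=0)
        assert np.allclose(x, 3.0)
        assert np.allclose(states, 3.0)

    def test_tip_variance_matches_bm_marginal(self):
        tree = balanced_tree(8, 5.0)  # every tip at depth 15
        sigma2 = 0.4
        draws = np.array([
            simulate_bm_traits(tree, sigma2, seed=s)[0] for s in range(2000)
        ])
        tip_var = draws.var(axis=0, ddof=1).mean()
        assert tip_var == pytest.approx(sigma2 * 15.0, rel=0.05)

    def test_clade_multiplier_raises_inside_variance(self, balanced64):
        node = next(v for v in range(64, balanced64.n_nodes)
                    if len(balanced64.clade_tips(v)) == 16)
        inside_var, outside_var = [], []
        for s in range(60):
            x, _ = simulate_bm_traits(balanced64, 0.05, seed=s,
                                      rate_multipliers={node: 10.0})
            tips = balanced64.clade_tips(node)
            inside_var.append(np.var(np.subtract(*x[tips[:2]][None].T)))
            inside_var[-1] = np.var(x[tips])
            outside_var.append(np.var(np.delete(x, tips)))
        assert np.mean(inside_var) > np.mean(outside_var)

    def test_unknown_clade_id_rejected(self, yule50):
        with pytest.raises(ConfigError, match="unknown clade"):
            simulate_bm_traits(yule50, 1.0, seed=0, rate_multipliers={999: 2.0})

    def test_lambda_dilution_reduces_phylogenetic_signal(self, yule50):
        from cochlevo.comparative import fit_lambda
        lam_hats = []
        for s in range(10):
            x, _ = simulate_bm_traits(yule50, 1.0, lam=0.2, seed=s)
            lam_hats.append(fit_lambda(yule50, x).lambda_hat)
        assert np.median(lam_hats) < 0.6


class TestSpiralPath:
    def test_generator_and_measurer_agree_on_turns(self):
        path, _, true_turns = generate_spiral_path(2.5, noise_sd=0.0, seed=0)
        assert morphometry.count_turns(path).quarter_rounded == true_turns

    def test_86_points_within_half_percent_of_quadrature(self):
        path, true_len, _ = generate_spiral_path(2.5, n_points=86, seed=0)
        measured = morphometry.polyline_length(path)
        assert measured <= true_len
        assert measured == pytest.approx(true_len, rel=5e-3)

    def test_43_points_underestimate_more(self):
        p86, true_len, _ = generate_spiral_path(2.5, n_points=86, seed=0)
        p43, _, _ = generate_spiral_path(2.5, n_points=43, seed=0)
        l86 = morphometry.polyline_length(p86)
        l43 = morphometry.polyline_length(p43)
        assert l43 < l86
        # shortfall on the order of a few percent
        assert 1e-4 < (true_len - l43) / true_len < 0.05

    def test_invalid_geometry(self):
        with pytest.raises(Exception):
            generate_spiral_path(-1.0, seed=0)
        with pytest.raises(Exception):
            generate_spiral_path(2.0, n_points=1, seed=0)

    def test_noise_reproducible(self):
        a, _, _ = generate_spiral_path(2.0, noise_sd=0.01, seed=5)
        b, _, _ = generate_spiral_path(2.0, noise_sd=0.01, seed=5)
        assert np.array_equal(a.points, b.points)


@pytest.fixture(scope="module")
def dataset():
    return generate_study_dataset(SimulationConfig(n_species=120, seed=11))


class TestStudyDataset:
    def test_outputs_pass_validators(self, dataset):
        phylo_io.validate_trait_table(dataset.traits)
        assert phylo_io.is_ultrametric(dataset.tree, rel_tol=1e-6)
        assert list(dataset.traits["species"]) == dataset.tree.tip_labels

    def test_reproducible(self, dataset):
        again = generate_study_dataset(SimulationConfig(n_species=120, seed=11))
        assert again.traits.equals(dataset.traits)
        assert np.array_equal(again.tree.lengths, dataset.tree.lengths)

    def test_echolocators_form_a_clade_with_calls(self, dataset):
        is_echo = dataset.truth["is_echolocator"]
        traits = dataset.traits
        assert set(traits.loc[is_echo, "echolocation_type"]) <= \
            {"CF", "FM", "broadband"}
        assert traits.loc[is_echo, "call_peak"].notna().all()
        assert traits.loc[~is_echo, "call_peak"].isna().all()
        clade_tips = set(dataset.truth["echolocator_species"])
        mrca = dataset.tree.mrca(clade_tips)
        assert set(dataset.tree.labels[i]
                   for i in dataset.tree.clade_tips(mrca)) == clade_tips

    def test_zero_offset_zero_noise_all_within(self):
        config = SimulationConfig(n_species=80, seed=3, echolocator_offset=0.0,
                                  noise_membrane=0.0, sigma2_membrane_dev=0.0)
        ds = generate_study_dataset(config)
        x = np.log10(ds.traits["mass"].to_numpy() ** (1 / 3))
        y = np.log10(ds.traits["membrane_length"].to_numpy())
        fit = fit_ols(y, x)
        with pytest.warns(UserWarning, match="width 0"):
            cls = fit.classify(x[:, None], y)
        assert (cls == "within").all()

    def test_echolocator_offset_classified_above(self):
        config = SimulationConfig(n_species=200, seed=4,
                                  echolocator_offset=0.12)
        ds = generate_study_dataset(config)
        is_echo = ds.truth["is_echolocator"]
        x = np.log10(ds.traits["mass"].to_numpy() ** (1 / 3))
        y = np.log10(ds.traits["membrane_length"].to_numpy())
        fit = fit_ols(y, x, mask=~is_echo)
        cls = fit.classify(x[:, None], y)
        assert (cls[is_echo] == "above").mean() > 0.5

    def test_allometric_slope_recovered(self):
        config = SimulationConfig(n_species=200, seed=5)
        ds = generate_study_dataset(config)
        is_echo = ds.truth["is_echolocator"]
        x = np.log10(ds.traits["mass"].to_numpy() ** (1 / 3))
        y = np.log10(ds.traits["membrane_length"].to_numpy())
        fit = fit_ols(y, x, mask=~is_echo)
        assert fit.params[1] == pytest.approx(config.allometric_slope, rel=0.05)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_species=100).validate()  # no seed
        with pytest.raises(ConfigError):
            SimulationConfig(n_species=2, seed=0).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(seed=0, lam=1.5).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(seed=0, rate_multipliers={"bats": 2.0}).validate()


class TestTreeHelpers:
    def test_balanced_tree_shape(self):
        tree = balanced_tree(16, 4.0)
        assert tree.n_tips == 16
        assert np.allclose(tree.tip_depths(), 16.0)
        with pytest.raises(ConfigError):
            balanced_tree(12)

    def test_rescale_depth(self, yule50):
        scaled = rescale_tree_depth(yule50, 64.0)
        assert scaled.total_depth() == pytest.approx(64.0)
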