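"""Simulated neurons, texture-modulation statistics, PLS predictivity,
partitioning, and distributional/rank comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcl.neuroeval import (NeuralDataset, family_rank_compare,
                           fit_pls_predictivity, load_neural_dataset,
                           modulation_index, partition_neurons, qq_compare,
                           relative_improvement, save_neural_dataset,
                           select_best_layer, simulate_v2_neurons,
                           PredictivityResult)
from lcl.stimuli import build_v2_stimulus_set


def make_dataset(responses, meta):
    return NeuralDataset(responses=np.asarray(responses, float), meta=meta)


@pytest.fixture(scope="module")
def stim():
    return build_v2_stimulus_set(n_families=5, n_samples=6, size=64, rng_seed=1)


class TestSimulateV2Neurons:
    def test_default_shape_matches_canonical_dataset(self, stim):
        data = simulate_v2_neurons(stim, rng_seed=0)
        assert data.responses.shape == (103, len(stim))
        assert data.responses.min() >= 0

    def test_reproducible_given_seed(self, stim):
        a = simulate_v2_neurons(stim, rng_seed=5)
        b = simulate_v2_neurons(stim, rng_seed=5)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_noiseless_metadata_mode_has_analytic_rmod(self, stim):
        data = simulate_v2_neurons(stim, n_neurons=20, noise_sd=0.0, rng_seed=2)
        table = modulation_index(data)
        np.testing.assert_allclose(table.per_pair, data.ground_truth["rmod"],
                                   atol=1e-12)

    def test_feature_mode_requires_basis(self, stim):
        with pytest.raises(ValueError, match="feature_basis"):
            simulate_v2_neurons(stim, mode="feature")

    def test_invalid_ranges_rejected(self, stim):
        with pytest.raises(ValueError, match="ordered"):
            simulate_v2_neurons(stim, baseline_range=(5.0, 1.0))


class TestModulationIndex:
    def _meta(self, n_fam=2, n_samp=2):
        rows = [(f, s, c) for f in range(n_fam) for s in range(n_samp)
                for c in ("texture", "noise")]
        return pd.DataFrame(rows, columns=["family_id", "sample_id", "condition"])

    def test_trivial_values(self):
        meta = self._meta(1, 1)  # columns: texture, noise
        assert modulation_index(
            make_dataset([[2.0, 2.0]], meta)).per_pair[0, 0] == 0.0
        assert modulation_index(
            make_dataset([[1.0, 0.0]], meta)).per_pair[0, 0] == 1.0
        assert modulation_index(
            make_dataset([[3.0, 1.0]], meta)).per_pair[0, 0] == 0.5

    def test_sample_averaging_before_the_ratio(self):
        meta = self._meta(1, 2)  # texture, noise, texture, noise
        resp = [[4.0, 1.0, 2.0, 1.0]]  # tex mean 3, noise mean 1 -> 0.5
        assert modulation_index(make_dataset(resp, meta)).per_pair[0, 0] == 0.5

    def test_undefined_pairs_excluded_from_averages(self):
        meta = self._meta(2, 1)
        resp = [[0.0, 0.0, 3.0, 1.0]]  # family 0 undefined, family 1 -> 0.5
        table = modulation_index(make_dataset(resp, meta))
        assert np.isnan(table.per_pair[0, 0])
        assert table.per_neuron[0] == 0.5

    def test_aggregation_levels_consistent(self, stim):
        data = simulate_v2_neurons(stim, n_neurons=12, rng_seed=3)
        t = modulation_index(data)
        np.testing.assert_allclose(t.per_neuron, np.nanmean(t.per_pair, 1),
                                   atol=1e-12)
        np.testing.assert_allclose(t.per_family, np.nanmean(t.per_pair, 0),
                                   atol=1e-12)

    def test_bounded_for_nonnegative_responses(self, stim):
        data = simulate_v2_neurons(stim, n_neurons=30, noise_sd=4.0, rng_seed=4)
        t = modulation_index(data)
        finite = t.per_pair[np.isfinite(t.per_pair)]
        assert np.all(np.abs(finite) <= 1)

    def test_analytic_recovery_with_many_samples(self):
        """Estimated Rmod approaches g*m/(2b + g*m) as the per-family sample
        count grows and the noise shrinks (100 samples, noise 1% of
        baseline)."""
        stim_large = build_v2_stimulus_set(n_families=3, n_samples=100,
                                           size=32, rng_seed=9)
        data = simulate_v2_neurons(stim_large, n_neurons=15,
                                   baseline_range=(10.0, 10.0),
                                   noise_sd=0.1, rng_seed=10)
        table = modulation_index(data)
        err = np.abs(table.per_pair - data.ground_truth["rmod"]).max()
        assert err < 0.02


class TestPLSPredictivity:
    def test_recovers_feature_driven_neurons(self, full_stimulus_set, rng):
        stim = full_stimulus_set
        basis = rng.normal(size=(len(stim), 40))
        data = simulate_v2_neurons(stim, n_neurons=25, mode="feature",
                                   feature_basis=basis, noise_sd=0.0,
                                   rng_seed=0)
        res = fit_pls_predictivity(basis, data, n_components=25, rng_seed=0)
        assert res.median >= 0.95

    def test_null_neurons_score_near_zero(self, full_stimulus_set, rng):
        stim = full_stimulus_set
        basis = rng.normal(size=(len(stim), 40))
        null = NeuralDataset(
            responses=np.abs(rng.normal(size=(25, len(stim)))),
            meta=stim.meta.copy())
        res = fit_pls_predictivity(basis, null, n_components=25, rng_seed=0)
        assert res.median <= 0.05

    def test_monotone_degradation_with_noise(self, full_stimulus_set, rng):
        stim = full_stimulus_set
        basis = rng.normal(size=(len(stim), 40))
        medians = []
        for noise_sd in (0.0, 2.0, 8.0, 32.0):
            data = simulate_v2_neurons(stim, n_neurons=15, mode="feature",
                                       feature_basis=basis, noise_sd=noise_sd,
                                       rng_seed=1)
            medians.append(
                fit_pls_predictivity(basis, data, n_components=10,
                                     rng_seed=1).median)
        assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_duplicated_feature_columns_leave_scores_unchanged(self, stim, rng):
        basis = rng.normal(size=(len(stim), 20))
        data = simulate_v2_neurons(stim, n_neurons=10, mode="feature",
                                   feature_basis=basis, noise_sd=1.0, rng_seed=2)
        r1 = fit_pls_predictivity(basis, data, n_components=8, rng_seed=3)
        r2 = fit_pls_predictivity(np.hstack([basis, basis]), data,
                                  n_components=8, rng_seed=3)
        np.testing.assert_allclose(r1.per_neuron, r2.per_neuron, atol=1e-6)


def _result(median):
    return PredictivityResult(per_neuron_per_fold=np.zeros((1, 1)),
                              per_neuron=np.array([median]), median=median,
                              n_components=1, n_folds=1)


class TestSelectBestLayer:
    def test_single_layer(self):
        assert select_best_layer({2: _result(0.3)}) == 2

    def test_validation_winner_selected(self):
        assert select_best_layer({1: _result(0.5), 2: _result(0.3)}) == 1

    def test_tie_goes_to_lower_index(self):
        assert select_best_layer({1: _result(0.4), 2: _result(0.4)}) == 1


class TestPartitionNeurons:
    def test_canonical_103_gives_26_per_quartile(self, rng):
        v1_like, v2_like = partition_neurons(rng.random(103))
        assert len(v1_like) == 26 and len(v2_like) == 26
        assert not set(v1_like) & set(v2_like)

    def test_small_n_uses_ceiling(self, rng):
        v1_like, v2_like = partition_neurons(rng.random(8))
        assert len(v1_like) == 2 and len(v2_like) == 2

    def test_ordering_by_score(self):
        scores = np.arange(12) / 12.0
        v1_like, v2_like = partition_neurons(scores)
        assert set(v1_like) == {9, 10, 11}
        assert set(v2_like) == {0, 1, 2}


class TestQQCompare:
    def test_identical_samples_on_identity_line(self, rng):
        x = rng.normal(size=200)
        _, mq, rq, gap = qq_compare(x, x.copy())
        assert gap == 0.0
        np.testing.assert_array_equal(mq, rq)

    def test_location_shift_appears_in_all_quantiles(self, rng):
        x = rng.normal(size=5000)
        probs, mq, rq, gap = qq_compare(x + 0.2, x)
        np.testing.assert_allclose(mq - rq, 0.2, atol=1e-9)

    def test_beta_samples_match_analytic_quantile_gap(self):
        r = np.random.default_rng(0)
        a = r.beta(2, 5, size=40_000)
        b = r.beta(5, 2, size=40_000)
        probs, mq, rq, _ = qq_compare(a, b, n_quantiles=10)
        expected = stats.beta.ppf(probs, 2, 5) - stats.beta.ppf(probs, 5, 2)
        np.testing.assert_allclose(mq - rq, expected, atol=0.02)


class TestFamilyRankCompare:
    def test_identical_and_reversed_rankings(self):
        v = np.array([0.1, 0.4, 0.2, 0.8, 0.6])
        assert family_rank_compare(v, v).rho == pytest.approx(1.0)
        assert family_rank_compare(v, -v).rho == pytest.approx(-1.0)

    def test_closed_form_on_tie_free_vectors(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        d2 = np.sum((ra - rb) ** 2)
        expected = 1 - 6 * d2 / (5 * (25 - 1))
        assert family_rank_compare(a, b).rho == pytest.approx(expected)

    def test_exhaustive_t4_permutations(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        for perm in itertools.permutations(range(4)):
            other = base[list(perm)]
            d2 = np.sum((stats.rankdata(base) - stats.rankdata(other)) ** 2)
            expected = 1 - 6 * d2 / (4 * 15)
            assert family_rank_compare(base, other).rho == pytest.approx(expected)

    def test_paired_bootstrap_separates_clear_winner(self, rng):
        """A model whose family profile tracks the reference should beat an
        anti-correlated competitor with a small p-value."""
        n_neurons, n_fam = 40, 8
        ref = rng.normal(size=(n_neurons, n_fam)) * 0.1 + np.linspace(0, 1, n_fam)
        model = rng.normal(size=(n_neurons, n_fam)) * 0.1 + np.linspace(0, 1, n_fam)
        comp = rng.normal(size=(n_neurons, n_fam)) * 0.1 + np.linspace(1, 0, n_fam)
        res = family_rank_compare(
            model.mean(0), ref.mean(0),
            model_table=model, reference_table=ref,
            competitor_per_family=comp.mean(0), competitor_table=comp,
            n_bootstrap=500, rng_seed=0)
        assert res.rho > 0.9 and res.competitor_rho < -0.9
        assert res.delta_rho_p_value < 0.05

    def test_constant_vector_gives_nan_rho(self):
        res = family_rank_compare(np.ones(5), np.arange(5.0))
        assert np.isnan(res.rho)


class TestRelativeImprovement:
    def test_headline_consistency_numbers(self):
        assert round(relative_improvement(0.211, 0.165)) == 28

    def test_identity_and_doubling(self):
        assert relative_improvement(0.4, 0.4) == 0.0
        assert relative_improvement(0.8, 0.4) == pytest.approx(100.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            relative_improvement(0.5, 0.0)


def test_neural_dataset_io_round_trip(tmp_path, stim):
    data = simulate_v2_neurons(stim, n_neurons=7, rng_seed=6)
    path = tmp_path / "neurons.npz"
    save_neural_dataset(data, path)
    loaded = load_neural_dataset(path)
    np.testing.assert_array_equal(loaded.responses, data.responses)
    assert loaded.meta.family_id.tolist() == data.meta.family_id.tolist()
    csv = pd.read_csv(path.with_suffix(".csv"))
    assert len(csv) == data.responses.size
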