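"""Fold assignment, normalized RMSE, CV protocol and model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msbind import (
    FitConfig,
    SimConfig,
    compare_models,
    correlate,
    crossval_ms,
    crossval_ss,
    make_folds,
    normalized_rmse,
    scan_windows,
    simulate,
    ss_candidate_model_count,
)
from msbind.evaluation import CVReport, WindowScan


class TestMakeFolds:
    def test_canonical_split_1000_into_10(self):
        folds = make_folds(1000, 10, seed=1)
        sizes = np.bincount(folds.fold_index, minlength=10)
        assert np.all(sizes == 100)

    def test_leave_one_out_when_n_equals_k(self):
        folds = make_folds(10, 10, seed=0)
        assert sorted(folds.fold_index) == list(range(10))

    def test_same_seed_same_assignment(self):
        a = make_folds(57, 5, seed=11)
        b = make_folds(57, 5, seed=11)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(10, 1, seed=0)

    @given(n=st.integers(4, 200), k=st.integers(2, 10), seed=st.integers(0, 5))
    def test_partition_property(self, n, k, seed):
        if n < k:
            return
        folds = make_folds(n, k, seed)
        sizes = np.bincount(folds.fold_index, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        # every record is in exactly one fold by construction of fold_index
        assert folds.fold_index.shape == (n,)


class TestNormalizedRMSE:
    def test_perfect_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert normalized_rmse(obs, obs) == 0.0

    def test_hand_computed_example(self):
        # RMS error 1, sd sqrt(2) -> 1/sqrt(2)
        assert normalized_rmse(np.array([1.0, 1.0]), np.array([0.0, 2.0])) == (
            pytest.approx(0.70710678, abs=1e-8)
        )

    def test_mean_predictor_scores_sqrt_n_minus_1_over_n(self, rng):
        obs = rng.normal(size=50)
        pred = np.full_like(obs, obs.mean())
        assert normalized_rmse(pred, obs) == pytest.approx(
            np.sqrt(49 / 50), abs=1e-12
        )

    def test_mean_predictor_baseline_concentrates_near_one(self, rng):
        """The 'random' baseline: a train-mean predictor scores ~1 on large folds."""
        train = rng.normal(size=2000)
        test = rng.normal(size=2000)
        pred = np.full_like(test, train.mean())
        assert abs(normalized_rmse(pred, test) - 1.0) < 0.1

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalized_rmse(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestCorrelate:
    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(x, 2 * x + 1) == pytest.approx(1.0)
        assert correlate(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert correlate([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


@pytest.fixture(scope="module")
def noiseless_ms_data():
    # 300 peptides for ~58 free parameters: a data/parameter ratio comparable
    # to the canonical 1000-spot arrays
    return simulate(
        SimConfig(n_peptides=300, lengths=((8, 1.0),), true_S=3,
                  noise_sd=0.0, seed=21)
    )


@pytest.fixture(scope="module")
def noisy_ms_data():
    return simulate(
        SimConfig(n_peptides=200, lengths=((8, 1.0),), true_S=3,
                  noise_sd=0.1, seed=22)
    )


FAST = FitConfig(n_restarts=1, seed=0)


class TestCrossvalMS:
    def test_noiseless_truth_is_predicted_almost_exactly(self, noiseless_ms_data):
        report = crossval_ms(noiseless_ms_data.records, 3, k=10, seed=1, config=FAST)
        assert report.mean_rmse < 0.05
        assert not report.incomplete
        assert len(report.fold_rmse) == 10
        assert report.alpha_selected == pytest.approx(
            float(np.median(report.fold_alphas))
        )

    def test_noisy_truth_hits_the_noise_floor(self, noisy_ms_data):
        """Mean normalized RMSE lands between ~the noise floor and 1."""
        report = crossval_ms(noisy_ms_data.records, 3, k=10, seed=1, config=FAST)
        obs_sd = float(
            np.std([r.pseudo_energy for r in noisy_ms_data.records], ddof=1)
        )
        floor = 0.1 / obs_sd
        assert 0.8 * floor <= report.mean_rmse <= 1.0


class TestCrossvalSS:
    def test_recovers_the_generating_site(self):
        ds = simulate(
            SimConfig(n_peptides=150, lengths=((8, 1.0),), true_S=3,
                      truth_kind="SS", true_site=3, noise_sd=0.05, seed=23)
        )
        report = crossval_ss(ds.records, 3, k=10, seed=1)
        assert report.site_offset == 3

    def test_full_length_window_has_one_candidate_site(self, noiseless_ms_data):
        report = crossval_ss(noiseless_ms_data.records, 8, k=5, seed=1)
        assert report.site_offset == 0
        assert len(report.per_site_mean_rmse) == 1

    def test_candidate_count_matches_triangular_number(self):
        assert ss_candidate_model_count(14) == 14 * 15 // 2 == 105


class TestScanAndCompare:
    def test_ms_scan_recovers_the_true_window_size(self, noisy_ms_data):
        scan = scan_windows(noisy_ms_data.records, "MS", [2, 3, 4], k=5,
                            seed=2, config=FAST)
        assert scan.best_S == 3

    def test_ss_scan_error_non_increasing_up_to_true_size(self):
        ds = simulate(
            SimConfig(n_peptides=200, lengths=((8, 1.0),), true_S=4,
                      truth_kind="SS", true_site=0, noise_sd=0.05, seed=24)
        )
        scan = scan_windows(ds.records, "SS", [1, 2, 3, 4], k=5, seed=2)
        means = [rep.mean_rmse for rep in scan.reports]
        assert all(means[i + 1] <= means[i] + 1e-6 for i in range(3))

    def test_single_size_scan_selects_it(self, noiseless_ms_data):
        scan = scan_windows(noiseless_ms_data.records, "MS", [3], k=5,
                            seed=2, config=FAST)
        assert scan.best_S == 3

    def test_empty_scan_rejected(self, noiseless_ms_data):
        with pytest.raises(ValueError):
            scan_windows(noiseless_ms_data.records, "MS", [], k=5, seed=2)

    @staticmethod
    def _scan(kind, fold_rmse, S=3, n=100, k=5, seed=0):
        rep = CVReport(kind=kind, S=S, k=k, seed=seed, n_records=n,
                       fold_rmse=tuple(fold_rmse))
        return WindowScan(kind=kind, reports=(rep,), best_S=S, k=k,
                          seed=seed, n_records=n)

    def test_identical_fold_errors_give_zero_decrease(self):
        ms = self._scan("MS", [0.8] * 5)
        ss = self._scan("SS", [0.8] * 5)
        assert compare_models(ms, ss).mean_percent_decrease == 0.0

    def test_percent_decrease_arithmetic(self):
        ms = self._scan("MS", [0.909] * 5)
        ss = self._scan("SS", [1.0] * 5)
        assert compare_models(ms, ss).mean_percent_decrease == pytest.approx(9.1)

    def test_swapping_model_labels_flips_the_sign(self):
        ms = self._scan("MS", [0.7, 0.8, 0.9, 0.7, 0.8])
        ss = self._scan("SS", [0.9, 0.9, 1.0, 0.8, 0.9])
        fwd = compare_models(ms, ss).mean_percent_decrease
        swapped = compare_models(
            self._scan("MS", [0.9, 0.9, 1.0, 0.8, 0.9]),
            self._scan("SS", [0.7, 0.8, 0.9, 0.7, 0.8]),
        ).mean_percent_decrease
        assert fwd > 0 > swapped

    def test_fold_mismatch_rejected(self):
        ms = self._scan("MS", [0.8] * 5, seed=0)
        ss = self._scan("SS", [0.8] * 5, seed=1)
        with pytest.raises(ValueError, match="identical folds"):
            compare_models(ms, ss)
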