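import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dsir.validation as validation
from dsir import (
    BoxStats,
    CVConfig,
    DSVector,
    aggregate_predictions,
    box_stats,
    mae,
    mre,
    repeated_kfold,
    sweep_k,
)
from dsir.errors import ConfigurationError, DivisionDomainError, ValidationError


class TestMetrics:
    def test_mae_examples(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae([0.5, 1.5], [1.0, 1.0]) == pytest.approx(0.5)
        assert mae([2.9], [3.0]) == pytest.approx(0.1)

    def test_mae_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(size=10), rng.uniform(size=10)
        assert mae(a, b) == mae(b, a)

    def test_mre_examples(self):
        assert mre([1.0], [1.0]) == 0.0
        assert mre([1.1], [1.0]) == pytest.approx(10.0)

    def test_mre_zero_reference_rejected(self):
        with pytest.raises(DivisionDomainError):
            mre([1.0, 2.0], [1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mae([1.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_metrics_match_naive_loops(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        ev = rng.uniform(0, 3, n)
        ref = rng.uniform(0.1, 3, n)
        naive_mae = sum(abs(e - r) for e, r in zip(ev, ref)) / n
        naive_mre = sum(abs(e - r) / r for e, r in zip(ev, ref)) / n * 100
        assert mae(ev, ref) == pytest.approx(naive_mae, abs=1e-12)
        assert mre(ev, ref) == pytest.approx(naive_mre, abs=1e-10)


class TestRepeatedKFold:
    def test_paper_protocol_fold_sizes(self, synth16):
        spectra, ds, _ = synth16
        res = repeated_kfold(spectra, ds, CVConfig(k=8, n_repeats=2, base_seed=0))
        assert (res.fold_metrics["n_test"] == 2).all()  # 16 samples, 8 folds -> 12.5%

    def test_folds_partition_each_repetition(self, synth16):
        spectra, ds, _ = synth16
        res = repeated_kfold(spectra, ds, CVConfig(k=5, n_repeats=3, base_seed=1))
        for _, rep in res.predictions.groupby("repetition"):
            assert sorted(rep["sample_id"]) == sorted(spectra.sample_ids)

    def test_each_sample_tested_exactly_n_times(self, synth16):
        spectra, ds, _ = synth16
        res = repeated_kfold(spectra, ds, CVConfig(k=4, n_repeats=6, base_seed=2))
        counts = res.predictions["sample_id"].value_counts()
        assert (counts == 6).all()

    def test_bit_identical_reproducibility(self, synth16):
        spectra, ds, _ = synth16
        cfg = CVConfig(k=8, n_repeats=2, base_seed=17)
        a = repeated_kfold(spectra, ds, cfg)
        b = repeated_kfold(spectra, ds, cfg)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.overall_mae == b.overall_mae

    def test_k_exceeding_s_rejected(self, synth16):
        spectra, ds, _ = synth16
        with pytest.raises(ConfigurationError):
            repeated_kfold(spectra, ds, CVConfig(k=99, n_repeats=1, base_seed=0))

    def test_n_best_exceeding_features_rejected(self, synth16):
        spectra, ds, _ = synth16
        cfg = CVConfig(k=4, n_repeats=1, base_seed=0,
                       selection_scope="per_fold", n_best=10**6)
        with pytest.raises(ValidationError):
            repeated_kfold(spectra, ds, cfg)

    def test_fold_sizes_differ_by_at_most_one(self, synth16):
        spectra, ds, _ = synth16
        for k in (3, 5, 7):
            res = repeated_kfold(spectra, ds, CVConfig(k=k, n_repeats=1, base_seed=0))
            sizes = res.fold_metrics["n_test"]
            assert sizes.max() - sizes.min() <= 1
            assert sizes.sum() == spectra.n_samples

    def test_selection_sees_only_training_rows(self, synth16, monkeypatch):
        """Leakage guard: per-fold scoring receives S - |test fold| rows."""
        spectra, ds, _ = synth16
        seen = []
        orig = validation.score_features

        def spy(T, D):
            seen.append(T.n_samples)
            return orig(T, D)

        monkeypatch.setattr(validation, "score_features", spy)
        repeated_kfold(
            spectra, ds,
            CVConfig(k=8, n_repeats=2, base_seed=0, selection_scope="per_fold", n_best=50),
        )
        assert seen and all(s == 14 for s in seen)  # 16 samples minus 2 test rows

    def test_region_restriction_applied(self, synth16):
        spectra, ds, _ = synth16
        res = repeated_kfold(
            spectra, ds, CVConfig(k=4, n_repeats=1, base_seed=0, region="CH")
        )
        assert res.overall_mae >= 0.0  # runs on ~49 columns without error


class TestAggregatePredictions:
    def _result(self, rows):
        pred = pd.DataFrame(rows)
        return validation.CVResult(
            config=CVConfig(k=2, n_repeats=1, base_seed=0),
            predictions=pred,
            fold_metrics=pd.DataFrame(),
            repetition_metrics=pd.DataFrame(),
            overall_mae=0.0,
            overall_mre=0.0,
        )

    def test_hand_computed_mean_and_sd(self):
        res = self._result(
            [
                {"repetition": 0, "fold": 0, "sample_id": "a", "ds_ref": 1.0, "ds_pred": 1.0},
                {"repetition": 1, "fold": 1, "sample_id": "a", "ds_ref": 1.0, "ds_pred": 1.2},
            ]
        )
        agg = aggregate_predictions(res)
        assert agg.loc[0, "mean"] == pytest.approx(1.1)
        assert agg.loc[0, "sd"] == pytest.approx(0.1414213562, abs=1e-9)

    def test_single_repetition_sd_zero(self, synth16):
        spectra, ds, _ = synth16
        res = repeated_kfold(spectra, ds, CVConfig(k=4, n_repeats=1, base_seed=0))
        agg = aggregate_predictions(res)
        assert (agg["sd"] == 0.0).all()

    def test_triangle_inequality_sanity_bound(self, synth16):
        spectra, ds, _ = synth16
        res = repeated_kfold(spectra, ds, CVConfig(k=8, n_repeats=4, base_seed=5))
        agg = aggregate_predictions(res)
        lhs = np.mean(np.abs(agg["mean"] - agg["ds_ref"]))
        assert lhs <= res.overall_mae + agg["sd"].max() + 1e-12


class TestBoxStats:
    def test_five_point_example(self):
        bs = box_stats([1, 2, 3, 4, 5])
        assert (bs.q1, bs.median, bs.q3) == (2.0, 3.0, 4.0)
        assert (bs.whisker_low, bs.whisker_high) == (1.0, 5.0)
        assert bs.outliers == ()
        assert bs.mean == 3.0

    def test_all_equal(self):
        bs = box_stats([2.0, 2.0, 2.0])
        assert bs.q1 == bs.median == bs.q3 == bs.whisker_low == bs.whisker_high == 2.0
        assert bs.outliers == ()

    def test_outlier_detection(self):
        bs = box_stats([1, 2, 3, 4, 100])
        assert bs.whisker_high == 4.0
        assert bs.outliers == (100.0,)

    def test_whiskers_are_attained_data_points(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=200)
        bs = box_stats(v)
        assert bs.whisker_low in v and bs.whisker_high in v
        iqr = bs.q3 - bs.q1
        assert bs.whisker_high <= bs.q3 + 1.5 * iqr
        assert bs.whisker_low >= bs.q1 - 1.5 * iqr

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            box_stats([])


class TestSweepK:
    def test_default_grid_clipped_to_sample_count(self, synth16):
        spectra, ds, _ = synth16
        long_df, summary = sweep_k(spectra, ds, n_repeats=1, base_seed=0)
        assert list(summary["k"]) == list(range(2, 17))

    def test_test_fold_sizes_never_grow_with_k(self, synth16):
        spectra, ds, _ = synth16
        long_df, _ = sweep_k(spectra, ds, n_repeats=1, base_seed=0, k_grid=[2, 4, 8, 16])
        max_sizes = long_df.groupby("k")["n_test"].max()
        assert list(max_sizes) == sorted(max_sizes, reverse=True)
        assert max_sizes[2] == 8 and max_sizes[16] == 1  # 50% ... 6.25% held out


def test_fold_assignment_matches_sklearn_bookkeeping(synth16):
    """Cross-check the fold-size contract against the reference CV splitter."""
    sk = pytest.importorskip("sklearn.model_selection")
    spectra, ds, _ = synth16
    ours = repeated_kfold(spectra, ds, CVConfig(k=5, n_repeats=3, base_seed=0))
    ref = sk.RepeatedKFold(n_splits=5, n_repeats=3, random_state=0)
    ref_sizes = sorted(len(te) for _, te in ref.split(spectra.matrix))
    our_sizes = sorted(ours.fold_metrics["n_test"])
    assert our_sizes == ref_sizes
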