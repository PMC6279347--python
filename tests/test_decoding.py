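import numpy as np
import pytest

import relmvpa as rm
from relmvpa.dataset import PatternDataset
from relmvpa.decoding import (
    DecodingError,
    DecodingScheme,
    balanced_accuracy,
    balanced_folds,
    cross_relevance,
    decode_timecourse,
    fit_ovr_logistic,
    interval_average,
    loro_within,
)
from relmvpa.design import TrialDesign
from tests.conftest import make_dataset


def micro_dataset(seed=0, n_runs=2, per_class=2, n_voxels=3, n_trs=2):
    """Tiny one-condition dataset for fold-bookkeeping checks."""
    rng = np.random.default_rng(seed)
    design, rows = [], []
    tid = 1
    for run in range(1, n_runs + 1):
        for cat in (1, 2, 3):
            for _ in range(per_class):
                design.append(
                    TrialDesign(tid, run, "current", cat, 1, True, n_trs)
                )
                rows.append(rng.standard_normal((n_trs, n_voxels)) + cat)
                tid += 1
    return PatternDataset(np.stack(rows), design)


class TestLoroWithin:
    def test_matches_manual_fold_enumeration(self):
        """Fold-by-fold predictions enumerated by hand reproduce the reported
        mean accuracy on a 2-run micro-dataset."""
        ds = micro_dataset(seed=3)
        y = ds.labels()
        runs = ds.runs_of()
        X = ds.at_tr(1)
        manual = []
        for run in (1, 2):
            tr_mask = runs != run
            model = fit_ovr_logistic(X[tr_mask], y[tr_mask])
            manual.append(np.mean(model.predict(X[~tr_mask]) == y[~tr_mask]))
        assert loro_within(ds, "current", 1) == pytest.approx(np.mean(manual))

    def test_each_trial_tested_exactly_once(self):
        ds = micro_dataset(seed=1, n_runs=3)
        runs = ds.runs_of()
        tested = np.concatenate([np.where(runs == r)[0] for r in (1, 2, 3)])
        assert sorted(tested) == list(range(ds.n_trials))

    def test_noiseless_dataset_decodes_perfectly(self, strong_exp2_dataset):
        assert loro_within(strong_exp2_dataset, "current", 5) == 1.0
        assert loro_within(strong_exp2_dataset, "prospective", 5) == 1.0

    def test_label_shuffled_strong_signal_at_chance(self):
        """Shuffling category labels destroys decodability: ~33.33%."""
        accs = []
        for seed in range(6):
            ds = make_dataset("exp2", seed=seed, n_voxels=30, noise_sd=0.3)
            rng = np.random.default_rng(seed + 100)
            idx = ds.index("current")
            cats = [ds.design[i].category for i in idx]
            shuffled = rng.permutation(cats)
            design = list(ds.design)
            for i, c in zip(idx, shuffled):
                t = design[i]
                design[i] = TrialDesign(
                    t.trial_id, t.run, t.condition, int(c), t.exemplar,
                    t.target_present, t.n_trs,
                )
            ds_shuf = PatternDataset(ds.patterns, design)
            for tr in (5, 9, 13):
                accs.append(loro_within(ds_shuf, "current", tr))
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.06)

    def test_single_run_rejected(self):
        ds = micro_dataset(n_runs=1)
        with pytest.raises(DecodingError, match="fewer than 2 runs"):
            loro_within(ds, "current", 1)


class TestBalancedLoro:
    def test_fold_structure_99_fits_30_trials_10_per_class(self, exp2_design):
        ds = make_dataset("exp2", seed=4, n_voxels=5, noise_sd=1.0)
        folds = list(balanced_folds(ds, "prospective"))
        assert len(folds) == 99
        y = ds.labels()
        for _run, _rep, train, test in folds:
            assert train.size == 30
            counts = np.bincount(y[train], minlength=4)[1:]
            assert (counts == 10).all()
            assert test.size == 4
        # every surplus trial excluded exactly once within its fold
        for run in range(1, 10):
            reps = [set(train) for r, _k, train, _te in folds if r == run]
            all_train = set().union(*reps)
            excl_counts = {i: sum(i not in s for s in reps) for i in all_train}
            assert set(excl_counts.values()) <= {0, 1}
            assert sum(excl_counts.values()) == 22  # 2 surplus trials x 11 reps

    def test_perfect_classifier_scores_one(self, strong_exp2_dataset):
        assert rm.balanced_loro(strong_exp2_dataset, "current", 5) == 1.0

    def test_wrong_fold_counts_error_names_fold(self):
        ds = make_dataset("exp1", seed=1, n_voxels=5, noise_sd=1.0)
        with pytest.raises(DecodingError, match="leaving out run 1"):
            list(balanced_folds(ds, "current"))

    def test_balanced_equals_plain_on_equinumerous_classes(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat([1, 2, 3], 8)
        y_pred = rng.choice([1, 2, 3], size=24)
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            np.mean(y_true == y_pred)
        )


class TestCrossRelevance:
    def test_same_condition_rejected(self, strong_exp2_dataset):
        with pytest.raises(DecodingError, match="within"):
            cross_relevance(strong_exp2_dataset, "current", "current", 5)

    def test_missing_condition_rejected(self):
        ds = make_dataset("exp1", seed=0, n_voxels=5, noise_sd=1.0)
        with pytest.raises(DecodingError, match="irrelevant"):
            cross_relevance(ds, "current", "irrelevant", 5)

    def test_shared_code_transfers_perfectly(self, strong_exp2_dataset):
        res = cross_relevance(strong_exp2_dataset, "current", "prospective", 5)
        assert res.mean == 1.0

    def test_inverted_code_transfers_below_chance(self, strong_exp2_dataset):
        res = cross_relevance(strong_exp2_dataset, "current", "prospective", 10)
        assert res.mean < 1 / 3

    def test_run_split_variant_close_to_default(self, strong_exp2_dataset):
        a = cross_relevance(strong_exp2_dataset, "current", "prospective", 5)
        b = cross_relevance(
            strong_exp2_dataset, "current", "prospective", 5, run_split=True
        )
        assert abs(a.mean - b.mean) < 0.05


class TestTimecourseAndIntervals:
    def test_constant_patterns_give_flat_chance_timecourse(self):
        design = rm.generate_design("exp2", seed=0, n_runs=3)
        ds = PatternDataset(np.ones((len(design), 16, 4)), design)
        tc = decode_timecourse(ds, rm.within_scheme("current"))
        assert tc.accuracy.size == 16
        assert np.allclose(tc.accuracy, tc.accuracy[0])

    def test_timecourse_length_matches_design(self, strong_exp2_dataset):
        tc = decode_timecourse(
            strong_exp2_dataset, rm.within_scheme("current"), trs=None
        )
        assert tc.accuracy.size == 16

    def test_scheme_contract(self):
        with pytest.raises(DecodingError):
            DecodingScheme("current", "prospective", "loro")
        with pytest.raises(DecodingError):
            DecodingScheme("current", "current", "train_all_cross")
        with pytest.raises(DecodingError):
            DecodingScheme("current", "current", "bogus")

    def test_interval_average_basics(self):
        tc = np.arange(1, 17) / 20.0
        out = interval_average(tc, {"Delay": [5, 6, 7], "One": [9]})
        assert out["Delay"] == pytest.approx(np.mean(tc[4:7]))
        assert out["One"] == pytest.approx(tc[8])
        const = interval_average(np.full(16, 0.4), {"A": [1, 2, 3], "B": [10, 11, 12]})
        assert const["A"] == const["B"] == pytest.approx(0.4)

    def test_interval_errors(self):
        with pytest.raises(DecodingError, match="empty"):
            interval_average(np.ones(5), {"x": []})
        with pytest.raises(DecodingError, match="outside"):
            interval_average(np.ones(5), {"x": [9]})

    def test_monotone_in_amplitude(self):
        """Within-relevance accuracy does not decrease with category gain."""
        means = []
        for amp in (0.0, 0.5, 1.0):
            vals = [
                loro_within(
                    make_dataset("exp2", seed=s, n_voxels=40, noise_sd=0.5,
                                 amplitude_scale=amp),
                    "current", 6,
                )
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] + 0.05 <= means[2] + 0.10
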