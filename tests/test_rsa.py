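import numpy as np
import pytest
from scipy.stats import rankdata

import relmvpa as rm
from relmvpa.rsa import (
    RDM,
    RSAError,
    classical_mds,
    compute_rdm,
    exemplar_patterns,
    rank_transform,
    same_vs_diff_contrast,
)
from tests.conftest import make_dataset


def brute_force_spearman(x, y):
    """Average-rank Spearman via the definitional rank-and-Pearson route."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


@pytest.fixture(scope="module")
def exp1_dataset():
    return make_dataset("exp1", seed=21, n_voxels=80, noise_sd=0.5)


class TestExemplarPatterns:
    def test_exp1_run_has_12_present_12_missing(self, exp1_dataset):
        labels, per_run = exemplar_patterns(exp1_dataset, tr=5)
        assert len(labels) == 24
        for run, pats in per_run.items():
            missing = np.isnan(pats[:, 0]).sum()
            assert missing == 12

    def test_single_trial_combination_equals_trial_pattern(self, exp1_dataset):
        ds = exp1_dataset
        labels, per_run = exemplar_patterns(ds, tr=3)
        # find a combination occurring exactly once in run 1
        from collections import Counter

        keys = [
            (t.condition, t.category, t.exemplar)
            for t in ds.design
            if t.run == 1
        ]
        single = [k for k, v in Counter(keys).items() if v == 1]
        key = single[0]
        i = next(
            i for i, t in enumerate(ds.design)
            if t.run == 1 and (t.condition, t.category, t.exemplar) == key
        )
        assert np.allclose(per_run[1][labels.index(key)], ds.patterns[i, 2])

    def test_repeated_combination_is_mean_of_trials(self):
        from relmvpa.dataset import PatternDataset
        from relmvpa.design import TrialDesign

        rng = np.random.default_rng(0)
        design = [
            TrialDesign(1, 1, "current", 1, 1, True, 2),
            TrialDesign(2, 1, "current", 1, 1, False, 2),  # same combination
            TrialDesign(3, 1, "current", 2, 1, True, 2),
        ]
        pats = rng.standard_normal((3, 2, 5))
        ds = PatternDataset(pats, design)
        labels, per_run = exemplar_patterns(ds, tr=1)
        i = labels.index(("current", 1, 1))
        assert np.allclose(per_run[1][i], pats[:2, 0].mean(axis=0))


class TestComputeRdm:
    def test_identical_patterns_give_zero_cell(self):
        # duplicate the pattern of one combination into another and check d=0
        ds = make_dataset("exp1", seed=2, n_voxels=30, noise_sd=0.3)
        rdm = compute_rdm(ds, 5)
        assert np.allclose(np.diag(rdm.d), 0.0)

    def test_sign_flip_gives_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert 1 - brute_force_spearman(x, -x) == pytest.approx(2.0)

    def test_cells_match_brute_force_spearman_with_ties(self):
        ds = make_dataset("exp1", seed=5, n_voxels=5, noise_sd=0.5)
        ds.patterns[:, :, 0] = np.round(ds.patterns[:, :, 0])  # induce ties
        ds.patterns[:, :, 1] = np.round(ds.patterns[:, :, 1])
        tr = 6
        rdm = compute_rdm(ds, tr)
        labels, per_run = exemplar_patterns(ds, tr)
        # independent accumulation for one label pair
        i, j = 0, 7
        vals = []
        for run, pats in per_run.items():
            if np.isnan(pats[i, 0]) or np.isnan(pats[j, 0]):
                continue
            vals.append(1 - brute_force_spearman(pats[i], pats[j]))
        assert rdm.d[i, j] == pytest.approx(np.mean(vals))

    def test_interval_is_mean_of_single_tr_rdms(self):
        ds = make_dataset("exp1", seed=9, n_voxels=20, noise_sd=0.5)
        r5 = compute_rdm(ds, 5)
        r6 = compute_rdm(ds, 6)
        r56 = compute_rdm(ds, [5, 6])
        assert np.allclose(r56.d, (r5.d + r6.d) / 2)

    def test_exp2_per_run_coverage_error_suggests_pooling(self):
        ds = make_dataset("exp2", seed=1, n_voxels=10, noise_sd=0.5)
        with pytest.raises(RSAError, match="zero contributing runs"):
            compute_rdm(ds, 5, conditions=["current", "prospective"])
        rdm = compute_rdm(
            ds, 5, conditions=["current", "prospective"], per_run=False
        )
        assert rdm.side == 24

    def test_rdm_cells_in_range_symmetric(self, exp1_dataset):
        rdm = compute_rdm(exp1_dataset, [4, 5, 6])
        assert rdm.d.min() >= 0 and rdm.d.max() <= 2
        assert np.allclose(rdm.d, rdm.d.T)


class TestRankTransform:
    def test_unique_values_evenly_spaced(self):
        n = 5
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = np.arange(1, iu[0].size + 1) * 0.1
        d = d + d.T
        rdm = RDM([("c", 1, k) for k in range(n)], d, "toy", 1)
        out = rank_transform(rdm)
        got = np.sort(out.d[iu])
        assert np.allclose(got, np.linspace(0, 1, iu[0].size))

    def test_invariant_under_monotone_transform_and_idempotent(self):
        rng = np.random.default_rng(4)
        n = 6
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.random(iu[0].size)
        d = d + d.T
        labels = [("c", 1, k) for k in range(n)]
        r1 = rank_transform(RDM(labels, d, "toy", 1))
        r2 = rank_transform(RDM(labels, np.exp(3 * d) - 1, "toy", 1))
        assert np.allclose(r1.d, r2.d)
        assert np.allclose(rank_transform(r1).d, r1.d)

    def test_ties_get_average_ranks_and_all_equal_maps_to_half(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        labels = [("c", 1, k) for k in range(n)]
        out = rank_transform(RDM(labels, d, "toy", 1))
        iu = np.triu_indices(n, 1)
        assert np.allclose(out.d[iu], 0.5)


class TestClassicalMds:
    def test_zero_dissimilarity_collapses_points(self):
        with pytest.warns(UserWarning):
            coords = classical_mds(np.zeros((4, 4)), k=2)
        assert np.allclose(coords, 0.0)

    def test_recovers_planted_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = classical_mds(D, k=2)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(np.sort(D2.ravel()), np.sort(D.ravel()), atol=1e-8)

    def test_euclidean_input_reproduced_within_truncation(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = classical_mds(D, k=3)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(D2, D, atol=1e-8)


class TestSameVsDiffContrast:
    def test_all_equal_cells_give_zero_difference(self):
        labels = [
            (cond, cat, ex)
            for cond in ("current", "prospective")
            for cat in (1, 2, 3)
            for ex in (1, 2)
        ]
        n = len(labels)
        d = np.ones((n, n)) - np.eye(n)
        rdm = RDM(labels, d, "toy", 1, d_fisher=d.copy())
        con = same_vs_diff_contrast(rdm, ("current", "prospective"), scale="raw")
        assert con.difference == pytest.approx(0.0)

    def test_antisymmetric_under_label_swap(self, exp1_dataset):
        rdm = compute_rdm(exp1_dataset, [8, 9, 10])
        a = same_vs_diff_contrast(rdm, ("current", "prospective"))
        b = same_vs_diff_contrast(rdm, ("prospective", "current"))
        assert a.difference == pytest.approx(b.difference)  # symmetric matrix

    def test_missing_relevance_level_rejected(self, exp1_dataset):
        rdm = compute_rdm(exp1_dataset, 5)
        with pytest.raises(RSAError, match="irrelevant"):
            same_vs_diff_contrast(rdm, ("current", "irrelevant"))

    def test_delay_similarity_and_search_reversal(self, exp1_dataset):
        """Upright shared code at delay: same-category pairs less dissimilar;
        inverted prospective code at search: same-category pairs more
        dissimilar."""
        delay = same_vs_diff_contrast(
            compute_rdm(exp1_dataset, [4, 5, 6]), ("current", "prospective")
        )
        search = same_vs_diff_contrast(
            compute_rdm(exp1_dataset, [8, 9, 10]), ("current", "prospective")
        )
        assert delay.difference < 0
        assert search.difference > 0
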