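import numpy as np
import pytest

import relmvpa as rm
from relmvpa.stats import (
    StatsError,
    paired_t,
    per_tr_uncorrected,
    rm_anova_oneway,
    roi_mean_timecourse,
    within_subject_sem,
)
from tests.conftest import make_dataset


class TestPairedT:
    def test_toy_against_textbook_formula(self):
        # x = (1,2,3) vs 0: mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3)
        res = paired_t([1.0, 2.0, 3.0], 0.0)
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.d == pytest.approx(2.0)

    def test_identical_samples_rejected_zero_variance(self):
        with pytest.raises(StatsError, match="zero-variance"):
            paired_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_antisymmetry_in_t_and_d(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.d == pytest.approx(-b.d)
        assert a.p == pytest.approx(b.p)

    def test_tails(self):
        x = np.array([0.4, 0.45, 0.5, 0.42])
        two = paired_t(x, 1 / 3, tail="two-sided")
        one = paired_t(x, 1 / 3, tail="greater")
        less = paired_t(x, 1 / 3, tail="less")
        assert one.p == pytest.approx(two.p / 2)
        assert less.p == pytest.approx(1 - one.p)
        with pytest.raises(StatsError):
            paired_t(x, 0, tail="sideways")

    def test_agrees_with_scipy(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(15) + 0.3, rng.standard_normal(15)
        res = paired_t(x, y)
        ref = scipy_stats.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestRmAnova:
    @staticmethod
    def hand_ss(data):
        S, C = data.shape
        grand = data.mean()
        ss_cond = sum(S * (data[:, j].mean() - grand) ** 2 for j in range(C))
        ss_subj = sum(C * (data[i].mean() - grand) ** 2 for i in range(S))
        ss_tot = ((data - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        F = (ss_cond / (C - 1)) / (ss_err / ((C - 1) * (S - 1)))
        eta = ss_cond / (ss_cond + ss_err)
        return F, eta

    def test_identical_columns_give_zero_F(self):
        data = np.tile(np.arange(4.0)[:, None], (1, 3))
        res = rm_anova_oneway(data)
        assert res.F == 0.0 and res.p == 1.0

    def test_toy_table_matches_hand_decomposition(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 3)) + np.array([0.0, 0.4, 0.1])
        res = rm_anova_oneway(data, sphericity="never")
        F, eta = self.hand_ss(data)
        assert res.F == pytest.approx(F)
        assert res.eta_p2 == pytest.approx(eta)
        assert (res.df_num, res.df_den) == (2, 6)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        data = rng.standard_normal((12, 3)) + np.array([0.0, 0.3, -0.2])
        res = rm_anova_oneway(data, sphericity="never")
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "cond": np.tile(np.arange(3), 12),
                "subj": np.repeat(np.arange(12), 3),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=False, effsize="np2")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]))
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]))
        assert res.eta_p2 == pytest.approx(float(ref["np2"].iloc[0]))

    def test_gg_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        base = rng.standard_normal((10, 1))
        data = np.hstack(
            [base + 0.1 * rng.standard_normal((10, 1)) for _ in range(2)]
            + [rng.standard_normal((10, 1))]
        )
        from relmvpa.stats import _gg_epsilon

        eps = _gg_epsilon(data)
        ref = float(pg.epsilon(pd.DataFrame(data), correction="gg"))
        assert eps == pytest.approx(ref, abs=1e-10)

    def test_25_subjects_3_conditions_dfs(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((25, 3)) * 0.05 + 1 / 3
        res = rm_anova_oneway(data, sphericity="never")
        assert (res.df_num, res.df_den) == (2, 48)

    def test_two_conditions_F_equals_t_squared(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((9, 2)) + np.array([0.0, 0.5])
        res = rm_anova_oneway(data)
        t = paired_t(data[:, 0], data[:, 1])
        assert res.F == pytest.approx(t.t ** 2)
        assert res.p == pytest.approx(t.p)

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(StatsError, match="complete"):
            rm_anova_oneway(data)


class TestWithinSubjectSem:
    def test_pure_subject_offsets_vanish(self):
        rng = np.random.default_rng(0)
        offsets = rng.standard_normal((8, 1)) * 10
        data = np.tile(offsets, (1, 4))
        sem = within_subject_sem(data)
        assert np.allclose(sem, 0.0, atol=1e-12)

    def test_single_column_equals_classical_sem(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 1))
        with pytest.warns(UserWarning):
            sem = within_subject_sem(data)
        assert sem[0] == pytest.approx(data.std(ddof=1) / np.sqrt(10))

    def test_matches_stepwise_normalization_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 3))
        norm = data - data.mean(axis=1, keepdims=True) + data.mean()
        oracle = norm.std(axis=0, ddof=1) / np.sqrt(3) * np.sqrt(3 / 2)
        assert np.allclose(within_subject_sem(data), oracle)


class TestPerTrAndBold:
    def test_null_mask_density_near_alpha(self):
        rng = np.random.default_rng(3)
        hits = 0
        total = 0
        for _ in range(200):
            tcs = 1 / 3 + 0.05 * rng.standard_normal((12, 10))
            mask, _ = per_tr_uncorrected(tcs, tail="greater")
            hits += mask.sum()
            total += mask.size
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se

    def test_strong_signal_flags_all_trs_and_mask_length(self):
        rng = np.random.default_rng(4)
        tcs = 0.8 + 0.02 * rng.standard_normal((10, 16))
        mask, pvals = per_tr_uncorrected(tcs, tail="greater")
        assert mask.shape == (16,)
        assert mask.all()
        assert ((pvals > 0) & (pvals <= 1)).all()

    def test_roi_timecourse_recovers_injected_profile(self):
        """A linear-in-TR mean response injected into every voxel is recovered
        by the trial/voxel average."""
        from relmvpa.dataset import PatternDataset
        import relmvpa as rm

        design = rm.generate_design("exp2", seed=3, n_runs=3)
        rng = np.random.default_rng(3)
        profile = np.linspace(0, 1, 16)
        pats = profile[None, :, None] + 0.3 * rng.standard_normal(
            (len(design), 16, 25)
        )
        out = roi_mean_timecourse(PatternDataset(pats, design))
        assert out["mean"].shape == (16,)
        assert np.allclose(out["mean"], profile, atol=0.05)

    def test_zero_signal_timecourse_near_zero(self):
        ds = make_dataset("exp2", seed=9, n_voxels=50, noise_sd=1.0,
                          amplitude_scale=0.0)
        out = roi_mean_timecourse(ds)
        assert np.abs(out["mean"]).max() < 0.05
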