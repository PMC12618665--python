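"""Exact and asymptotic tests, effect sizes, and the battery orchestrator."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from xai_reliance.data_model import StudyTable
from xai_reliance.stat_battery import (
    DegenerateDataError,
    independent_t,
    mann_whitney_u,
    paired_t,
    pearson_ls,
    run_full_battery,
    wilcoxon_signed_rank,
)

from conftest import make_estimate
from test_reliance import make_prediction


# -- brute-force oracles ----------------------------------------------------


def brute_wilcoxon_p(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    on midranks (zeros dropped)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    tol = 1e-9
    return min(1.0, 2 * min((ws <= w_obs + tol).mean(), (ws >= w_obs - tol).mean()))


def brute_mwu_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def u_stat(ga, gb):
        return (ga[:, None] > gb[None, :]).sum() + 0.5 * (ga[:, None] == gb[None, :]).sum()

    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    u_obs = u_stat(a, b)
    us = []
    for combo in itertools.combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.array(us)
    tol = 1e-9
    return min(1.0, 2 * min((us <= u_obs + tol).mean(), (us >= u_obs - tol).mean()))


# -- t-tests ----------------------------------------------------------------


class TestTTests:
    def test_identical_groups(self):
        res = independent_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)
        assert res.effect == 0

    def test_cohens_d_from_group_summaries(self):
        # groups constructed to have exactly mean 23.5 SD 4.3 and 15.7 SD 6.6
        def with_moments(mean, sd, n=10):
            base = np.arange(n, dtype=float)
            base = (base - base.mean()) / base.std(ddof=1)
            return base * sd + mean

        res = independent_t(with_moments(23.5, 4.3), with_moments(15.7, 6.6))
        # pooled-SD formula: d = 7.8 / sqrt((18.49 + 43.56)/2) = 1.400
        assert res.effect == pytest.approx(1.4004, abs=1e-3)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(DegenerateDataError):
            independent_t([0, 0], [1, 1])

    def test_paired_t_closed_forms(self):
        res = paired_t([1, -1])
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)
        res = paired_t([1, 2, 3])
        assert res.statistic == pytest.approx(2 * math.sqrt(3))

    def test_paired_t_constant_errors(self):
        with pytest.raises(DegenerateDataError):
            paired_t([2, 2, 2])

    def test_group_swap_flips_sign_keeps_p(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        r1, r2 = independent_t(a, b), independent_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


# -- exact nonparametrics ---------------------------------------------------


class TestWilcoxon:
    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_differences(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1, 2], [1, 2])

    def test_tied_ranks_symmetric(self):
        res = wilcoxon_signed_rank([2, 1], [1, 2])  # diffs +1, -1: midranks
        assert res.p_value == pytest.approx(1.0)

    @given(
        st.lists(st.integers(-3, 3), min_size=1, max_size=8),
    )
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_matches_enumeration_oracle(self, diffs):
        x = np.array(diffs, float)
        y = np.zeros_like(x)
        if np.all(x == 0):
            with pytest.raises(DegenerateDataError):
                wilcoxon_signed_rank(x, y)
            return
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(brute_wilcoxon_p(x, y))

    def test_tie_free_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.permutation(np.arange(1, 9)) * rng.choice([-1, 1], 8)
            ours = wilcoxon_signed_rank(d, np.zeros(8)).p_value
            ref = stats.wilcoxon(d, mode="exact").pvalue
            assert ours == pytest.approx(float(ref))

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1, 60)
        res = wilcoxon_signed_rank(x, np.zeros(60))
        assert 0 <= res.p_value <= 1


class TestMannWhitney:
    def test_disjoint_groups(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        assert mann_whitney_u([1, 2], [1, 2]).p_value == pytest.approx(1.0)

    def test_u_counts_a_above_b(self):
        assert mann_whitney_u([5], [1]).statistic == 1.0

    @given(
        st.lists(st.integers(0, 4), min_size=1, max_size=4),
        st.lists(st.integers(0, 4), min_size=1, max_size=4),
    )
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b):
        assert mann_whitney_u(a, b).p_value == pytest.approx(brute_mwu_p(a, b))

    def test_tie_free_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pooled = rng.permutation(np.arange(10, dtype=float))
            a, b = pooled[:4], pooled[4:]
            ours = mann_whitney_u(a, b).p_value
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref))


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson_ls([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
        assert pearson_ls([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_constant_errors(self):
        with pytest.raises(DegenerateDataError):
            pearson_ls([1, 1, 1], [1, 2, 3])

    def test_mean_r_over_permutations_is_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rs = [
            pearson_ls(x, np.array(p)).statistic
            for p in itertools.permutations([1.0, 2.0, 3.0, 4.0])
        ]
        assert np.mean(rs) == pytest.approx(0.0, abs=1e-12)


# -- orchestrator -----------------------------------------------------------

EXPECTED_LABELS = [
    "MAE stage 1 vs 2 (days)",
    "MAE stage 2 vs 3 (days)",
    "agreement stage 1 vs 2",
    "agreement stage 2 vs 3",
    "mean WoA stage 2 vs 3",
    "confidence stage 1 vs 2 (per estimate)",
    "confidence stage 2 vs 3 (per estimate)",
    "confidence stage 2: helped vs not helped",
    "confidence stage 3: helped vs not helped",
    "trust item 'trust' post-stage-2 vs post-stage-3",
    "trust item 'distrust' post-stage-2 vs post-stage-3",
    "helpfulness rating vs deltaMAE(3-2)",
    "log ratio appropriate vs under, stage 2",
    "log ratio under vs over, stage 2",
    "log ratio appropriate vs under, stage 3",
    "log ratio under vs over, stage 3",
    "comfort incorporating model: pre vs post study",
    "time per estimate stage 2 vs 3 (s)",
]


class TestRunFullBattery:
    def test_all_comparisons_present_on_simulated_study(self, sim_table):
        report = run_full_battery(sim_table)
        labels = [r.label for r in report.rows]
        for expected in EXPECTED_LABELS:
            assert expected in labels
        assert report.n_tests >= 14
        for row in report.rows:
            if row.result is not None:
                assert 0 <= row.result.p_value <= 1

    def test_report_serialises(self, sim_table, tmp_path):
        report = run_full_battery(sim_table)
        paths = report.write(tmp_path)
        assert paths["json"].exists() and paths["md"].exists()
        assert "statistical battery" in paths["md"].read_text()

    def test_stage2_duplicating_stage1_gives_null_mae_comparison(self, scheme):
        rng = np.random.default_rng(3)
        preds, estimates = [], []
        truths = rng.uniform(15, 40, 5)
        for i, y in enumerate(truths):
            img = f"img{i:03d}"
            preds.append(make_prediction(scheme, img, float(np.clip(y, 14.5, 40.0))))
            for pid_i in range(3):
                p1 = float(np.clip(y + rng.normal(0, 2), 10, 45))
                for stage in (1, 2, 3):
                    estimates.append(
                        make_estimate(
                            participant_id=f"p{pid_i:02d}",
                            image_id=img,
                            stage=stage,
                            true_ga_weeks=float(y),
                            estimate_weeks=p1,
                        )
                    )
        table = StudyTable(estimates, preds, [], scheme)
        report = run_full_battery(table)
        row = report.row("MAE stage 1 vs 2 (days)")
        assert row.result.statistic == pytest.approx(0.0)
        assert row.result.p_value == pytest.approx(1.0)

    def test_missing_items_become_not_computed_rows(self, scheme):
        # no likert data: helpfulness-dependent comparisons must degrade
        preds = [make_prediction(scheme, "img000", 25.0)]
        estimates = [
            make_estimate(stage=s, estimate_weeks=24.0, true_ga_weeks=25.0) for s in (1, 2, 3)
        ]
        table = StudyTable(estimates, preds, [], scheme)
        report = run_full_battery(table)  # must not raise
        helped_row = report.row("confidence stage 2: helped vs not helped")
        assert helped_row.result is None and "not computed" in helped_row.note
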