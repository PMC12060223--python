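"""Task-related activity, ERD, rank tests, Spearman, ANCOVA, threshold scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from icohnet.stats import (
    ancova_group_effect,
    erd,
    rank_sum,
    spearman,
    task_related_activity,
    threshold_scan,
)
from tests.conftest import make_epochs, narrowband


class TestTaskRelatedActivity:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(10.0, 15.0, 50.0), (3.7, 3.7, 0.0), (0.08, 0.02, -75.0)],
    )
    def test_worked_values(self, pre, post, expected):
        assert task_related_activity(pre, post) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        pre, post = rng.uniform(0.5, 2.0, size=2)
        for c in (-3.0, 0.17, 1e6):
            assert task_related_activity(c * pre, c * post) == pytest.approx(
                task_related_activity(pre, post)
            )

    def test_zero_pre_rejected(self):
        with pytest.raises(ZeroDivisionError):
            task_related_activity(0.0, 1.0)


class TestErd:
    fs = 256.0

    def _epochs_with_band_amp(self, rng, amp_pre, amp_post, band=(13.0, 30.0)):
        """Band oscillation whose amplitude changes at the cue, on channel 0."""
        n_samp = 1792
        times = -2.0 + np.arange(n_samp) / self.fs
        osc = narrowband(rng, 60, n_samp, self.fs, band).real
        env = np.where(times < 0, amp_pre, amp_post)
        data = 0.05 * rng.standard_normal((60, 2, n_samp))
        data[:, 0, :] += env * osc
        return make_epochs(data, fs=self.fs)

    def test_amplitude_drop_by_sqrt2_gives_minus_fifty_percent(self, rng):
        e = self._epochs_with_band_amp(rng, 1.0, 1.0 / np.sqrt(2))
        val = erd(e, (13.0, 30.0))["CH1"]
        assert val == pytest.approx(-50.0, abs=5.0)

    def test_stationary_signal_gives_no_erd(self, rng):
        # Welch noise per cohort is a few percent; the Monte-Carlo mean is ~0
        vals = [
            erd(self._epochs_with_band_amp(rng, 1.0, 1.0), (13.0, 30.0))["CH1"]
            for _ in range(10)
        ]
        assert abs(np.mean(vals)) < 3.0

    def test_out_of_band_power_change_ignored(self, rng):
        vals = []
        for _ in range(10):
            e = self._epochs_with_band_amp(rng, 1.0, 1.0)
            # strong post-only gamma-range noise, clear of the beta band edge;
            # beta ERD must stay ~0
            gamma = narrowband(rng, 60, 1792, self.fs, (40.0, 60.0)).real
            times = -2.0 + np.arange(1792) / self.fs
            e.data[:, 0, :] += 3.0 * np.where(times >= 0.25, 1.0, 0.0) * gamma
            vals.append(erd(e, (13.0, 30.0))["CH1"])
        assert abs(np.mean(vals)) < 3.0


class TestRankSum:
    def test_exact_worked_example(self):
        stat, p = rank_sum([1, 2, 3], [4, 5, 6])
        assert stat == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            _, p = rank_sum([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_label_swap_symmetry(self, rng):
        x, y = rng.standard_normal(7), rng.standard_normal(5)
        assert rank_sum(x, y)[1] == pytest.approx(rank_sum(y, x)[1])

    def test_exact_vs_normal_approximation_close(self, rng):
        # at n1 = n2 = 10 the exact and large-sample p agree within 0.02
        from scipy.stats import mannwhitneyu

        diffs = []
        for _ in range(20):
            x, y = rng.standard_normal(10), rng.standard_normal(10) + 0.3
            _, p_exact = rank_sum(x, y)
            p_norm = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_norm))
        assert max(diffs) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_worked_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_exact_p_matches_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        rho, p = spearman(x, y)
        # independent enumeration over all 5! rank permutations
        n = 5
        count = 0
        total = 0
        base = np.arange(1, n + 1)
        for perm in itertools.permutations(base):
            d2 = ((np.array(perm) - base) ** 2).sum()
            r = 1 - 6 * d2 / (n * (n * n - 1))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAncova:
    def test_group_difference_explained_by_covariate(self, rng):
        # post tracks pre (plus noise); groups differ only in their pre level,
        # so the covariate absorbs what a marginal group test calls an effect
        pre = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        post = pre + rng.normal(0, 0.1, 40)
        groups = ["a"] * 20 + ["b"] * 20
        _, p = ancova_group_effect(post, groups, pre)
        assert p > 0.05
        from scipy.stats import f_oneway

        assert f_oneway(post[:20], post[20:]).pvalue < 1e-6

    def test_matches_direct_linear_algebra(self, rng):
        # independent computation of the partial F from projection matrices
        n = 30
        pre = rng.standard_normal(n)
        g = np.array([0] * 15 + [1] * 15)
        post = 0.8 * pre + 0.9 * g + rng.standard_normal(n)
        F, p = ancova_group_effect(post, ["a" if v == 0 else "b" for v in g], pre)

        X_full = np.column_stack([np.ones(n), g, pre])
        X_red = np.column_stack([np.ones(n), pre])

        def sse(X):
            beta, *_ = np.linalg.lstsq(X, post, rcond=None)
            r = post - X @ beta
            return r @ r

        df_resid = n - X_full.shape[1]
        F_direct = (sse(X_red) - sse(X_full)) / (sse(X_full) / df_resid)
        assert F == pytest.approx(F_direct, abs=1e-9)

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError):
            ancova_group_effect([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], [1.0, 1.0, 1.0, 1.0])


class TestThresholdScan:
    @staticmethod
    def _icoh_like(rng, n, scale):
        m = scale * rng.standard_normal((n, n))
        return m - m.T

    def test_planted_topology_difference_detected(self, rng):
        # group 'dense': strong post-window edges form a hub (star), which at
        # a matched edge count is more integrated than scattered random edges
        icoh, groups = {}, {}
        for k in range(6):
            sid = f"d{k}"
            pre = self._icoh_like(rng, 12, 0.05)
            post = self._icoh_like(rng, 12, 0.05)
            post[0, 1:] = 0.9 + 0.01 * rng.standard_normal(11)
            post[1:, 0] = -post[0, 1:]
            icoh[sid] = {"pre": pre, "post": post}
            groups[sid] = "dense"
        for k in range(6):
            sid = f"n{k}"
            icoh[sid] = {"pre": self._icoh_like(rng, 12, 0.05), "post": self._icoh_like(rng, 12, 0.05)}
            groups[sid] = "null"
        res = threshold_scan(icoh, groups, fractions=np.arange(5, 50, 5) / 100.0)
        assert res.selected_fraction is not None
        acts = res.samples[res.selected_fraction]
        assert np.median(acts["dense"]) != np.median(acts["null"])

    def test_single_group_rejected(self, rng):
        icoh = {"s1": {"pre": np.zeros((4, 4)), "post": np.zeros((4, 4))}}
        with pytest.raises(ValueError):
            threshold_scan(icoh, {"s1": "only"})

    def test_table_covers_all_fractions(self, rng):
        icoh, groups = {}, {}
        for k in range(4):
            icoh[f"s{k}"] = {
                "pre": self._icoh_like(rng, 8, 1.0),
                "post": self._icoh_like(rng, 8, 1.0),
            }
            groups[f"s{k}"] = "a" if k < 2 else "b"
        fr = np.arange(10, 91, 10) / 100.0
        res = threshold_scan(icoh, groups, fractions=fr)
        assert len(res.table) == len(fr)
        assert res.table["p"].between(0, 1).all()
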