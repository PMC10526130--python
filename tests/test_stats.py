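"""Relative change, Mann-Whitney arm comparisons (with an enumeration
oracle), voxel densities and the report builder."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dcevasc.stats import (compare_arms, pipeline_report, relative_change,
                           voxel_density)


def make_table(rows):
    return pd.DataFrame(rows, columns=["subject", "arm", "timepoint",
                                       "metric", "value"])


class TestRelativeChange:
    def test_arithmetic(self):
        table = make_table([
            ("s1", "chemo", "baseline", "volume_cm3", 10.45),
            ("s1", "chemo", "12w", "volume_cm3", 2.75),
        ])
        ch = relative_change(table)
        assert len(ch) == 1
        assert ch["pct_change"].iloc[0] == pytest.approx(
            100 * (2.75 - 10.45) / 10.45)
        assert ch["pct_change"].iloc[0] == pytest.approx(-73.7, abs=0.05)

    def test_unchanged_value_zero_percent(self):
        table = make_table([("s1", "chemo", "baseline", "m", 5.0),
                            ("s1", "chemo", "1w", "m", 5.0)])
        assert relative_change(table)["pct_change"].iloc[0] == 0.0

    def test_pairwise_deletion(self):
        """A subject missing one follow-up stays in the other timepoints."""
        table = make_table([
            ("s1", "chemo", "baseline", "m", 1.0),
            ("s1", "chemo", "12w", "m", 2.0),
            ("s2", "chemo", "baseline", "m", 1.0),
            ("s2", "chemo", "1w", "m", 1.5),
            ("s2", "chemo", "12w", "m", 0.5),
            ("s3", "chemo", "1w", "m", 9.0),  # no baseline: dropped entirely
        ])
        ch = relative_change(table)
        assert set(ch[ch.timepoint == "1w"].subject) == {"s2"}
        assert set(ch[ch.timepoint == "12w"].subject) == {"s1", "s2"}
        assert "s3" not in set(ch.subject)

    def test_zero_baseline_flagged(self):
        table = make_table([("s1", "chemo", "baseline", "m", 0.0),
                            ("s1", "chemo", "1w", "m", 3.0)])
        ch = relative_change(table)
        assert not ch["defined"].iloc[0]
        assert np.isnan(ch["pct_change"].iloc[0])


def exact_mw_p_two_sided(x, y):
    """Enumeration oracle: two-sided p as the tail probability of U under
    all C(n+m, n) group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = len(x) * len(y) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = u_stat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu):
            count += 1
        total += 1
    return count / total


class TestCompareArms:
    def _changes(self, x, y):
        rows = []
        for i, v in enumerate(x):
            rows.append({"subject": f"a{i}", "arm": "chemo",
                         "timepoint": "1w", "metric": "m",
                         "pct_change": v, "defined": True})
        for i, v in enumerate(y):
            rows.append({"subject": f"b{i}", "arm": "chemo+bev",
                         "timepoint": "1w", "metric": "m",
                         "pct_change": v, "defined": True})
        return pd.DataFrame(rows)

    def test_separated_triplets_exact_p(self):
        """{1,2,3} vs {4,5,6}: U=0 and exact two-sided p = 2/20 = 0.1."""
        res = compare_arms(self._changes([1, 2, 3], [4, 5, 6]), "m", "1w")
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            exact_mw_p_two_sided([1, 2, 3], [4, 5, 6]))

    def test_matches_enumeration_oracle_on_random_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(0, 1, 4)
            y = rng.normal(0.5, 1, 5)
            res = compare_arms(self._changes(x, y), "m", "1w")
            assert res.p_value == pytest.approx(exact_mw_p_two_sided(x, y))

    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        res = compare_arms(self._changes(x, x), "m", "1w")
        assert res.p_value >= 0.9

    def test_exact_and_asymptotic_agree_moderate_n(self):
        """n = 10 vs 10 without ties: the two code paths agree to 0.02."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.8, 1, 10)
        from scipy.stats import mannwhitneyu
        p_exact = mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").pvalue
        p_norm = mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.02
        res = compare_arms(self._changes(x, y), "m", "1w")
        assert res.p_value == pytest.approx(p_exact)

    def test_ties_switch_to_corrected_asymptotic(self):
        res = compare_arms(self._changes([1, 1, 2], [1, 2, 3]), "m", "1w")
        assert res.method == "asymptotic"

    def test_empty_arm_rejected(self):
        ch = self._changes([1, 2, 3], [4])
        ch = ch[ch.arm == "chemo"]
        with pytest.raises(ValueError):
            compare_arms(ch, "m", "1w")


class TestVoxelDensity:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        d = voxel_density(rng.normal(50, 10, 2000))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_sample_has_two_peaks(self):
        """A mixed short/long TTP population shows two density maxima."""
        rng = np.random.default_rng(1)
        sample = np.concatenate([rng.normal(40, 5, 800),
                                 rng.normal(170, 12, 800)])
        d = voxel_density(sample)
        interior = d.density[1:-1]
        peaks = np.flatnonzero((interior > d.density[:-2])
                               & (interior > d.density[2:]))
        prominent = [p for p in peaks
                     if interior[p] > 0.2 * d.density.max()]
        assert len(prominent) == 2

    def test_duplication_invariance(self):
        """The density is normalized to the sample, so duplicating every
        value changes nothing (exactly so at fixed bandwidth; Silverman's
        rule only shifts the bandwidth with n)."""
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, 500)
        d1 = voxel_density(v, bw_method=0.3)
        d2 = voxel_density(np.concatenate([v, v]), grid=d1.grid,
                           bw_method=0.3)
        assert np.max(np.abs(d1.density - d2.density)) < 0.01 * d1.density.max()
        # with Silverman's rule the change is a small bandwidth effect
        s1 = voxel_density(v)
        s2 = voxel_density(np.concatenate([v, v]), grid=s1.grid)
        assert np.max(np.abs(s1.density - s2.density)) < 0.05 * s1.density.max()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            voxel_density(np.arange(5))


class TestPipelineReport:
    def _cohort(self, n=6, effect=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for arm, mult in (("chemo", 1.0), ("chemo+bev", effect)):
            for i in range(n):
                s = f"{arm}-{i}"
                base = 0.13 * rng.lognormal(0, 0.2)
                rows.append((s, arm, "baseline", "ktrans", base))
                rows.append((s, arm, "1w", "ktrans",
                             base * mult * rng.lognormal(0, 0.2)))
        return make_table(rows)

    def test_row_counts_no_missing_data(self):
        report = pipeline_report(self._cohort())
        assert len(report["summary"]) == 2 * 2  # arms x timepoints
        assert len(report["tests"]) == 1

    def test_effect_shows_in_delta_rows(self):
        report = pipeline_report(self._cohort(effect=0.4, seed=3))
        s = report["summary"]
        bev = s[(s.arm == "chemo+bev") & (s.timepoint == "1w")]
        chemo = s[(s.arm == "chemo") & (s.timepoint == "1w")]
        assert bev.delta_median_pct.iloc[0] < chemo.delta_median_pct.iloc[0]

    def test_empty_arm_fails_loudly(self):
        t = self._cohort()
        with pytest.raises(ValueError, match="two arms"):
            pipeline_report(t[t.arm == "chemo"])

    def test_bootstrap_ci_deterministic_in_seed(self):
        a = pipeline_report(self._cohort(), seed=5)["summary"]
        b = pipeline_report(self._cohort(), seed=5)["summary"]
        pd.testing.assert_frame_equal(a, b)


def test_median_invariant_to_subject_order():
    t = TestPipelineReport()._cohort(seed=9)
    shuffled = t.sample(frac=1.0, random_state=4).reset_index(drop=True)
    a = pipeline_report(t)["summary"].sort_values(
        ["metric", "arm", "timepoint"]).reset_index(drop=True)
    b = pipeline_report(shuffled)["summary"].sort_values(
        ["metric", "arm", "timepoint"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)
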