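"""Group summaries, Shapiro-Wilk, Kruskal-Wallis and the full battery.

The Kruskal-Wallis implementation is checked against a from-scratch
mid-rank oracle, worked small instances, a type-I-error simulation and a
rank-invariance property.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fessmotion.stats import (BatteryConfig, DegenerateDataError, dunn_posthoc,
                              kruskal_wallis, run_battery, shapiro_wilk,
                              summarize_groups)
from fessmotion.stats import tests_frame as results_frame


def kw_oracle(groups):
    """Brute-force tie-corrected H via explicit mid-ranks (independent of the
    implementation under test)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and pooled[order[j]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # mid-rank, 1-based
        i = j
    start, stat = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        stat += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    stat *= 12 / (n * (n + 1))
    ties = sum(c**3 - c for c in np.unique(pooled, return_counts=True)[1])
    return stat / (1 - ties / (n**3 - n))


class TestSummaries:
    def test_basic_mean_sd(self):
        df = pd.DataFrame({"group": ["senior"] * 3, "procedure": ["septoplasty"] * 3,
                           "hand": ["DH"] * 3, "m": [1.0, 2.0, 3.0]})
        (s,) = summarize_groups(df, "m")
        assert (s.n, s.mean, s.sd) == (3, 2.0, 1.0)

    def test_singleton_sd_flagged(self):
        df = pd.DataFrame({"group": ["senior"], "procedure": ["septoplasty"],
                           "hand": ["DH"], "m": [5.0]})
        (s,) = summarize_groups(df, "m")
        assert s.mean == 5.0 and s.sd is None


class TestShapiroWilk:
    def test_too_small(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([2.0] * 10)

    def test_level_on_normal_samples(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).normal(size=50))["p"] > 0.05
            for s in range(100))
        assert hits >= 90

    def test_power_on_exponential_samples(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).exponential(size=200))["p"] < 0.05
            for s in range(100))
        assert hits >= 95


class TestKruskalWallis:
    def test_worked_instance(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res["H"] == pytest.approx(7.2)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(np.exp(-3.6))

    def test_fully_separated_study_sizes(self):
        groups = [list(range(1, 11)), list(range(11, 21)), list(range(21, 25))]
        res = kruskal_wallis(groups)
        assert res["H"] == pytest.approx(19.6)

    def test_matches_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            sizes = rng.integers(1, 5, size=rng.integers(2, 5))
            if sizes.sum() < 3:
                continue
            groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = kruskal_wallis(groups)
            assert res["H"] == pytest.approx(kw_oracle(groups), rel=1e-10)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            pooled = rng.normal(size=24)
            rejections += kruskal_wallis([pooled[:10], pooled[10:20], pooled[20:]])["p"] < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=8), rng.normal(2, 1, size=4)]
        base = kruskal_wallis(groups)["H"]
        for f in (np.exp, lambda x: x**3, lambda x: np.arctan(x) * 10):
            assert kruskal_wallis([f(g) for g in groups])["H"] == pytest.approx(base)

    def test_permutation_p_close_to_chi2(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=10), rng.normal(0.8, 1, size=10), rng.normal(size=4)]
        p_chi2 = kruskal_wallis(groups)["p"]
        p_perm = kruskal_wallis(groups, p_method="permutation",
                                n_permutations=4000, seed=0)["p"]
        assert abs(p_perm - p_chi2) < 0.05

    def test_label_permutation_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        pooled = rng.normal(size=24)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(pooled)
            pvals.append(kruskal_wallis([perm[:10], perm[10:20], perm[20:]])["p"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_data(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0]])

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


def test_dunn_pairwise_sanity():
    rng = np.random.default_rng(8)
    groups = {"a": rng.normal(size=10), "b": rng.normal(3, 1, size=10),
              "c": rng.normal(size=4)}
    res = dunn_posthoc(groups)
    assert set(res) == {"a|b", "a|c", "b|c"}
    assert res["a|b"]["p"] < 0.01          # well-separated pair
    assert all(0 <= v["p"] <= 1 for v in res.values())


class TestBattery:
    def make_table(self, rng, identical=False):
        rows = []
        means = {"resident": 30, "specialist": 20, "senior": 10}
        for g, n in (("resident", 10), ("specialist", 10), ("senior", 4)):
            for i in range(n):
                for proc, hand in itertools.product(
                        ("septoplasty", "turbinoplasty"), ("DH", "NDH")):
                    mu = 20.0 if identical else means[g]
                    rows.append({"participant_id": f"{g}{i}", "group": g,
                                 "procedure": proc, "hand": hand,
                                 "duration_s": rng.normal(mu, 2),
                                 "path_length_m": rng.normal(mu, 2)})
        return pd.DataFrame(rows)

    def test_row_counts(self):
        table = self.make_table(np.random.default_rng(0))
        cfg = BatteryConfig(metrics=("duration_s", "path_length_m"),
                            procedures=("septoplasty", "turbinoplasty"))
        tests, summaries = run_battery(table, cfg)
        assert len(tests) == 2 * 2 * 2                    # metric x proc x hand
        assert len(summaries) == 2 * 2 * 2 * 3            # ... x group
        assert not results_frame(tests)["kw_p"].isna().any()

    def test_separated_groups_significant(self):
        table = self.make_table(np.random.default_rng(1))
        cfg = BatteryConfig(metrics=("duration_s",),
                            procedures=("septoplasty", "turbinoplasty"))
        tests, _ = run_battery(table, cfg)
        assert all(t.kw_p < 0.001 for t in tests)

    def test_identical_groups_mostly_nonsignificant(self):
        rng = np.random.default_rng(2)
        hits = total = 0
        for _ in range(25):
            table = self.make_table(rng, identical=True)
            cfg = BatteryConfig(metrics=("duration_s", "path_length_m"),
                                procedures=("septoplasty", "turbinoplasty"))
            tests, _ = run_battery(table, cfg)
            hits += sum(t.kw_p < 0.05 for t in tests)
            total += len(tests)
        assert hits / total < 0.12          # near the nominal 5% level

    def test_degenerate_cell_flagged_not_fatal(self):
        table = self.make_table(np.random.default_rng(3))
        table["duration_s"] = 1.0           # constant metric everywhere
        cfg = BatteryConfig(metrics=("duration_s",),
                            procedures=("septoplasty", "turbinoplasty"))
        tests, _ = run_battery(table, cfg)
        assert all(t.degenerate for t in tests)
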