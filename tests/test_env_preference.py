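"""rclr transform, rank tests vs brute-force oracles, BH, clustering."""

import itertools
import math

import numpy as np
import pytest

from hypogeo.data_model import GenusTable, Host, SampleRecord, SampleTable
from hypogeo.env_preference import (
    Direction,
    TestFlag as Flag,
    cluster_genera,
    fdr_adjust,
    host_preference_test,
    preference_report,
    rclr_transform,
    significance_stars,
    spearman_env,
)

import pandas as pd


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of average ranks (the tie-safe definition)."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def ranksum_exact_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    ranks = average_ranks(pooled)
    n1 = len(x)
    observed = sum(ranks[:n1])
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        stat = sum(ranks[i] for i in combo)
        total += 1
        if abs(stat - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


def bh_oracle(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# rclr
# ---------------------------------------------------------------------------

def make_genus_table(matrix):
    matrix = np.asarray(matrix)
    return GenusTable([f"g{i}" for i in range(matrix.shape[0])],
                      [f"S{j}" for j in range(matrix.shape[1])], matrix)


class TestRclr:
    def test_uniform_column_centres_to_zero(self):
        r = rclr_transform(make_genus_table([[1], [1], [1], [0]]))
        assert np.allclose(r.values[:3, 0], 0.0)
        assert np.isnan(r.values[3, 0])

    def test_scale_invariance(self):
        a = rclr_transform(make_genus_table([[7], [7], [0]]))
        b = rclr_transform(make_genus_table([[14], [14], [0]]))
        assert np.allclose(a.values[:2, 0], b.values[:2, 0])
        assert np.allclose(a.values[:2, 0], 0.0)

    def test_random_columns_centre_to_zero(self, rng):
        counts = rng.integers(0, 30, size=(15, 40))
        counts[0] += 1  # no all-zero sample
        r = rclr_transform(make_genus_table(counts))
        means = np.nanmean(r.values, axis=0)
        assert np.allclose(means, 0.0, atol=1e-9)
        assert np.array_equal(np.isnan(r.values), counts == 0)

    def test_all_zero_sample_dropped_with_record(self):
        r = rclr_transform(make_genus_table([[1, 0], [2, 0]]))
        assert r.sample_ids == ["S0"]
        assert r.dropped_samples == ["S1"]


# ---------------------------------------------------------------------------
# host preference
# ---------------------------------------------------------------------------

class TestHostPreference:
    def test_single_host_flagged_not_tested(self):
        vals = np.array([1.0, np.nan, 0.5, np.nan])
        hosts = ["QUERCUS", "PINUS", "QUERCUS", "PINUS"]
        res = host_preference_test(vals, hosts, "Glomus")
        assert res.flag is Flag.SINGLE_HOST_ONLY
        assert res.direction is Direction.QUERCUS
        assert res.p_raw is None

    def test_identical_groups_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        hosts = ["PINUS"] * 3 + ["QUERCUS"] * 3
        res = host_preference_test(vals, hosts)
        assert res.p_raw == pytest.approx(1.0)
        assert res.direction is Direction.NONE

    def test_matches_exact_enumeration_small_n(self, rng):
        for _ in range(25):
            nx, ny = rng.integers(2, 5), rng.integers(2, 5)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            vals = np.concatenate([x, y])
            hosts = ["PINUS"] * nx + ["QUERCUS"] * ny
            res = host_preference_test(vals, hosts)
            assert res.p_raw == pytest.approx(ranksum_exact_p(x, y), abs=1e-10)

    def test_shift_detected_with_direction(self, rng):
        hits = 0
        for rep in range(200):
            r = np.random.default_rng(1000 + rep)
            pinus = r.normal(2.0, 1.0, 50)
            quercus = r.normal(0.0, 1.0, 50)
            vals = np.concatenate([pinus, quercus])
            hosts = ["PINUS"] * 50 + ["QUERCUS"] * 50
            res = host_preference_test(vals, hosts)
            if res.p_raw < 0.001 and res.direction is Direction.PINUS:
                hits += 1
        assert hits >= 190  # ≥95% of replicates

    def test_other_hosts_excluded(self):
        vals = np.array([5.0, 1.0, 2.0, 1.5, 2.5])
        hosts = ["OTHER", "PINUS", "PINUS", "QUERCUS", "QUERCUS"]
        res = host_preference_test(vals, hosts)
        assert res.n_pairs == 4


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10, dtype=float)
        res = spearman_env(np.exp(x), x)
        assert res.statistic == pytest.approx(1.0)
        assert res.direction is Direction.POSITIVE

    def test_null_rho_small(self):
        small = 0
        for rep in range(200):
            r = np.random.default_rng(2000 + rep)
            x = r.normal(size=100)
            y = r.permutation(x)
            res = spearman_env(y, x)
            if abs(res.statistic) < 0.3:
                small += 1
        assert small >= 190

    def test_ties_match_average_rank_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            res = spearman_env(y, x)
            assert res.statistic == pytest.approx(spearman_oracle(y, x), abs=1e-12)

    def test_pairwise_deletion_and_min_pairs(self):
        vals = np.array([np.nan, 1.0, 2.0])
        cov = np.array([0.5, 0.6, np.nan])
        res = spearman_env(vals, cov)
        assert res.flag is Flag.TOO_FEW_PAIRS
        assert res.n_pairs == 1


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

class TestFdr:
    def test_hand_computed_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_step_up_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 25)))
            assert np.allclose(fdr_adjust(p), bh_oracle(list(p)), atol=1e-12)

    def test_properties(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)  # order-preserving

    def test_families_adjust_independently(self):
        p = [0.01, 0.02, 0.01, 0.02]
        fam = ["a", "a", "b", "b"]
        adj = fdr_adjust(p, fam)
        assert np.allclose(adj, [0.02, 0.02, 0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        f = pd.DataFrame([[0.5, -0.2], [0.5, -0.2], [3.0, 3.0]],
                         index=["a", "b", "c"])
        cl = cluster_genera(f)
        assert cl.linkage[0, 2] == pytest.approx(0.0)

    def test_complete_linkage_takes_max_distance(self):
        # collinear 1-D features at 0, 1, 3: squared distances {1, 4, 9}
        f = pd.DataFrame([[0.0], [1.0], [3.0]], index=["a", "b", "c"])
        cl = cluster_genera(f)
        assert cl.linkage[0, 2] == pytest.approx(1.0)
        assert cl.linkage[1, 2] == pytest.approx(9.0)

    def test_heights_non_decreasing(self, rng):
        f = pd.DataFrame(rng.normal(size=(12, 5)),
                         index=[f"g{i}" for i in range(12)])
        cl = cluster_genera(f)
        heights = cl.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_requires_two_genera(self):
        with pytest.raises(ValueError):
            cluster_genera(pd.DataFrame([[1.0]], index=["a"]))

    def test_newick_contains_all_leaves(self):
        f = pd.DataFrame([[0.0], [1.0], [3.0]], index=["a", "b", "c"])
        nwk = cluster_genera(f).to_newick()
        assert nwk.endswith(";")
        for leaf in "abc":
            assert leaf in nwk


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def make_survey(rng, n_samples=120, n_genera=6, mat_effect_genus=None):
    recs = []
    for i in range(n_samples):
        recs.append(SampleRecord(
            f"S{i}", f"site{i // 2}", f"grid{i // 4}",
            Host.PINUS if i % 2 == 0 else Host.QUERCUS,
            34.0 + 4.0 * rng.random(), 126.0 + 3.0 * rng.random(),
            {"MAT": float(rng.normal(11, 2)), "MAP": float(rng.normal(1300, 150)),
             "altitude": float(rng.uniform(50, 900)), "pH": float(rng.normal(5.5, 0.4)),
             "TOC": float(rng.normal(30, 8)), "TN": float(rng.normal(2.5, 0.6)),
             "NH4+": float(rng.normal(10, 3)), "NO3-": float(rng.normal(8, 2)),
             "TP": float(rng.normal(500, 120))},
        ))
    samples = SampleTable(recs)
    mats = np.array([r.covariates["MAT"] for r in recs])
    z = (mats - mats.mean()) / mats.std()
    counts = np.zeros((n_genera, n_samples), dtype=int)
    for g in range(n_genera):
        # the planted genus declines in abundance as MAT rises
        lam = np.exp(1.0 - 1.5 * z) if g == mat_effect_genus else np.full(n_samples, 2.0)
        det = rng.random(n_samples) < 0.65
        counts[g, det] = 1 + rng.poisson(lam[det])
    genus_table = GenusTable([f"Genus{g}" for g in range(n_genera)],
                             samples.sample_ids, counts)
    return samples, genus_table


class TestPreferenceReport:
    def test_recovers_planted_negative_mat_effect(self, rng):
        samples, gt = make_survey(rng, mat_effect_genus=2)
        frame, clustering, info = preference_report(gt, samples)
        cell = frame[(frame.genus == "Genus2") & (frame.variable == "MAT")].iloc[0]
        assert cell.p_adjusted < 0.05
        assert cell.direction == "NEGATIVE"
        assert clustering is not None

    def test_single_grid_genus_flagged_and_absent_from_clustering(self, rng):
        samples, gt = make_survey(rng, n_genera=4)
        counts = gt.counts.copy()
        counts[0] = 0
        counts[0, 0] = 3  # Genus0 present in one grid only
        gt = GenusTable(gt.genera, gt.sample_ids, counts)
        frame, clustering, info = preference_report(gt, samples)
        row = frame[frame.genus == "Genus0"].iloc[0]
        assert row.flag == "EXCLUDED_SINGLE_GRID"
        assert "Genus0" in info["excluded_single_grid"]
        assert "Genus0" not in clustering.genera

    def test_report_is_deterministic(self, rng):
        samples, gt = make_survey(rng)
        f1, c1, _ = preference_report(gt, samples)
        f2, c2, _ = preference_report(gt, samples)
        pd.testing.assert_frame_equal(f1, f2)
        assert np.array_equal(c1.linkage, c2.linkage)
        assert c1.to_newick() == c2.to_newick()

    def test_global_family_adjusts_across_variables(self, rng):
        samples, gt = make_survey(rng)
        per_var, _, _ = preference_report(gt, samples, fdr_family="per_variable")
        global_, _, _ = preference_report(gt, samples, fdr_family="global")
        tested = per_var.flag == "TESTED"
        assert np.allclose(per_var.loc[tested, "p_raw"],
                           global_.loc[tested, "p_raw"], equal_nan=True)
        # global family pools more tests, so adjusted values can only differ
        assert (global_.loc[tested, "p_adjusted"]
                >= per_var.loc[tested, "p_raw"] - 1e-12).all()
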