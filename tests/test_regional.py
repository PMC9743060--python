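"""Regional counting, nonparametric tests vs brute-force oracles,
ranked tables, and dose-profile classification."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

import phmribold as pb
from phmribold.regional import effect_size_uncorrected


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def kw_h_oracle(groups):
    """Kruskal-Wallis H from the textbook mid-rank formula with the
    tie-correction divisor, written independently of scipy."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank (1-based)
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def kw_permutation_p(groups, n_max=8):
    """Exact permutation p-value for the Kruskal-Wallis H by enumerating
    every assignment of the pooled values to the group sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    assert len(pooled) <= n_max
    h_obs = kw_h_oracle(groups)
    count = total = 0
    for perm in permutations(range(len(pooled))):
        vals = pooled[list(perm)]
        gs, start = [], 0
        for s in sizes:
            gs.append(vals[start : start + s])
            start += s
        if kw_h_oracle(gs) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def ranksum_exact_p(a, b):
    """Two-sided exact rank-sum p by full enumeration of arrangements."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n].sum()
    ws = []
    from itertools import combinations

    for idx in combinations(range(n + m), n):
        ws.append(ranks[list(idx)].sum())
    ws = np.asarray(ws)
    mu = ws.mean()
    p = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestCountActivated:
    def test_empty_map_all_zero(self, atlas_tiny):
        shape = atlas_tiny.labels.shape
        amap = pb.ActivationMap(
            positive=np.zeros(shape), negative=np.zeros(shape),
            voxel_size=atlas_tiny.voxel_size,
        )
        counts = pb.count_activated(amap, atlas_tiny)
        assert all(v == 0 for v in counts["positive"].values())

    def test_full_region_counts_region_size(self, atlas_tiny):
        shape = atlas_tiny.labels.shape
        pos = np.where(atlas_tiny.labels == 2, 5.0, 0.0)
        amap = pb.ActivationMap(
            positive=pos, negative=np.zeros(shape), voxel_size=atlas_tiny.voxel_size
        )
        counts = pb.count_activated(amap, atlas_tiny)
        assert counts["positive"][2] == atlas_tiny.region_sizes()[2]
        assert counts["positive"][1] == 0

    def test_seeded_subset_count(self, atlas_tiny):
        rng = np.random.default_rng(0)
        vox = np.argwhere(atlas_tiny.labels == 1)
        chosen = vox[rng.choice(len(vox), len(vox) // 10, replace=False)]
        pos = np.zeros(atlas_tiny.labels.shape)
        pos[tuple(chosen.T)] = 3.0
        amap = pb.ActivationMap(
            positive=pos, negative=np.zeros_like(pos),
            voxel_size=atlas_tiny.voxel_size,
        )
        counts = pb.count_activated(amap, atlas_tiny)
        assert counts["positive"][1] == len(chosen)

    def test_grid_mismatch_error(self, atlas_tiny):
        amap = pb.ActivationMap(
            positive=np.zeros((3, 3, 3)), negative=np.zeros((3, 3, 3)),
            voxel_size=(1, 1, 1),
        )
        with pytest.raises(ValueError, match="does not match"):
            pb.count_activated(amap, atlas_tiny)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = pb.kruskal_wallis([[3, 3], [3, 3], [3, 3, 3]])
        assert h == 0.0 and p == 1.0

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sizes = rng.integers(2, 6, size=rng.integers(2, 5))
            groups = [rng.integers(0, 10, s).astype(float) for s in sizes]
            if np.all(np.concatenate(groups) == groups[0][0]):
                continue
            h, _ = pb.kruskal_wallis(groups)
            assert h == pytest.approx(kw_h_oracle(groups), abs=1e-10)

    def test_no_tie_textbook_case(self):
        h, _ = pb.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(kw_h_oracle([np.array([1., 2]), np.array([3., 4]), np.array([5., 6])]), abs=1e-12)

    def test_chi2_p_near_exact_permutation_p(self):
        """For small n the chi-square approximation should track the exact
        permutation null within its known accuracy."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            groups = [rng.normal(0, 1, 3), rng.normal(1.0, 1, 3), rng.normal(0, 1, 2)]
            _, p_chi2 = pb.kruskal_wallis(groups)
            p_exact = kw_permutation_p(groups)
            assert abs(p_chi2 - p_exact) < 0.12


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert pb.wilcoxon_ranksum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_minimum_p(self):
        # smallest attainable two-sided exact p for 3 vs 3: 2 / C(6,3)
        p = pb.wilcoxon_ranksum([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(2 / comb(6, 3), abs=1e-12)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 50:
            n, m = rng.integers(2, 6, 2)
            a = rng.permutation(100)[:n].astype(float)
            b = rng.permutation(100)[50:][:m].astype(float)
            if np.intersect1d(a, b).size:
                continue
            assert pb.wilcoxon_ranksum(a, b) == pytest.approx(
                ranksum_exact_p(a, b), abs=1e-10
            )
            checked += 1


class TestEffectSize:
    def test_null_and_clipping(self):
        assert pb.effect_size(0.0, 20, 4) == 0.0
        assert pb.effect_size(3.0, 29, 4) == 0.0  # H = k-1 is the null mean

    def test_formula_value(self):
        assert pb.effect_size(14.8, 29, 4) == pytest.approx(0.472, abs=5e-4)

    def test_uncorrected_variant(self):
        assert effect_size_uncorrected(14.0, 29) == pytest.approx(0.5)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            pb.effect_size(1.0, 4, 4)


class TestRankAndCut:
    def test_printed_cutoffs(self):
        assert pb.step_up_cutoff(54, 134, q=0.2) == pytest.approx(0.0806, abs=1e-4)
        assert pb.step_up_cutoff(52, 134, q=0.2) == pytest.approx(0.0776, abs=1e-4)

    def test_all_p_one_nothing_retained(self):
        df = pd.DataFrame({"region": ["a", "b"], "p": [1.0, 1.0]})
        out = pb.rank_and_cut(df, v_regions=134)
        assert not out["significant"].any()
        assert out.attrs["cutoff"] is None

    def test_sorted_and_flagged(self):
        df = pd.DataFrame({"region": list("abcd"), "p": [0.5, 0.001, 0.02, 0.9]})
        out = pb.rank_and_cut(df, q=0.2)
        assert list(out["region"]) == ["b", "c", "a", "d"]
        assert out["significant"].tolist() == [True, True, False, False]
        assert out.attrs["cutoff"] == pytest.approx((2 / 4) * 0.2)


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "medians,label",
        [
            ((0, 164, 136, 8), "descending"),      # monotone decrease over doses
            ((1, 16, 4, 37), "U-shaped"),           # mid dose smallest
            ((0, 0, 0, 0), "flat"),
            ((0, 2, 8, 30), "ascending"),
            ((0, 25, 0, 0), "single-dose-max"),
            ((0, 5, 5, 5), "flat"),                  # tied doses fall through
        ],
    )
    def test_labels(self, medians, label):
        assert pb.classify_profile(medians).label == label

    def test_max_dose_reported(self):
        prof = pb.classify_profile((0, 25, 3, 1))
        assert prof.label == "descending" and prof.max_dose == "1.0"

    def test_tolerance_makes_comparable(self):
        # a 1-voxel edge is not a meaningful maximum under tolerance
        assert pb.classify_profile((5, 23, 22, 22), tol=2.0).label == "flat"
        assert pb.classify_profile((5, 23, 22, 22), tol=0.0).label == "single-dose-max"


class TestReferenceTables:
    def test_strict_max_tally_negative_table(self):
        table = pb.load_reference_voa("negative")
        assert len(table) == 52
        tally = pb.most_effective_dose_tally(table)
        assert tally["mg_3_3"] == 15

    def test_positive_table_loads(self):
        table = pb.load_reference_voa("positive")
        assert len(table) == 54
        assert "omega_sq" in table.columns


class TestRegionalTable:
    def test_synthetic_dose_recovery(self):
        """A region responding only at the low dose: largest median at
        1.0 mg/kg, single-dose-max profile, retained by the cutoff."""
        rng = np.random.default_rng(0)
        counts = {}
        for rid in range(1, 11):
            counts[rid] = {
                g: rng.poisson(1.0, 6).astype(float).tolist()
                for g in ("vehicle", "1.0", "3.3", "10")
            }
        counts[5] = {
            g: [0, 1, 0, 1, 0, 1] for g in ("vehicle", "3.3", "10")
        }
        counts[5]["1.0"] = [60, 52, 48, 66, 59, 61]
        table = pb.regional_table(counts)
        row = table[table["region"] == 5].iloc[0]
        medians = [row[f"median_{g}"] for g in ("vehicle", "1.0", "3.3", "10")]
        assert row["median_1.0"] == max(medians)
        assert bool(row["significant"])
        assert row["profile"] == "single-dose-max" and row["max_dose"] == "1.0"
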