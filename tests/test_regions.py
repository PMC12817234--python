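import numpy as np
import pandas as pd
import pytest

from methylaging.io_formats import BetaMatrix, ProbeManifest
from methylaging.regions import (
    LmcStratConfig,
    RegionSet,
    annotate_tss,
    equal_count_groups,
    intersect_region_sets,
    lmc_stratification,
    map_probes,
    promoter_windows,
    region_methylation_score,
)


def coverage_set(rs: RegionSet) -> set[tuple[str, int]]:
    """Per-base oracle: the set of (chrom, base) covered by a region set."""
    out = set()
    for iv in rs:
        out.update((iv.chrom, b) for b in range(iv.start, iv.end))
    return out


def random_region_set(rng, n, universe=2000) -> RegionSet:
    tuples = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, universe - 1))
        end = start + int(rng.integers(1, 60))
        tuples.append((chrom, start, end))
    return RegionSet.from_tuples(tuples)


class TestIntersection:
    def test_disjoint_sets_empty(self):
        a = RegionSet.from_tuples([("chr1", 0, 10)])
        b = RegionSet.from_tuples([("chr1", 10, 20), ("chr2", 0, 10)])
        assert len(intersect_region_sets(a, b)) == 0

    def test_self_intersection_is_identity(self):
        a = RegionSet.from_tuples([("chr1", 5, 15), ("chr1", 30, 42), ("chr2", 0, 7)])
        assert intersect_region_sets(a, a).as_tuples() == a.as_tuples()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_sets_match_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_region_set(rng, 200)
        b = random_region_set(rng, 200)
        got = coverage_set(intersect_region_sets(a, b))
        assert got == coverage_set(a) & coverage_set(b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            RegionSet.from_tuples([("chr1", 10, 10)])


class TestTssAnnotation:
    def test_tss_at_region_start_is_tss(self):
        rs = RegionSet.from_tuples([("chr1", 100, 200)])
        assert annotate_tss(rs, [("chr1", 100)]).tolist() == [True]

    def test_tss_at_exclusive_end_is_not_tss(self):
        rs = RegionSet.from_tuples([("chr1", 100, 200)])
        assert annotate_tss(rs, [("chr1", 200)]).tolist() == [False]

    def test_random_tss_match_linear_scan_oracle(self):
        rng = np.random.default_rng(3)
        rs = random_region_set(rng, 100)
        tss = [(f"chr{rng.integers(1, 3)}", int(rng.integers(0, 2000))) for _ in range(60)]
        got = annotate_tss(rs, tss)
        for i, iv in enumerate(rs):
            expected = any(
                c == iv.chrom and iv.start <= p < iv.end for c, p in tss
            )
            assert got[i] == expected


class TestPromoterWindows:
    def test_plus_strand_arithmetic(self):
        rs = promoter_windows([("chr1", 5000, "+")])
        assert rs.as_tuples() == [("chr1", 2000, 5200)]

    def test_clipped_at_zero(self):
        rs = promoter_windows([("chr1", 1000, "+")])
        assert rs.as_tuples() == [("chr1", 0, 1200)]

    def test_minus_strand_mirrors_plus(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pos = int(rng.integers(4000, 100000))
            up, down = int(rng.integers(0, 5000)), int(rng.integers(0, 500))
            minus = promoter_windows([("chr1", pos, "-")], up, down).as_tuples()[0]
            assert minus == ("chr1", pos - down, pos + up)

    def test_default_strand_is_plus(self):
        assert (
            promoter_windows([("chr1", 5000)]).as_tuples()
            == promoter_windows([("chr1", 5000, "+")]).as_tuples()
        )


def manifest_from_positions(positions: dict[str, tuple[str, int]]) -> ProbeManifest:
    return ProbeManifest(
        pd.DataFrame(
            {
                "chrom": [c for c, _ in positions.values()],
                "pos": [p for _, p in positions.values()],
            },
            index=pd.Index(list(positions), name="probe_id"),
        )
    )


class TestProbeMapping:
    def test_probe_inside_region_is_member(self):
        man = manifest_from_positions({"cgA": ("chr1", 15)})
        rs = RegionSet.from_tuples([("chr1", 10, 20)])
        assert map_probes(man, rs) == {"cgA": [0]}

    def test_probe_at_exclusive_end_is_not_member(self):
        # 1-based pos 21 -> 0-based 20, outside [10, 20)
        man = manifest_from_positions({"cgA": ("chr1", 21)})
        rs = RegionSet.from_tuples([("chr1", 10, 20)])
        assert map_probes(man, rs) == {}

    def test_random_manifest_matches_brute_force(self):
        rng = np.random.default_rng(5)
        rs = random_region_set(rng, 80)
        positions = {
            f"cg{i}": (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 2000)))
            for i in range(150)
        }
        got = map_probes(manifest_from_positions(positions), rs)
        regions_list = list(rs)
        for probe, (chrom, pos) in positions.items():
            expected = [
                i
                for i, iv in enumerate(regions_list)
                if iv.chrom == chrom and iv.start <= pos - 1 < iv.end
            ]
            assert got.get(probe, []) == expected


class TestRegionScore:
    def _matrix(self, data, samples=("s1", "s2")):
        return BetaMatrix(pd.DataFrame(data, columns=list(samples)))

    def test_uniform_half_betas_score_half(self):
        m = self._matrix(pd.DataFrame(0.5, index=["cg1", "cg2", "cg3"], columns=["s1", "s2"]))
        scores = region_methylation_score(m, {"cg1": [0], "cg2": [0]}, "X")
        assert (scores["mean_beta"] == 0.5).all()
        assert (scores["n_cpgs_used"] == 2).all()

    def test_single_member_equals_that_beta(self):
        df = pd.DataFrame({"s1": [0.3, 0.9]}, index=["cg1", "cg2"])
        scores = region_methylation_score(BetaMatrix(df), {"cg2": [0]}, "X")
        assert scores.loc["s1", "mean_beta"] == 0.9

    def test_matches_sum_count_oracle_and_order_invariance(self, rng):
        probes = [f"cg{i}" for i in range(40)]
        df = pd.DataFrame(
            rng.random((40, 6)), index=probes, columns=[f"s{j}" for j in range(6)]
        )
        members = {p: [0] for p in rng.choice(probes, 15, replace=False)}
        scores = region_methylation_score(BetaMatrix(df), members, "X")
        manual = df.loc[sorted(members)].sum(axis=0) / len(members)
        np.testing.assert_allclose(scores["mean_beta"], manual, atol=1e-12)
        # shuffled probe order gives identical scores
        shuffled = BetaMatrix(df.sample(frac=1, random_state=1))
        scores2 = region_methylation_score(shuffled, members, "X")
        np.testing.assert_allclose(scores2["mean_beta"], scores["mean_beta"], atol=1e-12)

    def test_empty_membership_rejected(self):
        df = pd.DataFrame({"s1": [0.3]}, index=["cg1"])
        with pytest.raises(ValueError, match="XYZ"):
            region_methylation_score(BetaMatrix(df), {"other": [0]}, "XYZ")


class TestLmcStratification:
    def test_equal_count_groups_sizes_differ_by_at_most_one(self, rng):
        for n in [14, 20, 23]:
            values = pd.Series(rng.random(n), index=[f"s{i}" for i in range(n)])
            groups = equal_count_groups(values, 7)
            sizes = groups.value_counts()
            assert sizes.max() - sizes.min() <= 1
            assert set(groups.unique()) == set(range(7))

    def test_groups_ordered_by_value(self):
        values = pd.Series([5.0, 1.0, 3.0, 2.0, 4.0, 6.0], index=list("abcdef"))
        groups = equal_count_groups(values, 3)
        assert groups["b"] == 0 and groups["f"] == 2

    def test_uniform_betas_give_uniform_cells(self):
        probes = [f"cg{i}" for i in range(30)]
        samples = [f"s{i}" for i in range(21)]
        m = BetaMatrix(pd.DataFrame(0.2, index=probes, columns=samples))
        membership = {p: [i // 3] for i, p in enumerate(probes)}
        ages = pd.Series(np.arange(21, dtype=float) + 30, index=samples)
        cfg = LmcStratConfig(n_groups=7, n_region_bins=2, lmc_beta_threshold=0.3)
        table = lmc_stratification(m, membership, 10, ages, cfg)
        np.testing.assert_allclose(table.to_numpy(), 0.2, atol=1e-12)

    def test_too_few_lmc_regions_rejected(self):
        probes = ["cg0", "cg1"]
        m = BetaMatrix(pd.DataFrame(0.1, index=probes, columns=["s1", "s2", "s3"]))
        membership = {"cg0": [0], "cg1": [1]}
        ages = pd.Series([1.0, 2.0, 3.0], index=["s1", "s2", "s3"])
        cfg = LmcStratConfig(n_groups=2, n_region_bins=5)
        with pytest.raises(ValueError, match="n_region_bins"):
            lmc_stratification(m, membership, 2, ages, cfg)
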