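"""Window aggregation, thresholding, region merging and gene intersection."""

import numpy as np
import pandas as pd
import pytest

from forestscan.matrix import FormatError
from forestscan.sim import write_gff
from forestscan.windows import (
    RegionSet,
    ThresholdSpec,
    WindowTrack,
    build_track,
    call_regions,
    fixed_threshold,
    overlapping_genes,
    permutation_threshold,
    read_genes,
    regions_to_genes,
    top_variants,
)


def _variants(positions, scaffold="sc1"):
    if isinstance(positions, dict):
        frames = [
            pd.DataFrame({"scaffold": s, "pos": p, "ref": "A", "alt": "T"})
            for s, p in positions.items()
        ]
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame({"scaffold": scaffold, "pos": positions, "ref": "A", "alt": "T"})


def brute_force_window_sums(imp, variants, lengths, size, offset):
    """Independent oracle: enumerate windows and test membership per variant."""
    sums = []
    for scaffold in sorted(lengths):
        for start in range(0, lengths[scaffold], offset):
            end = start + size
            total = 0.0
            for i, (_, v) in enumerate(variants.iterrows()):
                if v["scaffold"] == scaffold and start <= v["pos"] - 1 < end:
                    total += imp[i]
            sums.append(total)
    return np.array(sums)


class TestBuildTrack:
    def test_worked_example(self):
        """Two variants on a 10 kb scaffold land in the documented windows."""
        variants = _variants([100, 6000])
        track = build_track(np.array([0.2, 0.3]), variants, {"sc1": 10_000})
        w = track.windows
        assert list(w["start"]) == [0, 2500, 5000, 7500]
        np.testing.assert_allclose(w["importance_sum"], [0.2, 0.3, 0.3, 0.0])
        # pos 6000 covered twice, pos 100 (before the first offset) once
        assert w["variant_count"].tolist() == [1, 1, 1, 0]

    def test_empty_importance(self):
        variants = _variants([100, 6000])
        track = build_track(np.zeros(2), variants, {"sc1": 10_000})
        assert (track.windows["importance_sum"] == 0).all()

    def test_double_counting_conservation_random_tracks(self):
        """Window sums equal 2x total importance minus the first-stripe mass."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            lengths = {"sc1": 40_000, "sc2": 25_000}
            n = rng.integers(5, 60)
            scaffolds = rng.choice(["sc1", "sc2"], size=n)
            pos = np.array([rng.integers(1, lengths[s] + 1) for s in scaffolds])
            variants = (
                _variants({s: pos[scaffolds == s] for s in ("sc1", "sc2")})
                .sort_values(["scaffold", "pos"])
                .reset_index(drop=True)
            )
            variants = variants.drop_duplicates(["scaffold", "pos"]).reset_index(drop=True)
            imp = rng.random(len(variants))
            track = build_track(imp, variants, lengths, size=5000, offset=2500)
            first_stripe = sum(
                imp[i]
                for i, (_, v) in enumerate(variants.iterrows())
                if v["pos"] - 1 < 2500
            )
            expected = 2 * imp.sum() - first_stripe
            assert track.windows["importance_sum"].sum() == pytest.approx(expected)
            oracle = brute_force_window_sums(imp, variants, lengths, 5000, 2500)
            np.testing.assert_allclose(track.windows["importance_sum"], oracle)

    def test_variant_beyond_scaffold_errors(self):
        with pytest.raises(ValueError, match="sc1"):
            build_track(np.ones(1), _variants([20_001]), {"sc1": 20_000})


def _track_from_sums(sums, counts):
    n = len(sums)
    return WindowTrack(
        pd.DataFrame(
            {
                "scaffold": ["sc1"] * n,
                "start": np.arange(n) * 2500,
                "end": np.arange(n) * 2500 + 5000,
                "importance_sum": sums,
                "variant_count": counts,
            }
        )
    )


class TestFixedThreshold:
    def test_strict_inequality_at_threshold(self):
        track = _track_from_sums([1, 1, 1, 5], [10] * 4)
        res = fixed_threshold(track, ThresholdSpec(factor=2.5))
        assert res.threshold == pytest.approx(5.0)
        assert res.n_called == 0  # 5 > 5 is false

    def test_single_window_called(self):
        track = _track_from_sums([1, 1, 1, 9], [10] * 4)
        res = fixed_threshold(track, ThresholdSpec(factor=2.5))
        assert res.threshold == pytest.approx(7.5)
        assert res.called.tolist() == [False, False, False, True]

    def test_min_variants_gates_mean_and_calling(self):
        # the 100-sum window is ineligible: it neither inflates the mean nor calls
        track = _track_from_sums([1, 1, 1, 100], [10, 10, 10, 3])
        res = fixed_threshold(track, ThresholdSpec(factor=2.5, min_variants=10))
        assert res.threshold == pytest.approx(2.5)
        assert res.n_called == 0

    def test_no_eligible_window_errors(self):
        track = _track_from_sums([1, 2], [3, 4])
        with pytest.raises(ValueError, match="min_variants"):
            fixed_threshold(track, ThresholdSpec(min_variants=10))

    def test_factor_monotonicity(self):
        rng = np.random.default_rng(0)
        track = _track_from_sums(rng.exponential(size=30), [12] * 30)
        called_sets = []
        for factor in (1.0, 1.5, 2.5, 4.0):
            res = fixed_threshold(track, ThresholdSpec(factor=factor))
            called_sets.append(set(np.nonzero(res.called)[0]))
        for a, b in zip(called_sets, called_sets[1:]):
            assert b <= a


class TestPermutationThreshold:
    def test_exchangeable_null_calls_nothing(self):
        """All importances equal: every permutation reproduces the observed sums."""
        variants = _variants(np.arange(1, 21) * 1000)
        imp = np.full(20, 0.05)
        track = build_track(imp, variants, {"sc1": 21_000})
        res = permutation_threshold(
            track, imp, variants, ThresholdSpec(mode="permutation", n_permutations=200,
                                                min_variants=1, seed=1)
        )
        assert res.n_called == 0

    def test_planted_peak_called(self):
        rng = np.random.default_rng(5)
        variants = _variants(np.sort(rng.choice(np.arange(1, 100_000), 300, replace=False)))
        imp = rng.random(300) * 0.01
        peak = (variants["pos"] > 40_000) & (variants["pos"] <= 42_000)
        imp[peak.to_numpy()] += 1.0
        track = build_track(imp, variants, {"sc1": 100_000})
        res = permutation_threshold(
            track, imp, variants,
            ThresholdSpec(mode="permutation", n_permutations=300, min_variants=1, seed=2),
        )
        called_windows = track.windows[res.called]
        assert ((called_windows["start"] <= 41_999) & (called_windows["end"] > 40_000)).any()

    def test_percentile_monotonicity(self):
        rng = np.random.default_rng(8)
        variants = _variants(np.sort(rng.choice(np.arange(1, 50_000), 200, replace=False)))
        imp = rng.exponential(size=200)
        track = build_track(imp, variants, {"sc1": 50_000})
        called = []
        for pct in (90.0, 99.0):
            res = permutation_threshold(
                track, imp, variants,
                ThresholdSpec(mode="permutation", n_permutations=300,
                              min_variants=1, percentile=pct, seed=3),
            )
            called.append(set(np.nonzero(res.called)[0]))
        assert called[1] <= called[0]


class TestCallRegions:
    def test_overlapping_windows_merge(self):
        track = _track_from_sums([1, 1, 0], [10] * 3)
        called = np.array([True, True, False])
        regions = call_regions(track, called)
        assert len(regions) == 1
        r = regions.regions.iloc[0]
        assert (r["start"], r["end"], r["n_windows"]) == (0, 7500, 2)
        assert regions.total_length == 7500

    def test_disjoint_windows_stay_separate(self):
        df = pd.DataFrame(
            {
                "scaffold": ["sc1", "sc1"],
                "start": [0, 10_000],
                "end": [5000, 15_000],
                "importance_sum": [1.0, 1.0],
                "variant_count": [10, 10],
            }
        )
        regions = call_regions(WindowTrack(df), np.array([True, True]))
        assert len(regions) == 2

    def test_merge_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(4)
        starts = np.arange(0, 100_000, 2500)
        df = pd.DataFrame(
            {
                "scaffold": "sc1",
                "start": starts,
                "end": starts + 5000,
                "importance_sum": rng.random(len(starts)),
                "variant_count": 10,
            }
        )
        called = rng.random(len(starts)) < 0.3
        a = call_regions(WindowTrack(df), called)
        perm = rng.permutation(len(starts))
        b = call_regions(WindowTrack(df.iloc[perm].reset_index(drop=True)), called[perm])
        pd.testing.assert_frame_equal(a.regions, b.regions)
        # merged regions are non-overlapping
        for _, grp in a.regions.groupby("scaffold"):
            s = grp.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


class TestGenes:
    def test_half_open_overlap_rule(self):
        regions = pd.DataFrame({"scaffold": ["sc1"], "start": [0], "end": [5000]})
        genes = pd.DataFrame(
            {
                "gene_id": ["inside", "boundary"],
                "scaffold": ["sc1", "sc1"],
                "start": [2000, 5000],
                "end": [3000, 6000],
            }
        )
        hits = overlapping_genes(regions, genes)
        assert hits == [["inside"]]

    def test_tiling_gene_counts(self, tmp_path):
        gff = write_gff([("sc1", 60_000)], tmp_path / "g.gff3", gene_length=2000, gene_gap=1000)
        genes = read_genes(gff)
        pitch = 3000
        regions = RegionSet(
            pd.DataFrame(
                {
                    "scaffold": ["sc1"],
                    "start": [6000],
                    "end": [21_000],
                    "n_windows": [5],
                    "total_importance": [1.0],
                }
            )
        )
        out = regions_to_genes(regions, gff)
        n_genes = len(out.regions.iloc[0]["genes"].split(","))
        expected = int(np.ceil((21_000 - 6000) / pitch))
        assert abs(n_genes - expected) <= 1

    def test_gff_round_trip_coordinates(self, tmp_path):
        gff = write_gff([("sc1", 10_000)], tmp_path / "g.gff3", gene_length=1500, gene_gap=500)
        genes = read_genes(gff)
        # first tiled gene is 1-based [1, 1500] -> half-open [0, 1500)
        assert genes.iloc[0]["start"] == 0 and genes.iloc[0]["end"] == 1500

    def test_malformed_gff_names_line(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nsc1\tsrc\tgene\tnotanint\t10\t.\t+\t.\tID=x\n")
        with pytest.raises(FormatError, match=":2"):
            read_genes(path)


class TestTopVariants:
    def test_union_of_model_bests(self):
        variants = _variants([10, 20, 30])
        models = [np.array([0.5, 0.3, 0.2]), np.array([0.1, 0.8, 0.1])]
        dedup = np.maximum(*models)
        out = top_variants(models, dedup, variants, k=0)
        assert set(out["pos"]) == {10, 20}
        assert out["model_best"].all()

    def test_unanimous_best_single_row(self):
        variants = _variants([10, 20])
        models = [np.array([0.9, 0.1])] * 3
        out = top_variants(models, models[0], variants, k=0)
        assert len(out) == 1 and out.iloc[0]["pos"] == 10

    def test_global_top_k_added(self):
        variants = _variants([10, 20, 30, 40])
        models = [np.array([0.9, 0.05, 0.03, 0.02])]
        out = top_variants(models, models[0], variants, k=3)
        assert set(out["pos"]) == {10, 20, 30}
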