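import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_peaks

from atacpost.core import GenomicInterval, merge_union
from atacpost.peaks import (
    PeakCollection,
    ScoredPeak,
    count_insertions_in_peaks,
    representative_peaks_replicates,
    representative_peaks_union,
    sample_similarity_pca,
    size_factors,
    top_k_by_rank_average,
    top_k_by_significance,
)


def peak(chrom, start, end, score=1.0, sample="s"):
    return ScoredPeak(GenomicInterval(chrom, start, end), score, sample)


class TestReplicateSupport:
    def test_supported_in_two_of_three_kept(self):
        pooled = [peak("chr1", 100, 200)]
        reps = [
            [peak("chr1", 150, 250)],
            [peak("chr1", 190, 300)],
            [peak("chr2", 0, 100)],
        ]
        out = representative_peaks_replicates(pooled, reps)
        assert len(out) == 1
        assert out.provenance == "replicate-supported"

    def test_supported_in_one_of_three_dropped(self):
        pooled = [peak("chr1", 100, 200)]
        reps = [[peak("chr1", 150, 250)], [peak("chr2", 0, 50)], [peak("chr2", 60, 90)]]
        assert len(representative_peaks_replicates(pooled, reps)) == 0

    def test_min_support_exceeding_replicates_errors(self):
        with pytest.raises(ValueError, match="min_support"):
            representative_peaks_replicates(
                [peak("chr1", 0, 10)], [[peak("chr1", 0, 10)]] * 2, min_support=3
            )

    def test_random_fixture_matches_allpairs_oracle(self, rng):
        pooled = random_peaks(rng, 200, max_pos=5000, max_len=120)
        reps = [random_peaks(rng, 80, max_pos=5000, max_len=120) for _ in range(3)]
        got = representative_peaks_replicates(pooled, reps, min_support=2)
        want = oracles.replicate_supported(pooled, reps, min_support=2)
        assert [p.interval for p in got.peaks] == [pooled[i].interval for i in want]
        # output is a subset of the pooled input
        pooled_set = {(p.interval, p.score) for p in pooled}
        assert all((p.interval, p.score) in pooled_set for p in got.peaks)


class TestUnion:
    def test_identical_peaks_one_region_three_contributors(self):
        sets = [[peak("chr1", 100, 200, 5.0, f"i{j}")] for j in range(3)]
        out = representative_peaks_union(sets)
        assert len(out) == 1
        assert len(out.contributors[0]) == 3

    def test_disjoint_peaks_stay_separate(self):
        sets = [[peak("chr1", 0, 100, 1, "a")], [peak("chr1", 500, 600, 2, "b")]]
        out = representative_peaks_union(sets)
        assert len(out) == 2
        assert all(len(c) == 1 for c in out.contributors)

    def test_abutting_peaks_spanned_by_other_individual_merge(self):
        sets = [
            [peak("chr1", 0, 50, 1, "a"), peak("chr1", 50, 100, 2, "a")],
            [peak("chr1", 10, 90, 3, "b")],
        ]
        out = representative_peaks_union(sets)
        assert len(out) == 1
        assert out.peaks[0].interval == GenomicInterval("chr1", 0, 100)
        assert out.contributors[0] == {"a": 2, "b": 3}

    def test_union_covers_same_bases_as_merge(self, rng):
        sets = [random_peaks(rng, 60, sample=f"i{j}") for j in range(3)]
        out = representative_peaks_union(sets)
        expected = merge_union([p.interval for s in sets for p in s])
        assert out.intervals() == expected


class TestTopK:
    def test_three_largest_scores(self):
        peaks = [peak("chr1", i * 100, i * 100 + 50, float(i)) for i in range(10)]
        out = top_k_by_significance(PeakCollection(peaks), k=3)
        assert sorted(p.score for p in out.peaks) == [7.0, 8.0, 9.0]

    def test_k_larger_than_collection(self):
        peaks = [peak("chr1", 0, 10, 1.0)]
        assert len(top_k_by_significance(PeakCollection(peaks), k=50)) == 1

    def test_boundary_ties_broken_by_position(self, rng):
        peaks = [
            peak("chr1", int(s), int(s) + 10, float(score))
            for s, score in zip(
                rng.choice(10_000, 50, replace=False),
                rng.integers(1, 6, size=50),  # heavy ties
            )
        ]
        out = top_k_by_significance(PeakCollection(peaks), k=20)
        order = sorted(
            peaks, key=lambda p: (-p.score, p.interval.chrom, p.interval.start)
        )
        assert [p.interval for p in out.peaks] == [p.interval for p in order[:20]]


class TestRankAverage:
    def test_region_ranked_first_everywhere_selected_first(self):
        sets = [
            [peak("chr1", 100, 200, 9.0, "a"), peak("chr1", 500, 600, 1.0, "a")],
            [peak("chr1", 110, 210, 8.0, "b"), peak("chr2", 0, 50, 2.0, "b")],
        ]
        union = representative_peaks_union(sets)
        out = top_k_by_rank_average(union, sets, k=1)
        assert out.peaks[0].interval.start == 100

    def test_absent_individual_contributes_worst_rank_plus_one(self):
        # individual 1: region ranked 5 of 10; individual 2: absent with 10 peaks
        ind1 = [peak("chr1", 1000 * i, 1000 * i + 100, float(10 - i), "a")
                for i in range(10)]
        target = ind1[4].interval  # score 6 -> rank 5
        ind2 = [peak("chr2", 1000 * i, 1000 * i + 100, float(i + 1), "b")
                for i in range(10)]
        union = representative_peaks_union([ind1, ind2])
        from atacpost.peaks import rank_average_table

        table = rank_average_table(union, [ind1, ind2])
        row = [
            i for i, p in enumerate(union.peaks) if p.interval == target
        ][0]
        assert table.loc[row, "individual_1"] == 5
        assert table.loc[row, "individual_2"] == 11
        assert table.loc[row, "mean_rank"] == pytest.approx((5 + 11) / 2)

    def test_selection_matches_bruteforce_rank_oracle(self, rng):
        sets = [random_peaks(rng, 100, sample=f"i{j}", max_pos=50_000, max_len=300)
                for j in range(3)]
        union = representative_peaks_union(sets)
        out = top_k_by_rank_average(union, sets, k=20)
        table = oracles.rank_table(union.intervals(), sets)
        mean = table.mean(axis=1)
        order = sorted(
            range(len(union.peaks)),
            key=lambda i: (mean[i], union.peaks[i].interval.chrom,
                           union.peaks[i].interval.start),
        )
        want = [union.peaks[i].interval for i in order[:20]]
        assert [p.interval for p in out.peaks] == want

    def test_empty_individual_set_errors(self):
        sets = [[peak("chr1", 0, 10, 1.0, "a")], []]
        union = representative_peaks_union([sets[0]])
        with pytest.raises(ValueError, match="empty"):
            top_k_by_rank_average(union, sets, k=1)


class TestCounts:
    def test_containment(self):
        coll = PeakCollection([peak("chr1", 100, 200)])
        ins = {"s1": {"chr1": np.array([100, 150, 199, 200, 50])}}
        mat = count_insertions_in_peaks(ins, coll)
        assert mat.iloc[0, 0] == 3

    def test_empty_sample_gives_zero_column(self):
        coll = PeakCollection([peak("chr1", 100, 200)])
        mat = count_insertions_in_peaks({"s1": {}, "s2": {"chr1": np.array([150])}}, coll)
        assert mat["s1"].sum() == 0 and mat["s2"].sum() == 1

    def test_random_matches_linear_scan_oracle(self, rng):
        coll = PeakCollection(random_peaks(rng, 40, max_pos=5000, max_len=100))
        samples = {}
        for s in ("a", "b"):
            samples[s] = {
                "chr1": np.sort(rng.integers(0, 6000, size=5000)),
                "chr2": np.sort(rng.integers(0, 6000, size=5000)),
            }
        mat = count_insertions_in_peaks(samples, coll)
        for j, s in enumerate(("a", "b")):
            for i, p in enumerate(coll.peaks):
                pos = samples[s].get(p.interval.chrom, np.array([]))
                want = int(((pos >= p.interval.start) & (pos < p.interval.end)).sum())
                assert mat.iloc[i, j] == want


class TestPca:
    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            size_factors(counts)

    def test_identical_samples_identical_coordinates(self, rng):
        col = rng.integers(1, 100, size=50)
        counts = pd.DataFrame({"a": col, "b": col, "c": rng.integers(1, 100, size=50)})
        coords, _ = sample_similarity_pca(counts, n_components=2)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_variance_explained_is_sorted_and_bounded(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(100, 6)), columns=list("abcdef")
        )
        _, var = sample_similarity_pca(counts, n_components=4)
        assert all(x >= y - 1e-12 for x, y in zip(var, var[1:]))
        assert var.sum() <= 1 + 1e-9

    def test_group_structure_separates_on_pc1(self, rng):
        # two groups with distinct peak-intensity profiles
        n_peaks = 200
        base_a = rng.uniform(5, 50, size=n_peaks)
        base_b = rng.permutation(base_a)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = rng.poisson(base_a)
            cols[f"b{i}"] = rng.poisson(base_b)
        counts = pd.DataFrame(cols) + 1
        coords, _ = sample_similarity_pca(counts, n_components=2)
        a = coords.loc[[c for c in coords.index if c.startswith("a")], "PC1"]
        b = coords.loc[[c for c in coords.index if c.startswith("b")], "PC1"]
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_simulated_design_clusters_by_group(self):
        from sklearn.metrics import silhouette_score

        from atacpost import pipeline, simulate
        from atacpost.peaks import merge_collections

        cfg = pipeline.smoke_config(7)
        import dataclasses

        tissue = simulate.sim_peak_sets(cfg, n_samples=3, sample_prefix="t")
        reps = simulate.sim_peak_sets(
            dataclasses.replace(cfg, seed=cfg.seed + 1), n_samples=3, sample_prefix="r"
        )
        regions = PeakCollection(
            merge_collections(
                representative_peaks_union(list(tissue.per_sample.values())),
                representative_peaks_union(list(reps.per_sample.values())),
            )
        )
        insertions = {}
        from atacpost.simulate import sim_insertions

        for si, (s, ps) in enumerate({**tissue.per_sample, **reps.per_sample}.items()):
            insertions[s] = sim_insertions(
                cfg, [p.interval for p in ps],
                rng=np.random.default_rng((cfg.seed, 99, si)), depletion=0.0,
            )
        counts = count_insertions_in_peaks(insertions, regions)
        coords, _ = sample_similarity_pca(counts, n_components=2)
        labels = [0 if s.startswith("t") else 1 for s in coords.index]
        assert silhouette_score(coords.to_numpy(), labels) > 0
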