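import numpy as np
import pytest

from atacpost.core import DisjointIntervals, Genome, GenomicInterval
from atacpost.footprints import (
    MotifWindow,
    TranspositionMatrix,
    aggregate_profiles,
    build_windows,
    classify_bound,
    em_loglik_trace,
    em_posterior_standin,
    footprint_from_matrix,
    tpr_footprint,
    transposition_matrix,
)
from atacpost.motifs import MotifOccurrence


def occ(chrom="chr1", start=5000, length=10, strand="+", score=10.0):
    return MotifOccurrence(
        GenomicInterval(chrom, start, start + length, strand), "m", score
    )


def windows_from(occs, genome=None, flank=100):
    genome = genome or Genome(sizes={"chr1": 1_000_000})
    return build_windows(occs, genome, flank=flank)


class TestBuildWindows:
    def test_low_mappability_window_removed(self):
        # mappable only on 85% of the window
        window_start, window_end = 4900, 5110
        mappable_len = int(0.85 * (window_end - window_start))
        genome = Genome(
            sizes={"chr1": 1_000_000},
            mappability=DisjointIntervals(
                [GenomicInterval("chr1", window_start, window_start + mappable_len)]
            ),
        )
        assert build_windows([occ()], genome) == []

    def test_blacklist_single_bp_overlap_removes(self):
        genome = Genome(
            sizes={"chr1": 1_000_000},
            blacklist=DisjointIntervals([GenomicInterval("chr1", 5109, 5110)]),
        )
        assert build_windows([occ()], genome) == []

    def test_out_of_bounds_window_dropped(self):
        genome = Genome(sizes={"chr1": 5_100})
        assert build_windows([occ(start=5000)], genome) == []

    def test_all_mappable_keeps_all(self):
        occs = [occ(start=s) for s in (5000, 8000, 11000)]
        assert len(windows_from(occs)) == 3


class TestTranspositionMatrix:
    def test_single_insertion_at_motif_center(self):
        w = windows_from([occ(start=5000, length=10)])
        # motif occupies columns 100..109; its center base 5005 -> column 105
        m = transposition_matrix({"chr1": np.array([5005])}, w)
        assert m.counts.sum() == 1
        assert m.counts[0, 105] == 1

    def test_minus_strand_rows_mirror(self):
        ins = {"chr1": np.array([4905])}  # 5 bp into the window from the left
        plus = transposition_matrix(ins, windows_from([occ(strand="+")]))
        minus = transposition_matrix(ins, windows_from([occ(strand="-")]))
        width = plus.counts.shape[1]
        assert plus.counts[0, 5] == 1
        assert minus.counts[0, width - 1 - 5] == 1

    def test_random_fixture_matches_event_oracle(self, rng):
        occs = [occ(start=int(s), strand="+" if rng.random() < 0.5 else "-")
                for s in rng.choice(50_000, 20, replace=False) + 1000]
        w = windows_from(occs)
        pos = np.sort(rng.integers(0, 60_000, size=5000))
        m = transposition_matrix({"chr1": pos}, w)
        for i, win in enumerate(w):
            want = np.zeros(m.counts.shape[1], dtype=int)
            for p in pos:
                if win.window.start <= p < win.window.end:
                    off = p - win.window.start
                    if win.occurrence.interval.strand == "-":
                        off = m.counts.shape[1] - 1 - off
                    want[off] += 1
            assert (m.counts[i] == want).all()

    def test_strand_flip_with_mirrored_coordinates_gives_same_matrix(self, rng):
        """Flipping all strands and mirroring insertions around each window
        center reproduces the same count matrix."""
        occs = [occ(start=int(s)) for s in rng.choice(50_000, 10, replace=False) + 1000]
        w_plus = windows_from(occs)
        pos = np.sort(rng.integers(1000, 52_000, size=2000))
        m_plus = transposition_matrix({"chr1": pos}, w_plus)

        occs_minus = [
            MotifOccurrence(
                GenomicInterval(o.interval.chrom, o.interval.start, o.interval.end, "-"),
                o.motif_id, o.score)
            for o in occs
        ]
        w_minus = windows_from(occs_minus)
        for i, (wp, wm) in enumerate(zip(w_plus, w_minus)):
            # mirror this window's insertion positions around its center
            sel = pos[(pos >= wp.window.start) & (pos < wp.window.end)]
            mirrored = wp.window.start + (wp.window.end - 1 - sel)
            row = transposition_matrix({"chr1": np.sort(mirrored)}, [wm]).counts[0]
            assert (row == m_plus.counts[i]).all()


class TestClassifyBound:
    @pytest.mark.parametrize("p, label", [
        (0.995, "bound"), (0.3, "unbound"), (0.7, "ambiguous"),
        (0.99, "ambiguous"), (0.5, "ambiguous"),
    ])
    def test_thresholds(self, p, label):
        assert classify_bound(np.array([p]))[0] == label

    def test_out_of_range_posterior_rejected(self):
        with pytest.raises(ValueError):
            classify_bound(np.array([1.2]))


def planted_matrix(rng, n_bound=150, n_unbound=300, motif_len=10, flank=100,
                   rate=0.05, boost=3.0, depletion=0.4):
    width = motif_len + 2 * flank
    lam_b = np.full(width, rate * boost)
    lam_b[flank:flank + motif_len] *= 1 - depletion
    lam_u = np.full(width, rate)
    counts = np.vstack([
        rng.poisson(lam_b, size=(n_bound, width)),
        rng.poisson(lam_u, size=(n_unbound, width)),
    ])
    scores = np.concatenate([rng.normal(12, 1, n_bound), rng.normal(8, 1.5, n_unbound)])
    windows = [
        MotifWindow(occ(start=1000 + 1000 * i, length=motif_len, score=float(s)),
                    GenomicInterval("chr1", 1000 + 1000 * i - flank,
                                    1000 + 1000 * i + motif_len + flank))
        for i, s in enumerate(scores)
    ]
    labels = np.array([True] * n_bound + [False] * n_unbound)
    return TranspositionMatrix(counts, windows, motif_len, flank), labels


class TestEmStandin:
    def test_planted_components_recovered(self, rng):
        m, truth = planted_matrix(rng)
        post, info = em_posterior_standin(m)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(truth, post) >= 0.9

    def test_identical_windows_get_equal_posteriors(self):
        motif_len, flank = 10, 100
        width = motif_len + 2 * flank
        counts = np.ones((60, width), dtype=int)
        windows = [
            MotifWindow(occ(start=1000 + 500 * i, length=motif_len, score=5.0),
                        GenomicInterval("chr1", 1000 + 500 * i - flank,
                                        1000 + 500 * i + motif_len + flank))
            for i in range(60)
        ]
        m = TranspositionMatrix(counts, windows, motif_len, flank)
        post, _ = em_posterior_standin(m)
        assert np.allclose(post, post[0])

    def test_loglik_nondecreasing(self, rng):
        m, _ = planted_matrix(rng, n_bound=60, n_unbound=120)
        trace = em_loglik_trace(m, n_iter=12)
        assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))

    def test_too_few_windows_rejected(self, rng):
        m, _ = planted_matrix(rng, n_bound=10, n_unbound=20)
        with pytest.raises(ValueError, match="50"):
            em_posterior_standin(m)


class TestAggregateProfiles:
    def test_identical_bound_windows_equal_single_window_profile(self, rng):
        m, _ = planted_matrix(rng, n_bound=5, n_unbound=5)
        m.counts[:5] = m.counts[0]
        labels = np.array(["bound"] * 5 + ["unbound"] * 5, dtype=object)
        bound, _ = aggregate_profiles(m, labels, smoothing=0.0)
        single = m.counts[0] / m.counts[0].sum()
        assert np.allclose(bound, single)

    def test_top_unbound_selection_by_motif_score(self, rng):
        m, _ = planted_matrix(rng, n_bound=5, n_unbound=50)
        labels = np.array(["bound"] * 5 + ["unbound"] * 50, dtype=object)
        scores = m.scores
        top10 = np.argsort(-scores[5:], kind="stable")[:10] + 5
        _, unbound = aggregate_profiles(m, labels, top_unbound=10, smoothing=0.0)
        manual = m.counts[top10].sum(axis=0)
        assert np.allclose(unbound, manual / manual.sum())

    def test_profiles_sum_to_one(self, rng):
        m, truth = planted_matrix(rng, n_bound=20, n_unbound=30)
        labels = np.where(truth, "bound", "unbound").astype(object)
        b, u = aggregate_profiles(m, labels)
        assert b.sum() == pytest.approx(1.0) and u.sum() == pytest.approx(1.0)

    def test_no_bound_sites_errors(self, rng):
        m, _ = planted_matrix(rng, n_bound=5, n_unbound=5)
        labels = np.array(["unbound"] * 10, dtype=object)
        with pytest.raises(ValueError, match="no bound"):
            aggregate_profiles(m, labels)


class TestTpr:
    def test_equal_profiles_give_tpr_one_no_footprint(self):
        width = 10 + 200
        prof = np.full(width, 1.0 / width)
        res = tpr_footprint(prof, prof, 10, 100)
        assert np.allclose(res.tpr, 1.0)
        assert res.mtpr == pytest.approx(1.0)
        assert res.ftpr == pytest.approx(1.0)
        assert not res.has_footprint

    def test_halved_motif_positions_called_footprint(self):
        """Closed-form: bound profile halves its motif mass, then renormalizes."""
        motif_len, flank = 10, 100
        width = motif_len + 2 * flank
        unbound = np.full(width, 1.0 / width)
        bound_raw = np.full(width, 1.0)
        bound_raw[flank:flank + motif_len] = 0.5
        bound = bound_raw / bound_raw.sum()
        res = tpr_footprint(bound, unbound, motif_len, flank)
        scale = width / bound_raw.sum()
        assert res.mtpr == pytest.approx(0.5 * scale)
        assert res.ftpr == pytest.approx(1.0 * scale)
        assert res.has_footprint

    def test_scale_invariance_of_tpr(self, rng):
        m, truth = planted_matrix(rng, n_bound=100, n_unbound=200, rate=0.2)
        labels = np.where(truth, "bound", "unbound").astype(object)
        b, u = aggregate_profiles(m, labels, smoothing=0.0)
        res1 = tpr_footprint(b, u, m.motif_len, m.flank)
        m2 = TranspositionMatrix(m.counts * 7, m.windows, m.motif_len, m.flank)
        b2, u2 = aggregate_profiles(m2, labels, smoothing=0.0)
        res2 = tpr_footprint(b2, u2, m.motif_len, m.flank)
        assert np.allclose(res1.tpr, res2.tpr)
        assert res1.mtpr == pytest.approx(res2.mtpr)

    def test_zero_unbound_position_errors(self):
        width = 10 + 200
        unbound = np.full(width, 1.0 / width)
        unbound[0] = 0.0
        with pytest.raises(ValueError, match="zero"):
            tpr_footprint(np.full(width, 1.0 / width), unbound, 10, 100)

    def test_end_to_end_planted_depletion_called(self, rng):
        m, truth = planted_matrix(rng, n_bound=200, n_unbound=400, depletion=0.3)
        res = footprint_from_matrix(m, posteriors=np.where(truth, 1.0, 0.0))
        assert res.has_footprint
        assert res.mtpr < res.ftpr
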