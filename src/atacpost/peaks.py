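"""Representative-peak consolidation, top-K selection, counts-in-peaks, PCA.

Two consolidation schemes produce "representative peaks":

* technical replicates — peaks called on pooled reads are kept when they
  share >= 1 bp with replicate peaks from >= 2 distinct replicates;
* individuals (no technical replicates) — the union of per-individual peaks,
  merged into disjoint regions.

Top-K selection then takes either the K highest peak scores (-log10 p) or,
for union peaks, the K best mean per-individual score ranks, which keeps a
single individual's outlier p-values from dominating the ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DisjointIntervals, GenomicInterval, OverlapIndex, merge_union


@dataclass(frozen=True)
class ScoredPeak:
    """A peak call: interval + significance score (-log10 p) + sample label."""

    interval: GenomicInterval
    score: float
    sample: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.score) or self.score < 0:
            raise ValueError(f"peak score must be finite and >= 0, got {self.score}")


@dataclass
class PeakCollection:
    peaks: list[ScoredPeak]
    provenance: str = "raw"  # {replicate-supported | union | raw}
    group: str = ""
    # for union collections: per-region {sample: best contributing score}
    contributors: list[dict[str, float]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.peaks):
            row = {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "score": p.score,
                "sample": p.sample,
            }
            if self.contributors is not None:
                row["n_contributors"] = len(self.contributors[i])
                row["contributors"] = ",".join(sorted(self.contributors[i]))
            rows.append(row)
        df = pd.DataFrame(rows)
        df.attrs["provenance"] = self.provenance
        return df


def representative_peaks_replicates(
    pooled: list[ScoredPeak],
    replicate_sets: list[list[ScoredPeak]],
    min_support: int = 2,
) -> PeakCollection:
    """Pooled peaks overlapping (>=1 bp) peaks of >= ``min_support`` replicates.

    Pooled peak coordinates are retained unchanged.
    """
    if min_support > len(replicate_sets):
        raise ValueError(
            f"min_support={min_support} exceeds number of replicate sets "
            f"({len(replicate_sets)})"
        )
    if len(replicate_sets) < 2:
        raise ValueError("need at least 2 replicate sets")
    rep_indexes = [DisjointIntervals([p.interval for p in reps]) for reps in replicate_sets]
    kept = []
    for peak in pooled:
        support = sum(1 for idx in rep_indexes if idx.overlaps(peak.interval))
        if support >= min_support:
            kept.append(peak)
    return PeakCollection(kept, provenance="replicate-supported")


def representative_peaks_union(peak_sets: list[list[ScoredPeak]]) -> PeakCollection:
    """Disjoint union regions across individuals.

    Each region records the contributing samples and each contributor's best
    (max) score; the region's own score is the best score over contributors.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    all_peaks = [p for ps in peak_sets for p in ps]
    regions = merge_union([p.interval for p in all_peaks])
    index = OverlapIndex(regions)
    contributors: list[dict[str, float]] = [{} for _ in regions]
    for peak in all_peaks:
        hits = index.query(peak.interval)
        # merged regions are disjoint and cover every input peak entirely
        (ri,) = hits
        best = contributors[ri].get(peak.sample)
        if best is None or peak.score > best:
            contributors[ri][peak.sample] = peak.score
    peaks = [
        ScoredPeak(region, max(contrib.values()), "union")
        for region, contrib in zip(regions, contributors)
    ]
    return PeakCollection(peaks, provenance="union", contributors=contributors)


def merge_collections(*collections: PeakCollection) -> list[ScoredPeak]:
    """Disjoint union of several collections' regions (best score retained)."""
    all_peaks = [p for c in collections for p in c.peaks]
    regions = merge_union([p.interval for p in all_peaks])
    index = OverlapIndex(regions)
    best = [0.0] * len(regions)
    for p in all_peaks:
        (ri,) = index.query(p.interval)
        best[ri] = max(best[ri], p.score)
    return [ScoredPeak(r, s, "merged") for r, s in zip(regions, best)]


def top_k_by_significance(collection: PeakCollection, k: int = 50_000) -> PeakCollection:
    """K highest-score peaks; boundary ties broken by (chrom, start)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(len(collection.peaks)),
        key=lambda i: (
            -collection.peaks[i].score,
            collection.peaks[i].interval.chrom,
            collection.peaks[i].interval.start,
        ),
    )
    sel = order[:k]
    contrib = (
        [collection.contributors[i] for i in sel]
        if collection.contributors is not None
        else None
    )
    return PeakCollection(
        [collection.peaks[i] for i in sel],
        provenance=collection.provenance,
        group=collection.group,
        contributors=contrib,
    )


def rank_average_table(
    union_peaks: PeakCollection, per_individual_sets: list[list[ScoredPeak]]
) -> pd.DataFrame:
    """Per-union-region score ranks for each individual.

    Within an individual, peaks are ranked by descending score (rank 1 = most
    significant; ties share positions by stable (chrom, start) order).  A
    union region receives the rank of the individual's most significant
    overlapping peak, or (peak count + 1) when the individual has no peak
    there — a penalty that keeps non-shared regions without letting them win.
    """
    n_regions = len(union_peaks.peaks)
    region_index = OverlapIndex(union_peaks.intervals())
    ranks = np.zeros((n_regions, len(per_individual_sets)))
    for j, peaks in enumerate(per_individual_sets):
        if not peaks:
            raise ValueError(f"individual set {j} is empty")
        order = sorted(
            range(len(peaks)),
            key=lambda i: (-peaks[i].score, peaks[i].interval.chrom, peaks[i].interval.start),
        )
        rank_of = np.empty(len(peaks), dtype=np.int64)
        rank_of[order] = np.arange(1, len(peaks) + 1)
        worst = len(peaks) + 1
        best_rank = np.full(n_regions, worst, dtype=np.int64)
        for i, peak in enumerate(peaks):
            for ri in region_index.query(peak.interval):
                if rank_of[i] < best_rank[ri]:
                    best_rank[ri] = rank_of[i]
        ranks[:, j] = best_rank
    df = pd.DataFrame(
        ranks, columns=[f"individual_{j + 1}" for j in range(len(per_individual_sets))]
    )
    df["mean_rank"] = ranks.mean(axis=1)
    return df


def top_k_by_rank_average(
    union_peaks: PeakCollection,
    per_individual_sets: list[list[ScoredPeak]],
    k: int = 50_000,
) -> PeakCollection:
    """Union regions with the K best (smallest) mean per-individual ranks."""
    if k < 1:
        raise ValueError("k must be >= 1")
    table = rank_average_table(union_peaks, per_individual_sets)
    mean_rank = table["mean_rank"].to_numpy()
    order = sorted(
        range(len(union_peaks.peaks)),
        key=lambda i: (
            mean_rank[i],
            union_peaks.peaks[i].interval.chrom,
            union_peaks.peaks[i].interval.start,
        ),
    )
    sel = order[:k]
    contrib = (
        [union_peaks.contributors[i] for i in sel]
        if union_peaks.contributors is not None
        else None
    )
    return PeakCollection(
        [union_peaks.peaks[i] for i in sel],
        provenance=union_peaks.provenance,
        group=union_peaks.group,
        contributors=contrib,
    )


def count_insertions_in_peaks(
    insertions: dict[str, dict[str, np.ndarray]],
    peaks: PeakCollection,
) -> pd.DataFrame:
    """Counts matrix: rows = peaks, columns = samples.

    ``insertions`` maps sample -> chrom -> array of 0-based insertion
    positions.  A position counts for a peak under half-open containment.
    Overlapping peaks each receive positions falling inside them.
    """
    index = OverlapIndex(peaks.intervals())
    n = len(peaks.peaks)
    samples = list(insertions)
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    # disjoint peak sets (the common case) admit a vectorized assignment
    disjoint = DisjointIntervals(peaks.intervals())
    is_disjoint = disjoint.total_bp == sum(len(iv) for iv in peaks.intervals())
    if is_disjoint:
        # sorted per-chrom peak arrays admit a vectorized searchsorted lookup
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in {p.interval.chrom for p in peaks.peaks}:
            ids = np.array(
                [i for i, p in enumerate(peaks.peaks) if p.interval.chrom == chrom]
            )
            starts = np.array([peaks.peaks[i].interval.start for i in ids])
            ends = np.array([peaks.peaks[i].interval.end for i in ids])
            order = np.argsort(starts, kind="stable")
            by_chrom[chrom] = (starts[order], ends[order], ids[order])
        for j, sample in enumerate(samples):
            for chrom, pos in insertions[sample].items():
                if chrom not in by_chrom:
                    continue
                pos = np.asarray(pos, dtype=np.int64)
                starts, ends, ids = by_chrom[chrom]
                loc = np.searchsorted(starts, pos, side="right") - 1
                ok = (loc >= 0) & (pos < ends[np.clip(loc, 0, None)])
                np.add.at(counts[:, j], ids[loc[ok]], 1)
    else:
        for j, sample in enumerate(samples):
            for chrom, pos in insertions[sample].items():
                for p in np.asarray(pos, dtype=np.int64):
                    for i in index.query(GenomicInterval(chrom, int(p), int(p) + 1)):
                        counts[i, j] += 1
    peak_ids = [
        f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}" for p in peaks.peaks
    ]
    return pd.DataFrame(counts, index=peak_ids, columns=samples)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (library-size normalization).

    Uses rows with all-positive counts as the reference set; a sample whose
    factor is undefined (all-zero column) raises.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        bad = counts.columns[mat.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}; size factor undefined")
    positive = (mat > 0).all(axis=1)
    if positive.any():
        log_geo = np.log(mat[positive]).mean(axis=1)
        sf = np.exp(np.median(np.log(mat[positive]) - log_geo[:, None], axis=0))
    else:
        # no reference rows (e.g. disjoint sample groups): total-count factors
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.log(totals).mean())
    return pd.Series(sf, index=counts.columns, name="size_factor")


def sample_similarity_pca(
    counts: pd.DataFrame, n_components: int = 2, top_variable: int = 5000
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of log-normalized counts restricted to the most variable peaks.

    Normalization: median-of-ratios size factors, then log2(count/sf + 1) —
    a fully specified stand-in for regularized-log variance stabilization.
    Returns per-sample component coordinates and variance-explained fractions.
    """
    from sklearn.decomposition import PCA

    if counts.shape[1] < 2 or counts.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 peaks")
    sf = size_factors(counts)
    x = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    variances = x.var(axis=1)
    keep = np.argsort(-variances, kind="stable")[: min(top_variable, x.shape[0])]
    x = x[keep]
    n_components = min(n_components, counts.shape[1], x.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x.T)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=counts.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
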