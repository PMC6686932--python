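"""Matched-control enrichment of GWAS variants in peak sets.

The procedure mirrors the GREGOR-style design: GWAS lead variants are LD
clumped (r² > 0.2 within 1 Mb of a more significant lead removed), expanded
into loci of LD proxies (r² > 0.8 within 1 Mb), and compared against control
variants matched on LD-proxy count, minor-allele frequency, and distance to
the nearest TSS.  A locus "overlaps" a peak set when any member variant
falls inside a peak.  With per-locus control overlap probabilities p_i, the
observed overlap count is tested against the exact Poisson-binomial upper
tail, and the enrichment magnitude is summarized as

    z = (observed - expected) / sd,   expected = sum p_i,
                                      sd = sqrt(sum p_i (1 - p_i)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DisjointIntervals, GenomicInterval
from .peaks import PeakCollection

MB = 1_000_000

#: fixed proxy-count bins: 0, 1, 2, 3-5, 6-10, >10
PROXY_BIN_EDGES = (0, 1, 2, 3, 6, 11)
MAF_BIN_WIDTH = 0.02
N_TSS_BINS = 10


class UnmatchableLocusError(ValueError):
    """No control variant shares the lead's matching bins."""


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based internal (readers convert from 1-based)
    id: str
    maf: float
    tss_distance: int = 0
    p: float | None = None
    traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


class LdTable:
    """Symmetric pairwise r² restricted to pairs within 1 Mb."""

    def __init__(self, pairs: list[tuple[str, str, float]] | None = None):
        self._neighbors: dict[str, dict[str, float]] = {}
        for a, b, r2 in pairs or []:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1]")
        if a == b:
            return
        self._neighbors.setdefault(a, {})[b] = r2
        self._neighbors.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._neighbors.get(a, {}).get(b, 0.0)

    def neighbors(self, vid: str) -> dict[str, float]:
        return self._neighbors.get(vid, {})

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame, positions: dict[str, tuple[str, int]],
                     window: int = MB, r2_min: float = 0.0) -> "LdTable":
        """r² as squared Pearson correlation of dosage columns (variants)."""
        table = cls()
        ids = list(dosages.columns)
        mat = dosages.to_numpy(dtype=float)
        std = mat.std(axis=0)
        centered = mat - mat.mean(axis=0)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ci, pi = positions[ids[i]]
                cj, pj = positions[ids[j]]
                if ci != cj or abs(pi - pj) > window:
                    continue
                if std[i] == 0 or std[j] == 0:
                    continue
                r = (centered[:, i] * centered[:, j]).mean() / (std[i] * std[j])
                if r * r >= r2_min:
                    table.add(ids[i], ids[j], float(r * r))
        return table


@dataclass
class LocusSet:
    lead: Variant
    proxies: list[Variant] = field(default_factory=list)

    @property
    def members(self) -> list[Variant]:
        return [self.lead, *self.proxies]

    def __len__(self) -> int:
        return 1 + len(self.proxies)


@dataclass
class EnrichmentResult:
    trait: str
    peak_label: str
    n_loci: int
    observed: int
    expected: float
    sd: float
    p: float
    z: float


def ld_clump(
    leads: list[Variant], ld: LdTable, r2_max: float = 0.2, window: int = MB
) -> list[Variant]:
    """Greedy pruning: iterate by ascending p; drop leads in moderate LD
    (r² > r2_max) with a retained, more significant lead within ``window``.

    Exact p ties keep the earlier variant in (p, chrom, pos) stable order.
    """
    order = sorted(range(len(leads)),
                   key=lambda i: (leads[i].p if leads[i].p is not None else 0.0,
                                  leads[i].chrom, leads[i].pos))
    kept: list[Variant] = []
    for i in order:
        v = leads[i]
        drop = any(
            k.chrom == v.chrom
            and abs(k.pos - v.pos) <= window
            and ld.r2(k.id, v.id) > r2_max
            for k in kept
        )
        if not drop:
            kept.append(v)
    return kept


def expand_proxies(
    leads: list[Variant],
    pool_by_id: dict[str, Variant],
    ld: LdTable,
    r2_min: float = 0.8,
    window: int = MB,
) -> list[LocusSet]:
    """Each lead plus every variant with r² > r2_min within ``window``."""
    out = []
    for lead in leads:
        proxies = []
        for other_id, r2 in sorted(ld.neighbors(lead.id).items()):
            if r2 <= r2_min or other_id == lead.id:
                continue
            other = pool_by_id.get(other_id)
            if other is None:
                continue
            if other.chrom == lead.chrom and abs(other.pos - lead.pos) <= window:
                proxies.append(other)
        out.append(LocusSet(lead, proxies))
    return out


def proxy_count(variant: Variant, ld: LdTable, r2_min: float = 0.8,
                window: int = MB, pool_by_id: dict[str, Variant] | None = None) -> int:
    n = 0
    for other_id, r2 in ld.neighbors(variant.id).items():
        if r2 <= r2_min:
            continue
        if pool_by_id is not None:
            other = pool_by_id.get(other_id)
            if other is None or other.chrom != variant.chrom or abs(other.pos - variant.pos) > window:
                continue
        n += 1
    return n


def _proxy_bin(n: int) -> int:
    return int(np.searchsorted(PROXY_BIN_EDGES, n, side="right") - 1)


class ControlMatcher:
    """Bins the control pool by (proxy count, MAF, TSS distance) for matching.

    Bin definitions: proxy-count bins {0, 1, 2, 3-5, 6-10, >10}; MAF bins of
    width 0.02; TSS-distance bins at pool deciles.  An empty matching cell is
    retried once with the MAF bin widened to its immediate neighbors, then
    raises :class:`UnmatchableLocusError`.
    """

    def __init__(self, pool: list[Variant], ld: LdTable,
                 r2_min: float = 0.8, window: int = MB):
        self.pool = list(pool)
        self.by_id = {v.id: v for v in self.pool}
        self.ld = ld
        self.r2_min = r2_min
        self.window = window
        tss = np.array([abs(v.tss_distance) for v in self.pool])
        self.tss_edges = np.quantile(tss, np.linspace(0, 1, N_TSS_BINS + 1))[1:-1]
        self._proxy_counts = np.array(
            [proxy_count(v, ld, r2_min, window, self.by_id) for v in self.pool]
        )
        self._cells: dict[tuple[int, int, int], np.ndarray] = {}
        keys = [self.bins_of(v, int(self._proxy_counts[i]))
                for i, v in enumerate(self.pool)]
        cell_lists: dict[tuple[int, int, int], list[int]] = {}
        for i, key in enumerate(keys):
            cell_lists.setdefault(key, []).append(i)
        self._cells = {k: np.array(v) for k, v in cell_lists.items()}
        self._keys = keys

    def cell_sizes(self) -> np.ndarray:
        """Size of each pool variant's own matching cell."""
        return np.array([self._cells[k].size for k in self._keys])

    def bins_of(self, v: Variant, n_proxies: int) -> tuple[int, int, int]:
        maf_bin = int(v.maf / MAF_BIN_WIDTH)
        tss_bin = int(np.searchsorted(self.tss_edges, abs(v.tss_distance), side="right"))
        return (_proxy_bin(n_proxies), maf_bin, tss_bin)

    def candidates(self, lead: Variant, n_proxies: int | None = None,
                   exclude: set[str] | None = None) -> np.ndarray:
        if n_proxies is None:
            n_proxies = proxy_count(lead, self.ld, self.r2_min, self.window, self.by_id)
        pb, mb, tb = self.bins_of(lead, n_proxies)
        idx = self._cells.get((pb, mb, tb), np.empty(0, dtype=int))
        if exclude:
            idx = idx[[self.pool[i].id not in exclude for i in idx]] if idx.size else idx
        if idx.size:
            return idx
        # widen the MAF bin once to its immediate neighbors
        widened = [
            j for m in (mb - 1, mb, mb + 1)
            for j in self._cells.get((pb, m, tb), np.empty(0, dtype=int))
        ]
        idx = np.array(sorted(set(widened)), dtype=int)
        if exclude and idx.size:
            idx = idx[[self.pool[i].id not in exclude for i in idx]]
        if idx.size == 0:
            raise UnmatchableLocusError(
                f"unmatchable locus {lead.id}: no pool variant in proxy bin {pb}, "
                f"MAF bin {mb}+/-1, TSS bin {tb}"
            )
        return idx

    def match_controls(self, locus: LocusSet, n: int,
                       rng: np.random.Generator) -> list[LocusSet]:
        """``n`` control loci (without replacement; capped at cell size)."""
        exclude = {v.id for v in locus.members}
        idx = self.candidates(locus.lead, len(locus.proxies), exclude)
        take = min(n, idx.size)
        chosen = rng.choice(idx, size=take, replace=False)
        return [
            expand_proxies([self.pool[i]], self.by_id, self.ld,
                           self.r2_min, self.window)[0]
            for i in chosen
        ]

    def locus_overlap_flags(self, peaks: PeakCollection) -> np.ndarray:
        """For each pool variant: does its locus (self + proxies) hit a peak?"""
        merged = DisjointIntervals(peaks.intervals())
        in_peak = np.array(
            [merged.contains_positions(v.chrom, np.array([v.pos]))[0] for v in self.pool]
        )
        pos_of = {v.id: i for i, v in enumerate(self.pool)}
        flags = in_peak.copy()
        for i, v in enumerate(self.pool):
            if flags[i]:
                continue
            for other_id, r2 in self.ld.neighbors(v.id).items():
                if r2 <= self.r2_min:
                    continue
                j = pos_of.get(other_id)
                if j is None:
                    continue
                other = self.pool[j]
                if other.chrom == v.chrom and abs(other.pos - v.pos) <= self.window:
                    if in_peak[j]:
                        flags[i] = True
                        break
        return flags


def locus_overlaps(locus: LocusSet, peaks: PeakCollection) -> bool:
    merged = DisjointIntervals(peaks.intervals())
    return any(
        merged.contains_positions(v.chrom, np.array([v.pos]))[0] for v in locus.members
    )


def poisson_binomial_pmf(ps: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by convolution DP."""
    pmf = np.array([1.0])
    for p in np.asarray(ps, dtype=float):
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def poisson_binomial_tail(ps: np.ndarray, k: int) -> float:
    """P(X >= k) for the Poisson-binomial count X."""
    if k <= 0:
        return 1.0
    pmf = poisson_binomial_pmf(ps)
    if k >= pmf.size:
        return 0.0
    return float(np.clip(pmf[k:].sum(), 0.0, 1.0))


def enrichment_test(
    loci: list[LocusSet],
    peaks: PeakCollection,
    matcher: ControlMatcher,
    n_control_sets: int = 500,
    rng: np.random.Generator | int = 0,
    trait: str = "",
    peak_label: str = "",
    overlap_flags: np.ndarray | None = None,
) -> EnrichmentResult:
    """Matched-control enrichment of GWAS loci in a peak set.

    Per-locus control overlap probabilities are Monte-Carlo estimates over
    ``n_control_sets`` matched control loci (seeded, without replacement).
    Each locus draws from its own generator derived from the base seed and
    a stable hash of its lead id, so the result does not depend on locus
    order.  ``overlap_flags`` may carry precomputed pool-wide locus-overlap
    flags (from :meth:`ControlMatcher.locus_overlap_flags`) to amortize
    repeated tests against the same peak set.
    """
    import zlib

    if not loci:
        raise ValueError("need at least one locus")
    if isinstance(rng, np.random.Generator):
        base_seed = int(rng.integers(2**31))
    else:
        base_seed = int(rng)
    if overlap_flags is None:
        overlap_flags = matcher.locus_overlap_flags(peaks)
    merged = DisjointIntervals(peaks.intervals())
    observed = 0
    p_i = np.empty(len(loci))
    for li, locus in enumerate(loci):
        if any(merged.contains_positions(v.chrom, np.array([v.pos]))[0]
               for v in locus.members):
            observed += 1
        exclude = {v.id for v in locus.members}
        idx = matcher.candidates(locus.lead, len(locus.proxies), exclude)
        take = min(n_control_sets, idx.size)
        locus_rng = np.random.default_rng(
            (base_seed, zlib.crc32(locus.lead.id.encode()))
        )
        chosen = locus_rng.choice(idx, size=take, replace=False)
        p_i[li] = overlap_flags[chosen].mean()
    expected = float(p_i.sum())
    sd = float(np.sqrt((p_i * (1.0 - p_i)).sum()))
    if sd == 0.0:
        # degenerate null: every p_i is 0 or 1, so X == expected surely
        z = 0.0 if observed == expected else float(np.sign(observed - expected) * np.inf)
        p = 1.0 if observed <= expected else 0.0
    else:
        p = poisson_binomial_tail(p_i, observed)
        z = (observed - expected) / sd
    return EnrichmentResult(
        trait=trait, peak_label=peak_label, n_loci=len(loci),
        observed=observed, expected=expected, sd=sd, p=float(p), z=float(z),
    )


def bonferroni_call(
    results: list[EnrichmentResult], alpha: float = 0.05, n_traits: int = 11
) -> pd.DataFrame:
    """Significance flags at the Bonferroni-corrected threshold alpha/n_traits."""
    thr = alpha / n_traits
    rows = [
        {
            "trait": r.trait, "peak_label": r.peak_label, "n_loci": r.n_loci,
            "observed": r.observed, "expected": r.expected, "sd": r.sd,
            "p": r.p, "z": r.z, "significant": r.p < thr,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df.attrs["threshold"] = thr
    return df


def report_variant_peak_overlap(
    loci: list[LocusSet], peak_collections: dict[str, PeakCollection]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus variant-in-peak table plus a per-locus summary.

    Rows: one per (locus, variant) with the labels of peak sets hit.  Loci
    where exactly one member variant overlaps any peak set are flagged
    single-candidate in the summary.
    """
    merged = {label: DisjointIntervals(pc.intervals())
              for label, pc in peak_collections.items()}
    rows = []
    summary = []
    for locus in loci:
        n_overlapping = 0
        for v in locus.members:
            hits = [label for label, d in merged.items()
                    if d.contains_positions(v.chrom, np.array([v.pos]))[0]]
            if hits:
                n_overlapping += 1
                rows.append({
                    "locus": locus.lead.id,
                    "variant": v.id,
                    "chrom": v.chrom,
                    "pos_1based": v.pos + 1,
                    "peak_sets": ",".join(sorted(hits)),
                    "total_variants_at_locus": len(locus),
                })
        summary.append({
            "locus": locus.lead.id,
            "total_variants": len(locus),
            "variants_in_peaks": n_overlapping,
            "single_candidate": n_overlapping == 1,
        })
    return pd.DataFrame(rows), pd.DataFrame(summary)
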