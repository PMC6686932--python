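"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a pipeline quantity the slow, obvious way
(per-base marking, all-pairs scans, full enumeration) without touching the
implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def covered_bases(intervals) -> int:
    """Per-base boolean-marking count of distinct covered bases."""
    marked: set[tuple[str, int]] = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            marked.add((iv.chrom, p))
    return len(marked)


def pairwise_overlap_bp(a, b) -> int:
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def replicate_supported(pooled, replicate_sets, min_support) -> list[int]:
    """Indices of pooled peaks supported by >= min_support replicates (all-pairs)."""
    kept = []
    for i, peak in enumerate(pooled):
        support = 0
        for reps in replicate_sets:
            if any(pairwise_overlap_bp(peak.interval, r.interval) > 0 for r in reps):
                support += 1
        if support >= min_support:
            kept.append(i)
    return kept


def rank_table(union_intervals, per_individual_sets) -> np.ndarray:
    """Brute-force per-region per-individual best rank with worst+1 penalty."""
    n = len(union_intervals)
    table = np.zeros((n, len(per_individual_sets)))
    for j, peaks in enumerate(per_individual_sets):
        order = sorted(
            range(len(peaks)),
            key=lambda i: (-peaks[i].score, peaks[i].interval.chrom,
                           peaks[i].interval.start),
        )
        rank = {}
        for r, i in enumerate(order, start=1):
            rank[i] = r
        for ri, region in enumerate(union_intervals):
            best = len(peaks) + 1
            for i, p in enumerate(peaks):
                if pairwise_overlap_bp(region, p.interval) > 0:
                    best = min(best, rank[i])
            table[ri, j] = best
    return table


def genic_category(peak, genes) -> str:
    """Direct evaluation of the four category tests in precedence order."""
    def win_overlap(iv):
        return pairwise_overlap_bp(peak, iv) > 0

    for g in genes:
        if win_overlap(g.tss_window):
            return "TSS-proximal"
    for g in genes:
        if win_overlap(g.body):
            return "intragenic"
    for g in genes:
        if win_overlap(g.tts_window):
            return "downstream"
    return "distal"


def state_overlap_per_base(peak_intervals, segments) -> dict[str, int]:
    """Label every peak base by a double loop over segments."""
    bases: set[tuple[str, int]] = set()
    for iv in peak_intervals:
        for p in range(iv.start, iv.end):
            bases.add((iv.chrom, p))
    out: dict[str, int] = {}
    for iv, label in segments:
        hits = sum(1 for p in range(iv.start, iv.end) if (iv.chrom, p) in bases)
        out[label] = out.get(label, 0) + hits
    return out


def scan_windows(seq: str, log_odds: np.ndarray, threshold: float):
    """Exhaustive per-window rescoring on both strands.

    Returns (start, strand, score) tuples; windows containing non-ACGT
    symbols are skipped.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    length = log_odds.shape[0]
    out = []
    for i in range(len(seq) - length + 1):
        window = seq[i : i + length].upper()
        if any(c not in code for c in window):
            continue
        fwd = sum(log_odds[j, code[c]] for j, c in enumerate(window))
        rc = "".join(comp[c] for c in reversed(window))
        rev = sum(log_odds[j, code[c]] for j, c in enumerate(rc))
        if fwd >= threshold:
            out.append((i, "+", fwd))
        if rev >= threshold:
            out.append((i, "-", rev))
    return out


def greedy_clump(leads, ld, r2_max, window) -> list[str]:
    """Explicit greedy-by-p pruning; returns retained variant ids."""
    remaining = sorted(leads, key=lambda v: (v.p, v.chrom, v.pos))
    kept = []
    for v in remaining:
        ok = True
        for k in kept:
            if (k.chrom == v.chrom and abs(k.pos - v.pos) <= window
                    and ld.r2(k.id, v.id) > r2_max):
                ok = False
                break
        if ok:
            kept.append(v)
    return [v.id for v in kept]


def proxies_by_pair_scan(lead, pool, ld, r2_min, window) -> set[str]:
    out = set()
    for v in pool:
        if v.id == lead.id:
            continue
        if (v.chrom == lead.chrom and abs(v.pos - lead.pos) <= window
                and ld.r2(lead.id, v.id) > r2_min):
            out.add(v.id)
    return out


def poisson_binomial_enumeration(ps, k) -> float:
    """P(X >= k) by full 2^n outcome enumeration."""
    total = 0.0
    n = len(ps)
    for outcome in itertools.product([0, 1], repeat=n):
        prob = 1.0
        for o, p in zip(outcome, ps):
            prob *= p if o else (1 - p)
        if sum(outcome) >= k:
            total += prob
    return total


def betabinom_logpmf_direct(k: int, n: int, pi: float, rho: float) -> float:
    """Beta-function pmf evaluated with lgamma, independent of scipy."""
    a = pi * (1 - rho) / rho
    b = (1 - pi) * (1 - rho) / rho
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + math.lgamma(k + a) + math.lgamma(n - k + b) - math.lgamma(n + a + b)
        + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
    )


def binomial_two_tailed(k: int, n: int, p: float = 0.5) -> float:
    """Doubled smaller exact binomial tail, capped at 1."""
    def pmf(j):
        return math.comb(n, j) * p**j * (1 - p) ** (n - j)

    lower = sum(pmf(j) for j in range(0, k + 1))
    upper = sum(pmf(j) for j in range(k, n + 1))
    return min(1.0, 2.0 * min(lower, upper))
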