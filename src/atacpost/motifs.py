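"""PWM scanning, occurrence deduplication, dinucleotide shuffling, enrichment.

Scanning is a plain log-odds threshold scan: every window on either strand
scoring at or above the threshold is reported.  The default threshold is a
fraction (80%) of the motif's maximum attainable log-odds score, which gives
an occurrence set without any per-site p-value machinery.  Enrichment of a
motif in foreground vs background sequences is a one-sided Fisher exact test
on the "sequence has >= 1 occurrence" 2x2 table, Bonferroni-style corrected
into an E-value across the number of motifs tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core import GenomicInterval

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix with background, in log-odds form on demand."""

    motif_id: str
    matrix: np.ndarray  # (length, 4) probabilities over A,C,G,T
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if len(self) < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Counts -> probabilities with a per-cell pseudocount."""
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        return cls(motif_id, probs, background)

    @property
    def log_odds(self) -> np.ndarray:
        """log2 odds vs background, with a floor to keep zeros finite."""
        p = np.clip(self.matrix, 1e-9, None)
        return np.log2(p / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def default_threshold(self, fraction: float = 0.8) -> float:
        """Log-odds threshold at a fraction of the maximum attainable score."""
        return fraction * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complemented(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(), self.background)


@dataclass(frozen=True)
class MotifOccurrence:
    interval: GenomicInterval  # stranded, length == PWM length
    motif_id: str
    score: float
    haplotype: int | None = None


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; any other symbol (N) -> 4."""
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing N get -inf."""
    length = log_odds.shape[0]
    n_win = codes.size - length + 1
    if n_win <= 0:
        return np.empty(0)
    lo = np.vstack([log_odds, np.full((1, 4), np.nan)])  # row 4 marks N
    padded = np.hstack([lo, np.full((length + 1, 1), np.nan)])
    scores = np.zeros(n_win)
    for j in range(length):
        scores += padded[j, codes[j : j + n_win]]
    scores[np.isnan(scores)] = -np.inf
    return scores


def pwm_scan(
    sequence: str,
    pwm: PWM,
    threshold: float | None = None,
    chrom: str = "seq",
    origin: int = 0,
    haplotype: int | None = None,
) -> list[MotifOccurrence]:
    """All windows on both strands with log-odds >= threshold.

    A minus-strand occurrence is reported at the genomic window where the
    reverse complement of the window matches the motif.
    """
    if threshold is None:
        threshold = pwm.default_threshold()
    length = len(pwm)
    if len(sequence) < length:
        return []
    codes = encode(sequence)
    out: list[MotifOccurrence] = []
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complemented().log_odds)):
        scores = _window_scores(codes, lo)
        for i in np.flatnonzero(scores >= threshold):
            out.append(
                MotifOccurrence(
                    GenomicInterval(chrom, origin + int(i), origin + int(i) + length, strand),
                    pwm.motif_id,
                    float(scores[i]),
                    haplotype,
                )
            )
    out.sort(key=lambda o: (o.interval.start, o.interval.strand))
    return out


def dedup_same_coordinates(occs: list[MotifOccurrence]) -> list[MotifOccurrence]:
    """Keep the best-scoring occurrence per (motif, coordinates, strand).

    Ties keep the occurrence from the lowest-numbered haplotype (haplotype 1
    when two haplotypes score equally); occurrences at different strands or
    coordinates are all kept.  Input order is preserved.
    """
    best: dict[tuple, MotifOccurrence] = {}
    order: list[tuple] = []
    for occ in occs:
        key = (occ.motif_id, occ.interval.chrom, occ.interval.start,
               occ.interval.end, occ.interval.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = occ
            order.append(key)
        else:
            hap_cur = cur.haplotype if cur.haplotype is not None else 0
            hap_new = occ.haplotype if occ.haplotype is not None else 0
            if occ.score > cur.score or (occ.score == cur.score and hap_new < hap_cur):
                best[key] = occ
    return [best[k] for k in order]


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving the exact dinucleotide counts.

    Builds the multigraph whose edges are the sequence's adjacent pairs,
    fixes a uniformly random last-exit edge per vertex that forms a spanning
    arborescence into the final symbol, permutes the remaining exits, and
    walks the resulting Eulerian path.  First and last symbols are unchanged.
    """
    if len(sequence) < 2:
        return sequence
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = sequence.upper()
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    def reaches_last(last_edge: dict[str, str]) -> bool:
        for v in vertices:
            if v == last or not edges[v]:
                continue
            seen, cur = set(), v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    return False
                seen.add(cur)
                cur = last_edge[cur]
        return True

    non_terminal = [v for v in vertices if v != last and edges[v]]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        if reaches_last(last_edge):
            break

    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        perm = rng.permutation(len(pool))
        ordered = [pool[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        walk_lists[v] = ordered

    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


@dataclass
class EnrichmentFisher:
    motif_id: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    odds_ratio: float
    p: float
    e_value: float
    significant: bool


def motif_enrichment_fisher(
    fg: list[str],
    bg: list[str],
    pwm: PWM,
    threshold: float | None = None,
    n_motifs_tested: int = 1,
    e_threshold: float = 1e-100,
) -> EnrichmentFisher:
    """One-sided (enrichment) Fisher exact test on per-sequence motif presence.

    The E-value is p times the number of motifs tested; significance uses
    ``e_threshold`` (default the conventional 1e-100 cutoff).
    The odds ratio uses a Haldane–Anscombe +0.5 correction only when a cell
    is zero; the p-value is always exact.
    """
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if threshold is None:
        threshold = pwm.default_threshold()
    fg_hits = sum(1 for s in fg if pwm_scan(s, pwm, threshold))
    bg_hits = sum(1 for s in bg if pwm_scan(s, pwm, threshold))
    table = [[fg_hits, len(fg) - fg_hits], [bg_hits, len(bg) - bg_hits]]
    _, p = stats.fisher_exact(table, alternative="greater")
    a, b, c, d = fg_hits, len(fg) - fg_hits, bg_hits, len(bg) - bg_hits
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    e_value = p * n_motifs_tested
    return EnrichmentFisher(
        pwm.motif_id, fg_hits, len(fg), bg_hits, len(bg),
        float(odds), float(p), float(e_value), bool(e_value < e_threshold),
    )


def read_pfms(path: str | Path, fmt: str = "jaspar",
              pseudocount: float = 0.25) -> list[PWM]:
    """Read JASPAR (``fmt='jaspar'``) or MEME minimal (``fmt='minimal'``) PFMs."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, fmt)
    out = []
    for rec in records:
        counts = np.array([[rec.counts[base][i] for base in ALPHABET]
                           for i in range(rec.length)])
        name = rec.matrix_id if getattr(rec, "matrix_id", None) else rec.name
        out.append(PWM.from_counts(name, counts, pseudocount=pseudocount))
    return out
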