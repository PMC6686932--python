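"""Genic-context classification and chromatin-state overlap.

Peaks are placed into exactly one of four genic categories with a fixed
precedence (TSS-proximal > intragenic > downstream > distal), and peak bases
are tallied against 18-state chromatin segmentations, optionally merged into
combined labels (promoter / transcribed / enhancer / polycomb-repressed /
other) before cross-epigenome ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import DisjointIntervals, GenomicInterval
from .peaks import PeakCollection

TSS_UPSTREAM = 5000
TSS_DOWNSTREAM = 1000
TTS_DOWNSTREAM = 5000

CATEGORIES = ("TSS-proximal", "intragenic", "downstream", "distal")

#: 18-state mnemonics -> combined label
ROADMAP18_COMBINED: dict[str, str] = {
    "1_TssA": "promoter",
    "2_TssFlnk": "promoter",
    "3_TssFlnkU": "promoter",
    "4_TssFlnkD": "promoter",
    "14_TssBiv": "promoter",
    "5_Tx": "transcribed",
    "6_TxWk": "transcribed",
    "7_EnhG1": "enhancer",
    "8_EnhG2": "enhancer",
    "9_EnhA1": "enhancer",
    "10_EnhA2": "enhancer",
    "11_EnhWk": "enhancer",
    "15_EnhBiv": "enhancer",
    "16_ReprPC": "polycomb-repressed",
    "17_ReprPCWk": "polycomb-repressed",
    "12_ZNF/Rpts": "other",
    "13_Het": "other",
    "18_Quies": "other",
}


@dataclass(frozen=True)
class GeneModel:
    """Gene body with strand; TSS/TTS derive from strand orientation."""

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss_window(self) -> GenomicInterval:
        """Strand-aware promoter window: 5 kb upstream to 1 kb downstream of TSS."""
        b = self.body
        if b.strand == "+":
            start, end = b.start - TSS_UPSTREAM, b.start + TSS_DOWNSTREAM
        else:
            start, end = b.end - TSS_DOWNSTREAM, b.end + TSS_UPSTREAM
        return GenomicInterval(b.chrom, max(0, start), end, b.strand)

    @property
    def tts_window(self) -> GenomicInterval:
        """Strand-aware window covering 5 kb downstream of the TTS."""
        b = self.body
        if b.strand == "+":
            start, end = b.end, b.end + TTS_DOWNSTREAM
        else:
            start, end = b.start - TTS_DOWNSTREAM, b.start
        return GenomicInterval(b.chrom, max(0, start), max(1, end), b.strand)


@dataclass
class StateSegmentation:
    """Non-overlapping labeled segments for one (reference) epigenome."""

    epigenome: str
    segments: list[tuple[GenomicInterval, str]]

    def labels(self) -> set[str]:
        return {lab for _, lab in self.segments}


class GenicClassifier:
    """Precomputed indexes for classifying many peaks against one gene set."""

    def __init__(self, genes: list[GeneModel]):
        self._tss = DisjointIntervals([g.tss_window for g in genes])
        self._body = DisjointIntervals([g.body for g in genes])
        self._tts = DisjointIntervals([g.tts_window for g in genes])

    def classify(self, peak: GenomicInterval) -> str:
        if self._tss.overlaps(peak):
            return "TSS-proximal"
        if self._body.overlaps(peak):
            return "intragenic"
        if self._tts.overlaps(peak):
            return "downstream"
        return "distal"


def classify_peak_location(peak: GenomicInterval, genes: list[GeneModel]) -> str:
    """One of the four genic categories; precedence as listed in CATEGORIES."""
    return GenicClassifier(genes).classify(peak)


def classify_peaks(peaks: PeakCollection, genes: list[GeneModel]) -> pd.DataFrame:
    clf = GenicClassifier(genes)
    rows = [
        {
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "category": clf.classify(p.interval),
        }
        for p in peaks.peaks
    ]
    return pd.DataFrame(rows)


def combine_states(
    seg: StateSegmentation, mapping: dict[str, str] | None = None
) -> StateSegmentation:
    """Relabel raw mnemonics with combined labels, merging adjacent same-label runs."""
    mapping = ROADMAP18_COMBINED if mapping is None else mapping
    relabeled: list[tuple[GenomicInterval, str]] = []
    for iv, state in sorted(seg.segments, key=lambda t: (t[0].chrom, t[0].start)):
        if state not in mapping:
            raise KeyError(f"unknown state mnemonic {state!r}")
        label = mapping[state]
        if (
            relabeled
            and relabeled[-1][1] == label
            and relabeled[-1][0].chrom == iv.chrom
            and relabeled[-1][0].end == iv.start
        ):
            prev_iv, _ = relabeled[-1]
            relabeled[-1] = (GenomicInterval(iv.chrom, prev_iv.start, iv.end), label)
        else:
            relabeled.append((GenomicInterval(iv.chrom, iv.start, iv.end), label))
    return StateSegmentation(seg.epigenome, relabeled)


def state_overlap_bp(peaks: PeakCollection, seg: StateSegmentation) -> dict[str, int]:
    """Peak bases overlapping each state label.

    Peak bases are counted once (the peak set is merged first), so the total
    across labels never exceeds the distinct peak bases.
    """
    merged_peaks = DisjointIntervals(peaks.intervals())
    out: dict[str, int] = {lab: 0 for lab in seg.labels()}
    for iv, label in seg.segments:
        out[label] += merged_peaks.overlap_bp(iv)
    return out


def state_overlap_table(
    peaks: PeakCollection, segs: list[StateSegmentation]
) -> pd.DataFrame:
    total_bp = DisjointIntervals(peaks.intervals()).total_bp
    rows = []
    for seg in segs:
        for label, bp in sorted(state_overlap_bp(peaks, seg).items()):
            rows.append(
                {
                    "epigenome": seg.epigenome,
                    "label": label,
                    "overlap_bp": bp,
                    "fraction_of_peak_bases": bp / total_bp if total_bp else 0.0,
                }
            )
    return pd.DataFrame(rows)


def rank_epigenomes(
    peaks: PeakCollection, segs: list[StateSegmentation], label: str
) -> pd.DataFrame:
    """Epigenomes ranked by descending peak-base overlap with ``label``.

    Rank 1 = largest overlap; ties share the smaller (best) rank.
    """
    if len(segs) < 2:
        raise ValueError("need >= 2 epigenomes to rank")
    overlaps = {
        seg.epigenome: state_overlap_bp(peaks, seg).get(label, 0) for seg in segs
    }
    values = list(overlaps.values())
    rows = [
        {
            "epigenome": epi,
            "overlap_bp": bp,
            "rank": 1 + sum(1 for v in values if v > bp),
        }
        for epi, bp in overlaps.items()
    ]
    return pd.DataFrame(rows).sort_values(["rank", "epigenome"]).reset_index(drop=True)
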