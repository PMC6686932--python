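"""Readers and writers for the plain-text formats the pipeline exchanges.

BED/narrowPeak intervals stay 0-based half-open end to end.  Variant tables
use 1-based positions on disk (VCF convention) and are converted to 0-based
on read, back to 1-based on write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .core import DisjointIntervals, Genome, GenomicInterval


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chromosome, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6; strand taken from column 6 when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    """BED6 when any interval is stranded or names given, else BED3."""
    intervals = list(intervals)
    stranded = any(iv.strand != "." for iv in intervals) or names is not None
    names = list(names) if names is not None else [f"iv{i}" for i in range(len(intervals))]
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            if stranded:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path: str | Path, sample: str | None = None) -> "list":
    """narrowPeak (BED6+4); column 8 is the -log10 peak p-value used as score."""
    from .peaks import ScoredPeak

    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            label = sample if sample is not None else (p[3].rsplit("_peak", 1)[0] or "sample")
            peaks.append(
                ScoredPeak(
                    interval=GenomicInterval(p[0], int(p[1]), int(p[2])),
                    score=float(p[7]),
                    sample=label,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.sample}_peak_{i + 1}\t0\t.\t"
                f"0\t{pk.score:.6g}\t-1\t-1\n"
            )


def read_genome(
    chrom_sizes: str | Path,
    mappability_bed: str | Path | None = None,
    blacklist_bed: str | Path | None = None,
) -> Genome:
    sizes = read_chrom_sizes(chrom_sizes)
    mapp = DisjointIntervals(read_bed(mappability_bed)) if mappability_bed else None
    blk = DisjointIntervals(read_bed(blacklist_bed)) if blacklist_bed else None
    return Genome(sizes=sizes, mappability=mapp, blacklist=blk)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_insertions(path: str | Path) -> dict[str, "object"]:
    """Tn5 insertion centers as BED3 of 1-bp intervals -> chrom -> sorted positions."""
    import numpy as np

    by_chrom: dict[str, list[int]] = {}
    for iv in read_bed(path):
        by_chrom.setdefault(iv.chrom, []).append(iv.start)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}


def write_insertions(positions: dict[str, "object"], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(positions):
            for pos in positions[chrom]:
                fh.write(f"{chrom}\t{int(pos)}\t{int(pos) + 1}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
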