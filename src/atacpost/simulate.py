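"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline targets: a small set of
tissue "individuals" (3) plus cell-line groups with 2-3 technical
replicates, profiled on a toy genome of two 10-Mb chromosomes so that every
end-to-end run finishes in minutes.  Each generator is a pure function of
(config, seed): a fixed seed reproduces the exact same peaks, insertion
positions, variants, allele counts and sequences, and each generator emits a
truth table sufficient to score the downstream stage without re-simulation.

LD is generated at the block level (r-squared values assigned to
within-block pairs), not by coalescent simulation; that is all the
clumping / proxy-expansion / matched-control logic observes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .core import DisjointIntervals, Genome, GenomicInterval
from .annotate import GeneModel, StateSegmentation
from .ase import HetSiteCount
from .gwas import LdTable, Variant
from .motifs import PWM
from .peaks import ScoredPeak


@dataclass
class SimConfig:
    """Defaults are the study conditions every acceptance run uses."""

    seed: int
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    # peak landscape
    n_shared_regions: int = 400
    n_private_per_sample: int = 60
    peak_width_mean: int = 400
    peak_width_sd: int = 80
    boundary_jitter: int = 50
    share_fraction: float = 0.9
    n_individuals: int = 3
    n_replicates: int = 3
    # insertion-count profiles
    background_rate: float = 2e-5  # events per bp outside peaks
    peak_rate: float = 0.02       # events per bp inside peaks
    footprint_depletion: float = 0.3
    bound_signal_boost: float = 3.0  # extra accessibility at bound motif windows
    # gene models
    n_genes: int = 300
    # chromatin states
    n_epigenomes: int = 10
    planted_enhancer_fraction: float = 0.6
    # LD blocks / variants
    n_blocks: int = 5000
    vars_per_block: int = 6
    block_span: int = 30_000
    proxy_pair_prob: float = 0.5
    moderate_pair_prob: float = 0.25
    maf_low: float = 0.05
    maf_high: float = 0.5
    # allele counts
    n_sites: int = 10_000
    ase_pi: float = 0.5
    ase_rho: float = 0.05
    coverage_low: int = 10
    coverage_high: int = 60
    imbalanced_fraction: float = 0.0
    imbalanced_pi: float = 0.9
    reference_bias: float = 0.0  # added to pi at every site
    # sequences / motif planting
    n_fg_sequences: int = 200
    n_bg_sequences: int = 200
    sequence_length: int = 200
    plant_rate: float = 0.5

    def __post_init__(self) -> None:
        for name in ("share_fraction", "footprint_depletion", "proxy_pair_prob",
                     "moderate_pair_prob", "imbalanced_fraction", "plant_rate",
                     "planted_enhancer_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def genome(self) -> Genome:
        return Genome(sizes=dict(self.chrom_sizes))

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# ---------------------------------------------------------------------------
# peaks


@dataclass
class SimPeaks:
    per_sample: dict[str, list[ScoredPeak]]
    pooled: list[ScoredPeak]
    truth: pd.DataFrame  # region id, coordinates, type, per-sample membership


def _place_regions(cfg: SimConfig, rng: np.random.Generator, n: int,
                   width_mean: int | None = None) -> list[GenomicInterval]:
    """Non-overlapping regions on a jittered grid across the toy genome."""
    width_mean = width_mean or cfg.peak_width_mean
    chroms = list(cfg.chrom_sizes)
    slot = width_mean + 4 * cfg.peak_width_sd + 2 * cfg.boundary_jitter + 200
    slots = []
    for chrom in chroms:
        n_slots = (cfg.chrom_sizes[chrom] - slot) // slot
        slots.extend((chrom, i) for i in range(1, n_slots))
    if n > len(slots):
        raise ValueError(f"cannot place {n} regions in {len(slots)} slots")
    chosen = rng.choice(len(slots), size=n, replace=False)
    regions = []
    for s in sorted(chosen):
        chrom, i = slots[s]
        width = int(np.clip(rng.normal(width_mean, cfg.peak_width_sd), 100, slot - 100))
        start = i * slot + int(rng.integers(0, slot - width - 1))
        regions.append(GenomicInterval(chrom, start, start + width))
    return regions


def sim_peak_sets(cfg: SimConfig, n_samples: int | None = None,
                  sample_prefix: str = "sample") -> SimPeaks:
    """Per-sample peak calls with shared regions, private noise, scored peaks.

    Shared regions appear in each sample with probability ``share_fraction``
    (boundaries jittered, scores correlated around a region base score);
    private regions are sample-specific noise.  ``pooled`` emulates peaks
    called on pooled reads: every shared region present in >= 1 sample plus
    a little pooled-only noise.
    """
    rng = cfg.rng(stream=1)
    n_samples = n_samples if n_samples is not None else cfg.n_individuals
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    total_private = cfg.n_private_per_sample * n_samples + cfg.n_private_per_sample
    regions = _place_regions(cfg, rng, cfg.n_shared_regions + total_private)
    shared = regions[: cfg.n_shared_regions]
    private_iter = iter(regions[cfg.n_shared_regions:])

    base_scores = 2.0 + rng.gamma(shape=2.0, scale=8.0, size=cfg.n_shared_regions)
    membership = rng.random((cfg.n_shared_regions, n_samples)) < cfg.share_fraction
    # a region absent everywhere is useless as truth; force one carrier
    for i in np.flatnonzero(~membership.any(axis=1)):
        membership[i, rng.integers(n_samples)] = True

    per_sample: dict[str, list[ScoredPeak]] = {s: [] for s in samples}
    rows = []
    for i, region in enumerate(shared):
        rows.append({
            "region_id": f"shared_{i}", "chrom": region.chrom,
            "start": region.start, "end": region.end, "type": "shared",
            **{s: bool(membership[i, j]) for j, s in enumerate(samples)},
        })
        for j, s in enumerate(samples):
            if not membership[i, j]:
                continue
            jit = rng.integers(-cfg.boundary_jitter, cfg.boundary_jitter + 1, size=2)
            start = max(0, region.start + int(jit[0]))
            end = max(start + 50, region.end + int(jit[1]))
            score = max(0.1, base_scores[i] * rng.lognormal(0.0, 0.25))
            per_sample[s].append(
                ScoredPeak(GenomicInterval(region.chrom, start, end), float(score), s)
            )
    for j, s in enumerate(samples):
        for _ in range(cfg.n_private_per_sample):
            region = next(private_iter)
            score = max(0.1, 1.5 + rng.gamma(shape=1.5, scale=2.0))
            per_sample[s].append(ScoredPeak(region, float(score), s))
            rows.append({
                "region_id": f"private_{s}_{region.start}", "chrom": region.chrom,
                "start": region.start, "end": region.end, "type": "private",
                **{t: t == s for t in samples},
            })

    pooled = []
    for i, region in enumerate(shared):
        if membership[i].any():
            score = max(0.1, base_scores[i] * rng.lognormal(0.0, 0.15))
            pooled.append(ScoredPeak(region, float(score), "pooled"))
    for _ in range(cfg.n_private_per_sample):
        region = next(private_iter)
        pooled.append(ScoredPeak(region, float(1.5 + rng.gamma(1.5, 2.0)), "pooled"))

    return SimPeaks(per_sample=per_sample, pooled=pooled, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Tn5 insertions


def sim_insertions(
    cfg: SimConfig,
    peak_intervals: list[GenomicInterval],
    rng: np.random.Generator | None = None,
    depleted_cores: list[GenomicInterval] | None = None,
    depletion: float | None = None,
    boosted_windows: list[GenomicInterval] | None = None,
    boost: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-base Tn5 insertion positions: background + elevated rate in peaks.

    ``boosted_windows`` (bound motif windows) receive extra events at
    ``(boost - 1) x peak_rate``, emulating the high accessibility around an
    occupied binding site; events falling inside ``depleted_cores`` (the
    motif cores of those windows) are then thinned with probability
    ``depletion``, emulating the bound protein protecting its motif from
    transposition.
    """
    rng = rng if rng is not None else cfg.rng(stream=2)
    depletion = cfg.footprint_depletion if depletion is None else depletion
    boost = cfg.bound_signal_boost if boost is None else boost
    cores = DisjointIntervals(depleted_cores) if depleted_cores else None
    out: dict[str, list[np.ndarray]] = {c: [] for c in cfg.chrom_sizes}
    for chrom, size in cfg.chrom_sizes.items():
        n_bg = rng.poisson(cfg.background_rate * size)
        out[chrom].append(rng.integers(0, size, size=n_bg))
    for iv in peak_intervals:
        n = rng.poisson(cfg.peak_rate * len(iv))
        out[iv.chrom].append(iv.start + rng.integers(0, len(iv), size=n))
    for iv in boosted_windows or []:
        n = rng.poisson(max(0.0, boost - 1.0) * cfg.peak_rate * len(iv))
        out[iv.chrom].append(iv.start + rng.integers(0, len(iv), size=n))
    result: dict[str, np.ndarray] = {}
    for chrom, chunks in out.items():
        pos = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        if cores is not None and depletion > 0 and pos.size:
            in_core = cores.contains_positions(chrom, pos)
            drop = in_core & (rng.random(pos.size) < depletion)
            pos = pos[~drop]
        result[chrom] = np.sort(pos.astype(np.int64))
    return result


# ---------------------------------------------------------------------------
# gene models and chromatin states


def sim_gene_models(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    rng = rng if rng is not None else cfg.rng(stream=3)
    genes = []
    chroms = list(cfg.chrom_sizes)
    slot = 60_000
    slots = [(c, i) for c in chroms
             for i in range(1, (cfg.chrom_sizes[c] - slot) // slot)]
    chosen = rng.choice(len(slots), size=min(cfg.n_genes, len(slots)), replace=False)
    for gi, s in enumerate(sorted(chosen)):
        chrom, i = slots[s]
        length = int(np.clip(rng.lognormal(np.log(15_000), 0.6), 2_000, slot - 12_000))
        start = i * slot + int(rng.integers(6_000, slot - length - 6_000 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{gi}", GenomicInterval(chrom, start, start + length, strand)))
    return genes


_STATE_WEIGHTS = {
    "1_TssA": 1, "2_TssFlnk": 1, "3_TssFlnkU": 1, "4_TssFlnkD": 1, "14_TssBiv": 1,
    "5_Tx": 4, "6_TxWk": 6, "7_EnhG1": 1, "8_EnhG2": 1, "9_EnhA1": 2, "10_EnhA2": 2,
    "11_EnhWk": 3, "15_EnhBiv": 1, "16_ReprPC": 2, "17_ReprPCWk": 3,
    "12_ZNF/Rpts": 1, "13_Het": 4, "18_Quies": 30,
}


def sim_state_segmentations(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    planted_peaks: list[GenomicInterval] | None = None,
    target_epigenome: str = "E_target",
) -> list[StateSegmentation]:
    """Random 18-state tilings for ``n_epigenomes`` reference epigenomes.

    When ``planted_peaks`` is given, the target epigenome gets enhancer
    segments at a ``planted_enhancer_fraction`` of those peak locations
    (expanded a little), so it should rank first for enhancer overlap.
    """
    rng = rng if rng is not None else cfg.rng(stream=4)
    states = list(_STATE_WEIGHTS)
    weights = np.array([_STATE_WEIGHTS[s] for s in states], dtype=float)
    weights /= weights.sum()

    def random_tiling(exclude: DisjointIntervals | None = None) -> list[tuple[GenomicInterval, str]]:
        segs = []
        for chrom, size in cfg.chrom_sizes.items():
            pos = 0
            while pos < size:
                length = int(np.clip(rng.exponential(10_000), 200, 100_000))
                end = min(size, pos + length)
                iv = GenomicInterval(chrom, pos, end)
                if exclude is None or not exclude.overlaps(iv):
                    segs.append((iv, states[rng.choice(len(states), p=weights)]))
                else:
                    # split around excluded regions coarsely: skip this tile
                    pass
                pos = end
        return segs

    out = []
    names = [target_epigenome] + [f"E{i:03d}" for i in range(1, cfg.n_epigenomes)]
    for name in names:
        if planted_peaks is not None and name == target_epigenome:
            n_plant = int(round(cfg.planted_enhancer_fraction * len(planted_peaks)))
            chosen = rng.choice(len(planted_peaks), size=n_plant, replace=False)
            enh = [
                GenomicInterval(
                    planted_peaks[i].chrom,
                    max(0, planted_peaks[i].start - 200),
                    planted_peaks[i].end + 200,
                )
                for i in chosen
            ]
            enh_merged = DisjointIntervals(enh)
            segs = [(iv, "9_EnhA1") for iv in enh_merged.intervals()]
            segs.extend(random_tiling(exclude=enh_merged))
            segs.sort(key=lambda t: (t[0].chrom, t[0].start))
            out.append(StateSegmentation(name, segs))
        else:
            out.append(StateSegmentation(name, random_tiling()))
    return out


# ---------------------------------------------------------------------------
# variants, LD, GWAS leads


@dataclass
class SimVariants:
    pool: list[Variant]
    ld: LdTable
    truth: pd.DataFrame  # variant id, block id


def sim_variants_ld(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    genes: list[GeneModel] | None = None,
) -> SimVariants:
    """Variant pool tiling the genome in LD blocks.

    Within-block pairs get r-squared values drawn as: proxy-grade
    (U(0.81, 0.99)) with probability ``proxy_pair_prob``, moderate
    (U(0.21, 0.6)) with probability ``moderate_pair_prob``, weak otherwise;
    cross-block pairs are absent (r-squared 0).  TSS distances come from
    ``genes`` when given, otherwise from a long-tailed draw.
    """
    rng = rng if rng is not None else cfg.rng(stream=5)
    chroms = list(cfg.chrom_sizes)
    stride = cfg.block_span + 10_000
    blocks_per_chrom = {c: (cfg.chrom_sizes[c] - stride) // stride for c in chroms}
    total_slots = sum(blocks_per_chrom.values())
    n_blocks = min(cfg.n_blocks, total_slots)

    tss_sorted: dict[str, np.ndarray] | None = None
    if genes is not None:
        tss_sorted = {}
        for chrom in chroms:
            tss = [g.body.start if g.body.strand == "+" else g.body.end - 1
                   for g in genes if g.body.chrom == chrom]
            tss_sorted[chrom] = np.sort(np.array(tss, dtype=np.int64))

    def tss_distance(chrom: str, pos: int) -> int:
        if tss_sorted is None or tss_sorted[chrom].size == 0:
            return int(rng.lognormal(np.log(20_000), 1.0))
        arr = tss_sorted[chrom]
        i = np.searchsorted(arr, pos)
        cands = arr[max(0, i - 1): i + 1]
        return int(np.abs(cands - pos).min())

    slots = [(c, i) for c in chroms for i in range(blocks_per_chrom[c])]
    chosen = rng.choice(len(slots), size=n_blocks, replace=False)
    pool: list[Variant] = []
    ld = LdTable()
    rows = []
    for b, s in enumerate(sorted(chosen)):
        chrom, i = slots[s]
        block_start = i * stride + 5_000
        offsets = np.sort(rng.choice(cfg.block_span, size=cfg.vars_per_block, replace=False))
        ids = [f"rs{b}_{k}" for k in range(cfg.vars_per_block)]
        mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.vars_per_block)
        for k, off in enumerate(offsets):
            pos = block_start + int(off)
            pool.append(Variant(chrom, pos, ids[k], float(mafs[k]),
                                tss_distance=tss_distance(chrom, pos)))
            rows.append({"variant": ids[k], "block": b, "chrom": chrom, "pos": pos})
        for a in range(cfg.vars_per_block):
            for c in range(a + 1, cfg.vars_per_block):
                u = rng.random()
                if u < cfg.proxy_pair_prob:
                    r2 = rng.uniform(0.81, 0.99)
                elif u < cfg.proxy_pair_prob + cfg.moderate_pair_prob:
                    r2 = rng.uniform(0.21, 0.6)
                else:
                    r2 = rng.uniform(0.0, 0.2)
                ld.add(ids[a], ids[c], float(r2))
    return SimVariants(pool=pool, ld=ld, truth=pd.DataFrame(rows))


def sim_gwas_scenario(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    covered_block_fraction: float = 0.2,
) -> tuple[SimVariants, "object"]:
    """Variant pool plus a peak set covering a fraction of LD blocks.

    Peaks span all variants of the covered blocks, so a locus overlaps the
    peak set if and only if its block is covered; the per-locus control
    overlap probability is therefore ~``covered_block_fraction`` uniformly
    across matching cells.  This is the controlled backdrop for enrichment
    calibration (null leads) and power (leads planted into covered blocks).
    """
    from .peaks import PeakCollection, ScoredPeak

    rng = rng if rng is not None else cfg.rng(stream=8)
    sim = sim_variants_ld(cfg, rng=rng)
    blocks = sim.truth.groupby("block")
    block_ids = np.array(sorted(blocks.groups))
    n_cov = int(round(covered_block_fraction * block_ids.size))
    covered = set(rng.choice(block_ids, size=n_cov, replace=False).tolist())
    intervals = []
    for b, grp in blocks:
        if b not in covered:
            continue
        intervals.append(GenomicInterval(
            grp["chrom"].iloc[0], int(grp["pos"].min()) - 10,
            int(grp["pos"].max()) + 10,
        ))
    collection = PeakCollection(
        [ScoredPeak(iv, 10.0, "sim") for iv in intervals], provenance="raw",
        group="gwas_scenario",
    )
    sim.truth["block_covered"] = sim.truth["block"].isin(covered)
    return sim, collection


def sim_gwas_leads(
    pool: list[Variant],
    overlap_flags: np.ndarray,
    n_leads: int,
    rng: np.random.Generator,
    overlap_rate: float | None = None,
    eligible: np.ndarray | None = None,
    block_of: dict[str, int] | None = None,
    p_scale: float = 5e-8,
) -> list[Variant]:
    """GWAS lead variants drawn from the pool, one per LD block.

    ``overlap_rate=None`` draws leads uniformly (null scenario); otherwise
    the draw fixes the fraction of leads whose locus overlaps peaks
    (enriched scenario).  ``eligible`` masks the draw (e.g. to variants with
    a sufficiently populated matching cell).  Leads get genome-wide
    significant p-values.
    """
    idx = np.arange(len(pool))
    if eligible is not None:
        idx = idx[eligible]
    if block_of is not None:
        seen: dict[int, list[int]] = {}
        for i in idx:
            seen.setdefault(block_of[pool[i].id], []).append(int(i))
        idx = np.array([members[int(rng.integers(len(members)))]
                        for members in seen.values()])
    flags = overlap_flags[idx]
    if overlap_rate is None:
        chosen = rng.choice(idx, size=n_leads, replace=False)
    else:
        n_hit = int(round(n_leads * overlap_rate))
        hit_idx, miss_idx = idx[flags], idx[~flags]
        if n_hit > hit_idx.size or (n_leads - n_hit) > miss_idx.size:
            raise ValueError("pool cannot supply the requested overlap composition")
        chosen = np.concatenate([
            rng.choice(hit_idx, size=n_hit, replace=False),
            rng.choice(miss_idx, size=n_leads - n_hit, replace=False),
        ])
    leads = []
    for i in chosen:
        v = pool[int(i)]
        leads.append(Variant(v.chrom, v.pos, v.id, v.maf, v.tss_distance,
                             p=float(p_scale * rng.random()), traits=("trait",)))
    return leads


# ---------------------------------------------------------------------------
# allele counts


def sim_allele_counts(
    cfg: SimConfig, rng: np.random.Generator | None = None, sample: str = "sample1"
) -> tuple[list[HetSiteCount], np.ndarray]:
    """Het-site reference/alternate counts with beta-binomial overdispersion.

    Null sites draw the per-site reference probability from
    Beta(alpha, beta) at (pi + reference_bias, rho); a truly imbalanced
    fraction uses the shifted ``imbalanced_pi`` (side chosen at random).
    Returns the counts and the truth labels (True = imbalanced).
    """
    rng = rng if rng is not None else cfg.rng(stream=6)
    n = cfg.n_sites
    totals = rng.integers(cfg.coverage_low, cfg.coverage_high + 1, size=n)
    imbalanced = rng.random(n) < cfg.imbalanced_fraction
    pis = np.full(n, min(0.999, cfg.ase_pi + cfg.reference_bias))
    flip = rng.random(n) < 0.5
    pis[imbalanced & ~flip] = cfg.imbalanced_pi
    pis[imbalanced & flip] = 1.0 - cfg.imbalanced_pi
    if cfg.ase_rho > 0:
        a = pis * (1 - cfg.ase_rho) / cfg.ase_rho
        b = (1 - pis) * (1 - cfg.ase_rho) / cfg.ase_rho
        p_site = rng.beta(a, b)
    else:
        p_site = pis
    refs = rng.binomial(totals, p_site)
    counts = [
        HetSiteCount(
            chrom="chr1", pos=1000 + 50 * i, site_id=f"site_{i}",
            ref_count=int(refs[i]), alt_count=int(totals[i] - refs[i]),
            other_count=0, sample=sample,
        )
        for i in range(n)
    ]
    return counts, imbalanced


# ---------------------------------------------------------------------------
# sequences


def sim_sequences(
    cfg: SimConfig, pwm: PWM, rng: np.random.Generator | None = None
) -> tuple[list[str], list[str], list[int]]:
    """Foreground/background sequence sets with planted motif consensus.

    Background sequences are i.i.d. uniform over ACGT; each foreground
    sequence receives the PWM consensus at a random position with
    probability ``plant_rate``.  Returns (fg, bg, planted positions with -1
    for unplanted foreground sequences).
    """
    rng = rng if rng is not None else cfg.rng(stream=7)
    bases = np.array(list("ACGT"))
    length = cfg.sequence_length
    consensus = pwm.consensus

    def random_seq() -> str:
        return "".join(bases[rng.integers(0, 4, size=length)])

    bg = [random_seq() for _ in range(cfg.n_bg_sequences)]
    fg, planted = [], []
    for _ in range(cfg.n_fg_sequences):
        s = random_seq()
        if rng.random() < cfg.plant_rate:
            pos = int(rng.integers(0, length - len(consensus)))
            s = s[:pos] + consensus + s[pos + len(consensus):]
            planted.append(pos)
        else:
            planted.append(-1)
        fg.append(s)
    return fg, bg, planted
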