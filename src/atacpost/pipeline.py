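"""End-to-end orchestration on synthetic inputs.

``run_all`` exercises every stage in order — simulate inputs, consolidate
representative peaks, counts + PCA, genic and chromatin-state annotation,
motif enrichment, aggregate footprinting, matched-control GWAS enrichment,
and allelic imbalance — writing one tidy TSV per stage plus a JSON summary
of the headline numbers.  The CLI and the smoke tests are thin wrappers
around this module.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, ase, footprints, gwas, motifs, peaks, simulate
from .core import GenomicInterval
from .io import write_table
from .motifs import PWM, MotifOccurrence

#: example motif used by the built-in pipeline run (C/EBP-like half site)
EXAMPLE_PWM_COUNTS = np.array(
    [
        [80, 5, 10, 5],
        [5, 5, 5, 85],
        [5, 5, 5, 85],
        [5, 5, 80, 10],
        [10, 70, 10, 10],
        [70, 10, 10, 10],
        [5, 5, 5, 85],
        [10, 10, 70, 10],
        [80, 5, 10, 5],
        [5, 80, 10, 5],
    ]
)


def example_pwm() -> PWM:
    return PWM.from_counts("CEBP_like", EXAMPLE_PWM_COUNTS)


def smoke_config(seed: int) -> simulate.SimConfig:
    """A reduced configuration for fast end-to-end runs."""
    return simulate.SimConfig(
        seed=seed,
        n_shared_regions=250,
        n_private_per_sample=40,
        n_blocks=1500,
        n_sites=4000,
        n_epigenomes=6,
        imbalanced_fraction=0.05,
        n_fg_sequences=100,
        n_bg_sequences=100,
    )


def run_all(cfg: simulate.SimConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = cfg.genome()
    summary: dict = {"seed": cfg.seed}

    # --- representative peaks: individuals (union) and replicates ----------
    tissue = simulate.sim_peak_sets(cfg, n_samples=cfg.n_individuals,
                                    sample_prefix="tissue")
    union = peaks.representative_peaks_union(list(tissue.per_sample.values()))
    top_union = peaks.top_k_by_rank_average(
        union, list(tissue.per_sample.values()), k=min(50_000, len(union))
    )
    write_table(top_union.to_frame(), outdir / "peaks_union_rank_average.tsv")
    summary["n_union_regions"] = len(union)
    summary["n_top_union"] = len(top_union)

    rep_cfg = dataclasses.replace(cfg, seed=cfg.seed + 1)
    reps = simulate.sim_peak_sets(rep_cfg, n_samples=cfg.n_replicates,
                                  sample_prefix="rep")
    rep_supported = peaks.representative_peaks_replicates(
        reps.pooled, list(reps.per_sample.values()), min_support=2
    )
    top_rep = peaks.top_k_by_significance(
        rep_supported, k=min(50_000, len(rep_supported))
    )
    write_table(top_rep.to_frame(), outdir / "peaks_replicate_supported.tsv")
    summary["n_replicate_supported"] = len(rep_supported)

    # --- counts in peaks + PCA --------------------------------------------
    all_regions = peaks.PeakCollection(
        peaks.merge_collections(top_union, top_rep), provenance="union"
    )
    insertions = {}
    for si, (sample, sample_peaks) in enumerate(
        {**tissue.per_sample, **reps.per_sample}.items()
    ):
        rng = np.random.default_rng((cfg.seed, 10, si))
        insertions[sample] = simulate.sim_insertions(
            cfg, [p.interval for p in sample_peaks], rng=rng, depletion=0.0
        )
    counts = peaks.count_insertions_in_peaks(insertions, all_regions)
    write_table(counts.reset_index(names="peak"), outdir / "counts.tsv")
    coords, var_explained = peaks.sample_similarity_pca(counts, n_components=2)
    write_table(coords.reset_index(names="sample"), outdir / "pca.tsv")
    summary["pc1_variance_fraction"] = float(var_explained[0])

    # --- annotation ---------------------------------------------------------
    genes = simulate.sim_gene_models(cfg)
    genic = annotate.classify_peaks(top_union, genes)
    write_table(genic, outdir / "genic_categories.tsv")
    summary["genic_fractions"] = (
        genic["category"].value_counts(normalize=True).to_dict()
    )

    segs = simulate.sim_state_segmentations(
        cfg, planted_peaks=top_union.intervals(), target_epigenome="E_target"
    )
    combined = [annotate.combine_states(s) for s in segs]
    write_table(annotate.state_overlap_table(top_union, combined),
                outdir / "state_overlap.tsv")
    ranks = annotate.rank_epigenomes(top_union, combined, "enhancer")
    write_table(ranks, outdir / "epigenome_ranks.tsv")
    summary["target_epigenome_enhancer_rank"] = int(
        ranks.loc[ranks["epigenome"] == "E_target", "rank"].iloc[0]
    )

    # --- motif enrichment ---------------------------------------------------
    pwm = example_pwm()
    fg, _, _ = simulate.sim_sequences(cfg, pwm)
    shuffle_rng = cfg.rng(stream=11)
    bg = [motifs.dinucleotide_shuffle(s, shuffle_rng) for s in fg]
    enr = motifs.motif_enrichment_fisher(fg, bg, pwm, n_motifs_tested=519)
    write_table(pd.DataFrame([dataclasses.asdict(enr)]),
                outdir / "motif_enrichment.tsv")
    summary["motif_enrichment_p"] = enr.p
    summary["motif_enrichment_evalue"] = enr.e_value

    # --- footprints ---------------------------------------------------------
    fp = run_footprint_stage(cfg, outdir=outdir)
    summary.update(fp)

    # --- GWAS enrichment ----------------------------------------------------
    gw = run_gwas_stage(cfg, top_union, genes, outdir=outdir)
    summary.update(gw)

    # --- allelic imbalance --------------------------------------------------
    counts_ase, truth = simulate.sim_allele_counts(cfg)
    kept = ase.filter_sites(counts_ase)
    null = ase.fit_betabinom_null([(c.ref_count, c.total) for c in kept])
    results = ase.ase_scan(kept, null)
    write_table(results, outdir / "ase_results.tsv")
    summary["ase_pi_hat"] = null.pi
    summary["ase_rho_hat"] = null.rho
    summary["ase_nominal_fraction"] = float(results["nominal"].mean())

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def plant_motif_occurrences(
    cfg: simulate.SimConfig,
    peak_intervals: list[GenomicInterval],
    n_bound: int,
    n_unbound: int,
    rng: np.random.Generator,
    motif_len: int = 10,
) -> tuple[list[MotifOccurrence], np.ndarray]:
    """Motif occurrences centered in distinct peaks; bound sites score higher.

    Returns the occurrences and the planted bound-truth labels.
    """
    usable = [iv for iv in peak_intervals if len(iv) >= motif_len + 20]
    if n_bound + n_unbound > len(usable):
        raise ValueError("not enough peaks to host the requested motif sites")
    chosen = rng.choice(len(usable), size=n_bound + n_unbound, replace=False)
    occs, is_bound = [], np.zeros(n_bound + n_unbound, dtype=bool)
    is_bound[:n_bound] = True
    for i, pi in enumerate(chosen):
        iv = usable[int(pi)]
        center = (iv.start + iv.end) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        score = float(rng.normal(12.0, 1.0) if is_bound[i] else rng.normal(8.0, 1.5))
        occs.append(MotifOccurrence(
            GenomicInterval(iv.chrom, center - motif_len // 2,
                            center - motif_len // 2 + motif_len, strand),
            "CEBP_like", score,
        ))
    return occs, is_bound


def run_footprint_stage(
    cfg: simulate.SimConfig,
    outdir: Path | None = None,
    n_bound: int = 300,
    n_unbound: int = 600,
    rng: np.random.Generator | None = None,
    use_em: bool = True,
) -> dict:
    """Plant bound/unbound motif sites in fresh peaks, simulate insertions,
    and compute the aggregate footprint statistic."""
    rng = rng if rng is not None else cfg.rng(stream=12)
    genome = cfg.genome()
    fp_peaks = simulate.sim_peak_sets(
        dataclasses.replace(cfg, seed=cfg.seed + 2,
                            n_shared_regions=max(cfg.n_shared_regions,
                                                 n_bound + n_unbound + 50)),
        n_samples=1, sample_prefix="fp",
    )
    intervals = [p.interval for p in fp_peaks.per_sample["fp1"]]
    occs, is_bound = plant_motif_occurrences(cfg, intervals, n_bound, n_unbound, rng)
    windows = footprints.build_windows(occs, genome, flank=100)
    # build_windows preserves order; realign planted labels with kept windows
    kept = []
    j = 0
    for i, occ in enumerate(occs):
        if j < len(windows) and windows[j].occurrence is occ:
            kept.append(i)
            j += 1
    is_bound = is_bound[kept]
    cores = [w.occurrence.interval for w, b in zip(windows, is_bound) if b]
    boosted = [w.window for w, b in zip(windows, is_bound) if b]
    ins = simulate.sim_insertions(cfg, intervals, rng=rng, depleted_cores=cores,
                                  depletion=cfg.footprint_depletion,
                                  boosted_windows=boosted)
    matrix = footprints.transposition_matrix(ins, windows)
    if use_em:
        posteriors, em_info = footprints.em_posterior_standin(matrix)
    else:
        posteriors = np.where(is_bound, 1.0, 0.0)
        em_info = {}
    labels = footprints.classify_bound(posteriors)
    # fall back to planted truth if the EM split leaves a group empty
    if (labels == "bound").sum() == 0 or (labels == "unbound").sum() == 0:
        labels = np.where(is_bound, "bound", "unbound").astype(object)
    bound_prof, unbound_prof = footprints.aggregate_profiles(matrix, labels)
    result = footprints.tpr_footprint(
        bound_prof, unbound_prof, matrix.motif_len, matrix.flank,
        motif_id="CEBP_like",
        n_bound=int((labels == "bound").sum()),
        n_unbound=int((labels == "unbound").sum()),
    )
    if outdir is not None:
        prof = pd.DataFrame({
            "position": np.arange(len(result.tpr)) - matrix.flank,
            "bound_profile": result.bound_profile,
            "unbound_profile": result.unbound_profile,
            "tpr": result.tpr,
        })
        write_table(prof, Path(outdir) / "footprint_profile.tsv")
        write_table(pd.DataFrame([{
            "motif": result.motif_id, "mtpr": result.mtpr, "ftpr": result.ftpr,
            "has_footprint": result.has_footprint,
            "n_bound": result.n_bound, "n_unbound": result.n_unbound,
        }]), Path(outdir) / "footprints.tsv")
    out = {
        "footprint_mtpr": result.mtpr,
        "footprint_ftpr": result.ftpr,
        "footprint_called": bool(result.has_footprint),
    }
    if em_info:
        out["footprint_em_converged"] = bool(em_info.get("converged", False))
        from sklearn.metrics import roc_auc_score

        out["footprint_em_auroc"] = float(roc_auc_score(is_bound, posteriors))
    return out


def run_gwas_stage(
    cfg: simulate.SimConfig,
    peak_collection: peaks.PeakCollection,
    genes,
    outdir: Path | None = None,
    n_leads: int = 100,
    n_control_sets: int = 500,
    min_cell: int = 10,
) -> dict:
    """Null and 2x-enriched GWAS scenarios against one peak set."""
    rng = cfg.rng(stream=13)
    sim = simulate.sim_variants_ld(cfg, genes=genes)
    matcher = gwas.ControlMatcher(sim.pool, sim.ld)
    flags = matcher.locus_overlap_flags(peak_collection)
    eligible = matcher.cell_sizes() >= min_cell
    block_of = dict(zip(sim.truth["variant"], sim.truth["block"]))
    n_eligible_blocks = len({block_of[sim.pool[i].id]
                             for i in np.flatnonzero(eligible)})
    n_leads = min(n_leads, max(10, n_eligible_blocks // 2))

    results = []
    for scenario, rate in (("null", None), ("enriched_2x", "double")):
        if rate == "double":
            base = float(flags[eligible].mean())
            rate_val = min(0.95, 2.0 * base)
        else:
            rate_val = None
        leads = simulate.sim_gwas_leads(
            sim.pool, flags, n_leads, rng, overlap_rate=rate_val,
            eligible=eligible, block_of=block_of,
        )
        clumped = gwas.ld_clump(leads, sim.ld)
        loci = gwas.expand_proxies(clumped, matcher.by_id, sim.ld)
        res = gwas.enrichment_test(
            loci, peak_collection, matcher, n_control_sets=n_control_sets,
            rng=rng, trait=scenario, peak_label="top_union",
            overlap_flags=flags,
        )
        results.append(res)
    table = gwas.bonferroni_call(results, n_traits=11)
    if outdir is not None:
        write_table(table, Path(outdir) / "gwas_enrichment.tsv")
        report, locus_summary = gwas.report_variant_peak_overlap(
            gwas.expand_proxies(
                gwas.ld_clump(
                    simulate.sim_gwas_leads(sim.pool, flags, 30, rng,
                                            eligible=eligible, block_of=block_of),
                    sim.ld),
                matcher.by_id, sim.ld),
            {"top_union": peak_collection},
        )
        write_table(report, Path(outdir) / "gwas_variant_peak_overlap.tsv")
        write_table(locus_summary, Path(outdir) / "gwas_locus_summary.tsv")
    null_res, enr_res = results
    return {
        "gwas_null_z": null_res.z, "gwas_null_p": null_res.p,
        "gwas_enriched_z": enr_res.z, "gwas_enriched_p": enr_res.p,
        "gwas_enriched_significant": bool(enr_res.p < 0.05 / 11),
    }
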