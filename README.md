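# atacpost

Downstream analysis of ATAC-seq open-chromatin profiles: the computational
steps that come *after* alignment and peak calling, for studies that profile
a tissue with a handful of individuals plus cell-line groups with technical
replicates, and then ask which regulatory regions those peaks mark, which
transcription factors occupy them, and which trait-associated and
allele-specific variants they contain.

The package is aimed at regulatory-genomics analysts who have peak calls
(narrowPeak), per-base Tn5 insertion positions, gene models, chromatin-state
segmentations, motif matrices and variant catalogs, and want a tested,
scriptable implementation of the following pipeline stages:

- **Representative peaks** (`atacpost.peaks`) — consolidate peak calls either
  by replicate support (a pooled-read peak is kept when it shares ≥ 1 bp with
  peaks from ≥ 2 technical replicates) or by the union of peaks across
  individuals; select the top-K peaks by significance or, for union peaks, by
  the mean of per-individual significance ranks (regions absent from an
  individual receive that individual's worst rank + 1); build counts-in-peaks
  matrices and a sample-similarity PCA on
  log₂(count / size-factor + 1)-transformed counts.
- **Annotation** (`atacpost.annotate`) — classify peaks into TSS-proximal
  (TSS − 5 kb to TSS + 1 kb, strand-aware), intragenic, downstream
  (≤ 5 kb past the TTS) and distal categories with fixed precedence; merge
  18-state chromatin segmentations into promoter / transcribed / enhancer /
  polycomb-repressed labels; rank reference epigenomes by peak-base overlap.
- **Motifs** (`atacpost.motifs`) — log-odds PWM scanning on both strands,
  same-coordinate haplotype deduplication, Altschul–Erickson
  dinucleotide-preserving shuffles, and one-sided Fisher-exact motif
  enrichment with E-values.
- **Footprints** (`atacpost.footprints`) — motif ± 100 bp windows filtered at
  90 % mappability, sites × positions Tn5 transposition matrices, bound /
  unbound classification from posterior binding probabilities (> 0.99 bound,
  < 0.5 unbound; a two-component EM mixture with a motif-score prior supplies
  posteriors when none are given), and the aggregate transposition
  probability ratio

  TPR[pos] = bound_profile[pos] / unbound_profile[pos],

  with mTPR (mean over motif positions) < fTPR (mean over flank positions)
  defining an aggregate footprint.
- **GWAS enrichment** (`atacpost.gwas`) — LD clumping (drop leads with
  r² > 0.2 to a more significant lead within 1 Mb), proxy expansion
  (r² > 0.8 within 1 Mb), controls matched on LD-proxy count, minor-allele
  frequency and TSS distance, an exact Poisson-binomial enrichment p-value,
  the z-score (observed − expected) / sd, Bonferroni calls at α / n_traits,
  and per-locus variant-in-peak reports with single-candidate flags.
- **Allelic imbalance** (`atacpost.ase`) — filter heterozygous-site allele
  counts (≥ 10 total, ≥ 1 per allele, no non-genotyped bases), fit a
  per-sample beta-binomial null (reference ratio π, dispersion ρ) by maximum
  likelihood, and run exact two-tailed tests per site.
- **Synthetic data** (`atacpost.simulate`) — seeded generators for every
  input above, with planted ground truth (shared/private peaks, footprint
  depletion, LD-block structure, imbalanced sites, planted motifs) so each
  stage can be scored against what was simulated.

## Worked example: allelic imbalance

```python
from atacpost import ase, simulate

cfg = simulate.SimConfig(seed=1, n_sites=5000, ase_pi=0.5, ase_rho=0.05,
                         imbalanced_fraction=0.05, imbalanced_pi=0.9)
sites, truth = simulate.sim_allele_counts(cfg)
kept = ase.filter_sites(sites)
null = ase.fit_betabinom_null([(s.ref_count, s.total) for s in kept])
print(f"fitted null: pi = {null.pi:.4f}, rho = {null.rho:.4f} ({len(kept)} sites)")
results = ase.ase_scan(kept, null)
print(f"nominal (p < 0.05) sites: {int(results['nominal'].sum())} "
      f"({results['nominal'].mean():.3f} of sites)")
print(results.head(3).to_string(index=False))
```

prints

```
fitted null: pi = 0.4973, rho = 0.0763 (4943 sites)
nominal (p < 0.05) sites: 217 (0.044 of sites)
chrom    pos   site_id  ref_count  alt_count  total  ref_ratio        p  nominal
 chr1  84500 site_1670          1         59     60   0.016667 0.000043     True
 chr1  75450 site_1489          1         50     51   0.019608 0.000100     True
 chr1 192350 site_3827         58          2     60   0.966667 0.000140     True
```

The fitted null absorbs the simulated overdispersion (ρ̂ ≈ 0.076 against a
generating mix of ρ = 0.05 plus a 5 % truly imbalanced fraction), and the
most extreme sites — near-monoallelic counts at deep coverage — surface with
the smallest two-tailed p-values.

The same end-to-end flow is available from the shell:

```bash
atacpost sim all --seed 3 --out results/toy   # simulate + run every stage
atacpost ase fit --counts counts.tsv --out null.json
atacpost enrich --gwas gwas.tsv --pool pool.tsv --ld ld.tsv \
    --peaks peaks.narrowPeak --seed 7 --out enrichment.tsv
```

`atacpost sim all` writes one tidy TSV per stage (representative peaks,
counts, PCA, genic categories, state overlaps, epigenome ranks, motif
enrichment, footprint profile and call, GWAS enrichment and locus reports,
allelic-imbalance results) plus a `summary.json` of headline numbers.

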