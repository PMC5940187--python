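# gbrkit

Toolkit for classifying transcription-factor binding regions into
coregulator-**blocked** and **non-blocked** classes from ChIP-seq peak and
count data, and for characterizing the two classes by chromatin-remodeler
dependency, proximity to gene classes, chromatin accessibility (ATAC-seq),
and DNA motif content.

## The problem

The glucocorticoid receptor (GR) binds thousands of genomic regions (GR
binding regions, GBR) after hormone stimulation, but the coregulator Hic-5
blocks GR occupancy at a specific subset of them. Depleting Hic-5 unmasks
these sites: the number of called GR peaks rises several-fold, and a
differential-occupancy analysis finds regions whose GR signal increases
strongly upon depletion. `gbrkit` implements that analysis end-to-end for
anyone working with peak-level ChIP-seq/ATAC-seq data on a
coregulator-depletion design:

- **Interval algebra** (`gbrkit.intervals`): BED-convention peaks with
  summits, ≥ *k*-bp overlap tests, 2–3-way Venn partitioning into atomic
  union regions, a replicate-overlap reproducibility filter, summit windows,
  and summit-to-TSS distances.
- **Differential occupancy** (`gbrkit.occupancy`): consensus regions
  supported by peak calls in ≥ 2 samples, CPM normalization, and a
  negative-binomial Wald test. Counts K_gj for region *g* are modeled as
  NB(μ_gj, α_g) with Var = μ + αμ²; α_g is a method-of-moments estimate
  shrunk 50/50 toward a mean–dispersion trend, and the test statistic is
  z = log2FC / SE(log2FC) with Benjamini–Hochberg correction across regions.
  A region is significant when FDR ≤ 0.01 **and** |fold change| ≥ 3 (the
  fold gate is dropped for the remodeler contrasts).
- **Classification** (`gbrkit.classify`): *blocked* = significant gain upon
  depletion ∧ reproducibly called in depleted cells; *non-blocked* =
  reproducibly called in both conditions ∧ not significant. Remodeler
  (CHD9/BRM) dependency is compartmentalized two ways: by disappearance of
  the called peak upon remodeler+coregulator co-depletion, or by a
  significant directional occupancy drop (FDR ≤ 0.01, log2FC < 0).
- **Proximity enrichment** (`gbrkit.proximity`): blocked/non-blocked
  proportions within 10 kb–1 Mb TSS windows of the *block* / *ind* / *mod*
  gene classes, compared by Pearson χ² on the 2×2 ratio table.
- **Accessibility** (`gbrkit.accessibility`): open-chromatin fractions by
  ATAC-peak overlap, newly-accessible subsets upon depletion, and
  summit-centered metaprofiles (mean reads-per-million per 10-nt bin,
  ±1 kb).
- **Motifs** (`gbrkit.motifs`): log-odds PWM scanning of 1-kb summit windows
  (bundled GRE / AP-1 / ETS-family models), hypergeometric enrichment of one
  region class against the other, positional distributions, and three-way
  motif co-occurrence.
- **Synthetic data** (`gbrkit.simulate`): a seeded generator that emits the
  full study design — six siRNA conditions × two replicates of narrowPeak
  calls, NB counts over consensus regions, ATAC peaks and coverage for four
  conditions, gene classes, and motif-planted sequences — together with a
  ground-truth table for recovery scoring.

## Worked example

```python
from gbrkit.simulate import SyntheticConfig, generate
from gbrkit.pipeline import PipelineConfig, run_pipeline

cfg = SyntheticConfig(seed=7, n_gbr=1000,
                      genome=(("chr1", 12_000_000), ("chr2", 12_000_000)),
                      n_genes={"block": 100, "ind": 20, "mod": 70})
manifest, truth = generate(cfg, "demo/data")
print(f"planted regions: {len(truth.table)} "
      f"({(truth.table['label'] == 'blocked').sum()} blocked)")

summary = run_pipeline(PipelineConfig.from_manifest("demo/data/manifest.json",
                                                    outdir="demo/results"))
print("classified:", summary["classification_counts"])
dep = summary["dependency"]["blocked"]["peakset"]
print(f"blocked regions remodeler-dependent: CHD9 {dep['pct_chd9']}%, "
      f"BRM {dep['pct_brm']}%, both {dep['pct_both']}%")
```

Output:

```
planted regions: 841 (475 blocked)
classified: {'blocked': 466, 'non_blocked': 327, 'hic5_dependent': 20, 'shared_nonsig': 21, 'other': 7}
blocked regions remodeler-dependent: CHD9 82%, BRM 73%, both 70%
```

841 planted regions survive spacing constraints, of which 475 are truly
blocked; the pipeline recovers 466 blocked calls (98% of them correct), and
the remodeler-dependency percentages (82/73/70) match the generator's
planted probabilities (80/72/68) to within sampling error. Further summary
fields report proximity proportions per gene class with χ² p-values, open
chromatin fractions and newly-accessible subsets per condition,
accessibility profile means, and motif enrichment — e.g. for this run the
ETS motif is found in 51% of blocked regions (hypergeometric p ≈ 6e-48
against non-blocked background), and 100% of significant regions gained
occupancy upon depletion.

The same workflow is available from the shell:

```
gbrkit simulate --seed 7 --outdir demo/data
gbrkit run-all --manifest demo/data/manifest.json --outdir demo/results
```

plus per-stage subcommands (`consensus`, `diff`, `classify`, `dependency`,
`proximity`, `access`, `motifs`, `report`).

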