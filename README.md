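# wntlineage

Quantitative lineage analysis of nuclear Wnt-effector localization in
*C. elegans* embryos.

In the worm embryo, every cell division is oriented, and the Wnt/β-catenin
asymmetry pathway partitions its nuclear effectors between the two
daughters: the β-catenins SYS-1 and WRM-1 accumulate in the posterior
daughter's nucleus, while the TCF transcription factor POP-1 accumulates in
the anterior daughter's. Automated lineage tracing of fluorescent reporters
yields, for every cell named in Sulston nomenclature (founder prefix + a
suffix of division polarities, e.g. `ABplaaaapp`), a single
background-subtracted mean nuclear concentration over the cell's lifetime
("blot"). This package implements the statistics of that data for
developmental biologists working with lineage-resolved reporter
quantifications:

- **Sister asymmetry** — per division, posterior-minus-anterior daughter
  concentration, tested across replicate embryos (one-sample *t* by
  default) with Benjamini–Hochberg FDR, and classified
  normal/low/none/reversed against wild-type-derived thresholds.
- **Cousin enrichment** — the transmitotic signal: a "High-High" cell (the
  reporter-High daughter of a High parent) is compared with its matched
  "Low-High" cousin (same grandparent, opposite-polarity parent). The
  headline statistic is the percent increase of HH over LH group means,
  (mean<sub>HH</sub> − mean<sub>LH</sub>)/mean<sub>LH</sub> × 100, with a
  Wilcoxon signed-rank *p* over matched pairs; triple-history contrasts
  (HHH vs LHH, LHH vs HLH) resolve whether the memory spans one or two
  divisions.
- **Subtree activity** for stable lagged transcriptional reporters
  (POPTOP-style TCF-site reporters): a cell's activity is the mean
  expression of the cell and all its recorded descendants; activity
  differences between sister subtrees isolate single divisions;
  expression-initiating cells are inferred by walking maximal expressing
  clades back along the lineage by the fluorophore maturation lag
  (~30 min), and genes are scored by the fraction of their initiating
  lineages that are SYS-1 High-High.
- **TCF/Helper motif scanning** of regulatory sequences (IUPAC consensus
  and/or PWMs, both strands, deduplicated) with permutation enrichment of
  site density over background regions.
- A **synthetic-embryo generator** that emulates all of the above with
  known ground truth, so every stage of the pipeline is tested by
  parameter recovery, null calibration, and brute-force oracles — no
  imaging data required.

## Worked example

```sh
wntlineage simulate --stage 350 --n-embryos 8 --seed 1 --outdir demo
wntlineage run-all --manifest demo/manifest.csv --outdir demo_out
```

prints (seed 1):

```
{
  "n_embryos": 8,
  "n_divisions_tested": 384,
  "n_divisions_significant": 379,
  "fraction_significant": 0.9869791666666666,
  "cousin_percent_increase": 75.16000883739305,
  "cousin_mean_ratio": 1.820733381513308,
  "cousin_p": 3.7059553066921366e-182,
  "n_cousin_pairs": 1104
}
```

Read: of 384 divisions observed in all 8 embryos, 379 (98.7%) show
significant sister asymmetry at nominal p < 0.05, and High-High cells carry
75% more nuclear reporter than their Low-High cousins over 1104 matched
quartets — recovering the 74% enrichment this dataset was generated with.

The same steps are available as numbered drivers under `analysis/`
(`01_simulate_embryos.py` … `05_motif_enrichment.py`), which write their
tables under `results/tables/` and print one-line findings per condition,
including the receptor-null dissociation (sister asymmetry persists while
cousin enrichment collapses to ~0%).

The library surface mirrors the pipeline: `wntlineage.lineage_model`
(names, trees, cousin pairing), `io_tables` (per-cell table dialect,
manifests), `quantify` (trace aggregation, replicate correlation),
`asymmetry`, `history_enrichment`, `reporter_activity`, `motif_scan`,
`synthetic_data`, and `cli`.

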