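# methlink

**Sliding-window DMR calling and methylome–transcriptome integration for
plant WGBS + RNA-seq studies.**

Plants methylate cytosines in three sequence contexts — CG, CHG and CHH
(H = A, C or T) — and stress responses such as freezing tolerance in
winter rapeseed (*Brassica napus*) leave footprints in both the
methylome and the transcriptome. `methlink` is a reusable, fully tested
pipeline for the standard integration analysis of such studies: it takes
per-cytosine bisulfite reports and gene-level count matrices and produces
per-context methylation statistics, differentially methylated regions
(DMRs), differentially expressed genes (DEGs), and their intersection —
differentially methylated genes (DMGs) — together with downstream
set/enrichment/transcription-factor summaries. A synthetic-data module
generates complete studies with planted, recoverable truth, so every
stage can be validated end to end without any sequencing data.

It is aimed at epigenomics researchers and methods developers who want a
transparent, exactly checkable reference implementation of this analysis
rather than a black box.

## The model

**Methylation levels.** For a set of cytosines, the *weighted* level is
the read-count-weighted mean

    m = Σ meth / Σ (meth + unmeth).

Sites with coverage below 4 reads are excluded. A site counts as
*methylated* (for context proportions) when a one-sided binomial test of
its methylated count against the bisulfite non-conversion rate rejects
after Benjamini–Hochberg (BH) correction at 0.05.

**DMR calling.** Chromosomes are tiled with 200-bp windows. Within each
window, context and group, read counts are pooled over replicates and
sites, and the pooled 2×2 table (meth/unmeth × control/treatment) is
tested with a two-sided Fisher exact test; p-values are converted to
q-values by BH step-up within each context. A window is a DMR iff

| context | sites in window (both groups) | \|Δm\| | q |
|---------|------------------------------:|-------:|------:|
| CG      | ≥ 5                           | ≥ 0.25 | ≤ 0.05 |
| CHG     | ≥ 5                           | ≥ 0.25 | ≤ 0.05 |
| CHH     | ≥ 15                          | ≥ 0.15 | ≤ 0.05 |

with Δm = m_treatment − m_control (hyper- vs hypomethylated by sign).

**Expression.** Counts are normalised as FPKM =
count / ((length/10³)·(library/10⁶)). Differential expression uses an
exact two-sided binomial test on replicate-pooled counts with a
library-size offset; DEGs require p < 0.001 and |log₂FC| ≥ 2.

**Integration.** A DMG is a DEG with ≥ 1 DMR overlapping its gene body
± 2 kb (region labelled upstream2k / body / downstream2k by the DMR
midpoint, strand-aware). Term enrichment of DMG sets uses the
hypergeometric upper tail with BH q-values; qPCR validation uses the
2^−ΔΔCt method and sign concordance with RNA-seq log₂FC.

## Worked example

The self-contained demo generates a two-condition, three-replicate
synthetic study (two 300-kb chromosomes, 150 genes, ~30× cytosine
coverage, an unmethylated spike-in chromosome, 36 planted DMRs and 20
planted DEGs), runs the full pipeline, and scores the calls against the
planted truth:

```python
from methlink import pipeline
bundle = pipeline.demo(seed=7, out_dir="methlink_demo")
print(bundle["methylation_summary"].to_string(index=False))
```

```
condition context  n_called_sites  site_proportion  weighted_level
  control      CG          225750         0.298709        0.647918
  control     CHG          167007         0.220981        0.285688
  control     CHH          362995         0.480310        0.100838
treatment      CG          225690         0.298647        0.646569
treatment     CHG          167089         0.221103        0.287080
treatment     CHH          362929         0.480250        0.101903
```

The genome-wide weighted levels reproduce the canonical Brassica-like
ordering CG (0.65) ≫ CHG (0.29) ≫ CHH (0.10), while CHH sites dominate
the *count* of methylated sites (48%) — the familiar inversion between
level and abundance. The truth report shows full recovery of the
planted effects:

```python
print(bundle["truth_report"])
```

```
{"dmr_sensitivity": 1.0, "dmr_precision": 1.0,
 "deg_sensitivity": 1.0, "deg_precision": 1.0,
 "dmg_expected": 14, "dmg_observed": 14, "dmg_exact_match": 1.0, ...}
```

All 36 planted DMR windows are called (no false windows among 9,000
tested), all 20 planted DEGs are recovered, and the DMG table equals the
expected planted DMR ∧ DEG intersection exactly — e.g.

```
gene_id context  n_dmrs    regions meth_direction expr_direction
  g0082      CG       1       body           hypo           down
  g0029     CHG       1       body          hyper             up
  g0005     CHH       1       body          hyper           down
```

Outputs land under `methlink_demo/results/` as TSV/BED/JSON, with a
manifest recording every threshold, input checksum and stage row count.

The same stages are available as CLI subcommands
(`methlink simulate|methylome|dmr|expression|integrate|enrich|demo|run`).

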