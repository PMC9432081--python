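# Methods

This note documents the statistical model behind `methlink`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Coordinates and data model

All coordinates are 1-based inclusive in memory, matching the cytosine
report and GFF3 conventions; BED6 output converts to 0-based half-open
at the I/O boundary. A cytosine record is strand-specific: `pos` is the
position of the cytosine on the forward-strand axis, and its context
(CG / CHG / CHH, H = A, C or T) is read 5′→3′ on the cytosine's own
strand. Symmetric CG pairs are *not* merged across strands — each
strand's cytosine is an independent observation (an optional merge is
deliberately not the default, since the report format is
strand-resolved). Within 2 bp of a strand's 3′ end, missing downstream
bases are treated as H.

Windows, bins or summary cells with no covered cytosine are reported as
NaN, an explicit missing flag; they are never imputed and never
conflated with a level of 0.

## Methylation statistics

* **Weighted level**: Σ meth / Σ (meth + unmeth) over a record set —
  invariant to record order and to splitting/merging of reads at a
  site. Raises an explicit no-data error, not 0, on empty input.
* **Coverage floor**: 4 reads per site (inclusive), applied per
  replicate before any pooling.
* **Methylated-site call** (for context proportions): one-sided
  binomial test of the site's methylated count against the measured
  non-conversion rate, BH-corrected at 0.05 across covered sites.
  The source studies never state a site-call rule; this is the standard
  convention. A `covered` mode (proportions over all covered sites) is
  also exposed because either reading of a "proportion of methylation
  sites" figure is defensible.
* **Chromosome profile**: 1-Mb windows from position 1 (last partial
  window included); gene density = genes per window by midpoint.
* **Metaprofile**: 20 upstream bins (100 bp each at the default 2-kb
  flank), 20 length-normalised gene-body bins, 20 downstream bins,
  oriented 5′→3′ (minus-strand genes reversed). Counts are pooled over
  genes, then divided — i.e. each bin reports a weighted level, so
  deeply covered genes weigh more. Genes shorter than the bin count are
  binned by position fraction and never dropped. Bin resolution is a
  free choice (the emulated figures do not state one); 100-bp flank
  bins match the window scale of the DMR caller.
* **Conversion rate**: Σ unmeth / Σ coverage on a designated
  fully-unmethylated spike-in sequence.

## DMR caller

Non-overlapping 200-bp tiles by default. "Sliding window" names no step
in the emulated protocol, so step = width; an overlapping step and a
merge-adjacent-windows post-pass are available but off by default
(merging is never implied by window-level criteria).

Replicate counts are pooled within each group (control, treatment) after
the per-site coverage floor; the window's site count is the number of
distinct covered cytosine positions of its context, required in *both*
groups — a methylation level is meaningless at uncovered sites. The
window test is a two-sided Fisher exact test on the pooled 2×2 table.
The underlying protocol states only "q ≤ 0.05"; Fisher on pooled counts
is the minimal defensible choice and is exactly checkable against
enumeration (the test interface is pluggable). Pooling ignores
replicate-to-replicate dispersion, so on overdispersed real data the
caller is anticonservative relative to a beta-binomial model — a known
limitation shared by several published window callers.

q-values are BH step-up computed **within each context** (the criteria
differ per context, and CHH windows outnumber CG windows several-fold;
a joint correction would let the abundant context set the threshold for
the rare one). All criteria comparisons are inclusive (≥, ≤) exactly as
printed: CG/CHG ≥ 5 sites, |Δ| ≥ 0.25; CHH ≥ 15 sites, |Δ| ≥ 0.15;
q ≤ 0.05. Direction is the sign of treatment − control.

Windows covered in only one group are ineligible (p = NaN), never
"significant by absence".

### Numerical notes

The two-sided Fisher p uses the minimum-likelihood definition (sum of
all hypergeometric outcomes with probability ≤ 1+1e-7 times the observed
table's), the same convention as R's `fisher.test` and scipy. The pmf
is evaluated in log space via `gammaln` (relative error ~1e-12), which
keeps half a million windows testable in seconds; unit tests verify
agreement with `scipy.stats.fisher_exact` and with exact big-integer
enumeration. The same construction is used for the exact binomial test
in the expression module.

## Expression

FPKM = count / ((length/10³)·(library/10⁶)); gene length is the
annotated gene span, and library size defaults to the column sum of the
count matrix. The DE statistic is an exact two-sided binomial test of
the pooled treatment count against the treatment share of the pooled
library — deterministic, assumption-light and oracle-checkable. It does
not model biological dispersion, so absolute DEG counts on strongly
overdispersed data will exceed those of a negative-binomial fit; the
strict thresholds (p < 0.001 *strict*, |log₂FC| ≥ 2 *inclusive*) do the
heavy lifting in the planted-truth setting this package targets.

log₂FC compares condition-mean FPKMs with a pseudo-value of 10⁻³ FPKM
*substituted* for a zero (or sub-10⁻³) mean rather than added to every
mean: adding a constant to both means would make a 1-vs-4 FPKM gene miss
the |log₂FC| ≥ 2 boundary by the epsilon, which is not what the
threshold intends.

QC uses log₂(FPKM+1): sample–sample Pearson correlation (zero-variance
samples flagged NaN) and PCA via SVD of the gene-centred sample matrix,
with component signs canonicalised so the largest-magnitude gene loading
is positive.

## Integration

A DMR associates with a gene when it overlaps the gene body ± 2 kb —
the same regional scheme as the metaprofile. The genic region label
(upstream2k / body / downstream2k, strand-aware: upstream is 5′) is
assigned by the DMR midpoint; a midpoint exactly on a gene boundary is
body. A DMR may associate with several genes. A DMG is a DEG with ≥ 1
associated DMR of the given context, one record per (gene, context);
an optional filter restricts which genic regions qualify (default: any
region — the DMG definition in the emulated study names none).

Enrichment is the hypergeometric upper tail P[X ≥ overlap] per term with
BH q-values over tested terms; the universe defaults to all genes with
≥ 1 annotation. Top-k figures are the k smallest p. Raw p < 0.01 is the
conventional significance line; q is always reported alongside.

qPCR relative quantification is 2^−ΔΔCt; platform concordance counts
sign agreement between log₂ of the qPCR fold and the RNA-seq log₂FC
(zero against non-zero is discordant).

## Synthetic data generator

The generator emulates a two-condition (control / freezing-treatment),
three-replicate plant WGBS + RNA-seq study:

* **Genome**: uniform-ACGT random chromosomes (every 200-bp tile holds
  ~50 cytosines per strand in expectation), non-overlapping genes on
  both strands packed with random gaps; infeasible packing errors out.
* **Methylome**: coverage ~ Poisson(depth), methylated count ~
  Binomial(coverage, p); p depends on context and region — flank-like
  (intergenic) vs gene-body levels, defaults CG 0.75/0.50,
  CHG 0.35/0.18, CHH 0.115/0.06. With ~35–40% of the genome in gene
  bodies these land near the Brassica-like genome-wide weighted levels
  (≈0.65/0.29/0.10) with the flank-high/body-low dip, so the metaprofile
  shape is a recoverable property, not a hard-coded curve. Bisulfite
  non-conversion (default 0.01) is a false-methylation probability
  p_obs = p + (1−p)·fail; an optional unmethylated spike-in chromosome
  supports conversion-rate estimation. Optional per-replicate level
  jitter (default 0: the emulated study reports no replicate variance).
* **Planted DMRs** are tile-aligned on the caller's 200-bp grid, so
  sensitivity is evaluable without partial-overlap ambiguity; the
  treatment p is shifted by a signed delta, clipped to [0,1] with a
  warning. Feasible delta signs follow from the base levels: CG effects
  are planted as hypomethylation (−Δ), CHG and CHH as hypermethylation
  (+Δ). Linked DMRs take the tile containing a gene's midpoint;
  unlinked ones are drawn ≥ flank + one tile away from every gene, so
  they can never associate.
* **Counts**: NB(mean, dispersion) with mean = mean_expression·(length
  /1 kb)·a log-normal per-gene baseline factor (sd 1.2 on the natural
  log). The baseline spread matters: FPKM divides length out, and
  without between-gene dynamic range, replicate-correlation QC would
  measure pure noise. Planted DEGs are planted *at* the configured mean
  (baseline 1) — the truth object is "a gene expressed at mean m with
  fold change 2^lfc", not a fold change on an arbitrarily silent gene —
  and the treatment mean is multiplied by 2^lfc.
* **Determinism**: every sample draws from its own RNG stream keyed on
  the master seed (numpy SeedSequence on (seed, stage, condition,
  replicate)), so adding replicates never perturbs existing ones and a
  fixed seed is bit-reproducible.

What it does **not** emulate: read-level errors and mapping bias,
PCR duplicates, M-bias, bimodal per-site methylation states (every site
of a context/region shares one underlying level), CNVs, overdispersion
of methylation counts beyond binomial, and isoform structure. Passing
tests therefore demonstrate correctness of the statistics and
bookkeeping under the stated model, not robustness to real-data
artefacts.

## Pipeline

`run_pipeline` is deterministic given inputs + seed: TSV outputs use a
fixed float format and are byte-identical across reruns; the manifest
records every threshold, input SHA-256 checksums, library versions and
per-stage row counts (sites read, sites passing coverage, windows
tested, DMRs, DEGs, DMGs) so the set-size bookkeeping is auditable. The
config file is flat `key = value` text with CLI overrides; the study
thresholds are the immutable defaults unless overridden. Any stage
failure aborts with the stage name and cause.

The demo study uses two 300-kb chromosomes, 150 genes, depth 30, three
replicates and a 20-kb spike-in; the validation suite additionally runs
50 random 10-kb methylomes against a brute-force re-enumeration oracle,
20 seeded 1-Mb null methylomes (5,000 windows per context each) for
false-call calibration, a 2,000-gene transcriptome for DEG recovery and
replicate QC (the type-I-error check uses 20,000 null Poisson genes),
and a 500-gene, depth-30 metaprofile-shape study. These sizes keep the
whole suite comfortably interactive while leaving each check
well-powered.

## Known limitations

* Pooled Fisher testing ignores replicate dispersion (see above); a
  beta-binomial or replicate-aware test would be the next step and can
  be slotted into the pluggable test interface.
* The DE test is not a substitute for dispersion-modelling DE tools on
  real overdispersed data.
* Enrichment treats terms independently (no ontology DAG propagation,
  no pathway topology).
* Gene "length" for FPKM is the genomic span, not an exon-model
  effective length.
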