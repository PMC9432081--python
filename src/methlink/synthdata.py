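"""Synthetic WGBS + RNA-seq data with planted, recoverable truth.

The generator emulates the data model of a plant freezing-stress
methylome/transcriptome study: random genomes with non-overlapping genes
on both strands; per-cytosine bisulfite reports in which coverage is
Poisson and the methylated count binomial with a context- and
region-dependent success probability (flank-like/intergenic regions high,
gene bodies low, CG >> CHG >> CHH); differential methylation planted as
tile-aligned windows whose treatment-level probability is shifted by a
configurable delta; and negative-binomial gene counts with planted fold
changes, optionally on genes linked to planted DMRs.  Bisulfite
non-conversion is modelled as a small false-methylation probability and
an optional fully-unmethylated spike-in chromosome supports
conversion-rate estimation.

Every sample draws from its own RNG stream derived from the master seed,
so adding replicates never perturbs existing ones, and a fixed seed gives
bit-identical outputs.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome import CONTEXTS, REPORT_COLUMNS, classify_genome

#: chromosome name of the unmethylated spike-in control
CONTROL_CHROM = "chrUn_lambda"

_BASES = np.array(["A", "C", "G", "T"])

# (flank-like, gene-body) background methylation probability per context.
# Chosen so a genome with ~35-40% of its span in gene bodies lands near
# the CG >> CHG >> CHH ordering typical of Brassica (genome-wide weighted
# levels around 0.66 / 0.29 / 0.095) with the flank-high/body-low dip.
DEFAULT_BASE_LEVELS = {
    "CG": (0.75, 0.50),
    "CHG": (0.35, 0.18),
    "CHH": (0.115, 0.06),
}


@dataclasses.dataclass
class PlantedDMR:
    """Ground-truth differential window (tile-aligned on the caller grid)."""

    chrom: str
    start: int
    end: int
    context: str
    delta: float                 # treatment level minus control level
    linked_gene: str | None = None

    def __post_init__(self):
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("|delta| must be <= 1")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclasses.dataclass
class PlantedDEG:
    """Ground-truth differentially expressed gene."""

    gene_id: str
    log2_fold_change: float
    direction: str               # 'up' | 'down'

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if (self.direction == "up") != (self.log2_fold_change > 0):
            raise ValueError("direction inconsistent with log2_fold_change sign")


@dataclasses.dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study design: two conditions x three
    replicates, ~30x cytosine coverage, three contexts with
    flank-high/body-low background levels, negative-binomial counts.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_genes: int = 150
    gene_length_range: tuple = (800, 2500)
    flank: int = 2000
    base_levels: Mapping[str, tuple] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BASE_LEVELS))
    planted_dmrs: list = dataclasses.field(default_factory=list)
    planted_degs: list = dataclasses.field(default_factory=list)
    depth: float = 30.0
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    mean_expression: float = 200.0
    expression_log_sd: float = 1.2      # per-gene baseline spread (ln scale)
    conversion_failure: float = 0.01
    control_chrom_length: int = 0       # >0 adds an unmethylated spike-in
    replicate_jitter: float = 0.0       # sd of per-replicate level shift
    window: int = 200                   # tile grid for planted DMRs

    def validate(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.n_chrom < 1 or self.chrom_length < 1 or self.n_genes < 0:
            raise ValueError("genome dimensions must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.expression_log_sd < 0:
            raise ValueError("expression_log_sd must be >= 0")
        lo, hi = self.gene_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad gene_length_range")
        for ctx in CONTEXTS:
            for level in self.base_levels[ctx]:
                if not 0.0 <= level <= 1.0:
                    raise ValueError("base levels must be probabilities")
        if not 0.0 <= self.conversion_failure < 1.0:
            raise ValueError("conversion_failure must be in [0, 1)")


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    """Independent RNG stream keyed on the master seed (stable hashing)."""
    return np.random.default_rng([int(cfg.seed)] + [int(s) for s in stream])


def chrom_names(cfg: SimConfig) -> list:
    return [f"chr{i + 1}" for i in range(cfg.n_chrom)]


def generate_genome(cfg: SimConfig) -> tuple[dict, pd.DataFrame]:
    """Random genome plus non-overlapping gene annotation.

    Sequences are uniform over ACGT (every 200-bp tile holds ~50
    cytosines per strand in expectation); genes are packed per chromosome
    with random gaps >= 1 bp and random strands.  Raises ValueError when
    the requested genes cannot fit.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    genome = {}
    for chrom in chrom_names(cfg):
        genome[chrom] = "".join(
            _BASES[rng.integers(0, 4, size=cfg.chrom_length)])
    if cfg.control_chrom_length > 0:
        genome[CONTROL_CHROM] = "".join(
            _BASES[rng.integers(0, 4, size=cfg.control_chrom_length)])

    per_chrom = np.full(cfg.n_chrom, cfg.n_genes // cfg.n_chrom)
    per_chrom[: cfg.n_genes % cfg.n_chrom] += 1
    rows = []
    gene_no = 0
    lo, hi = cfg.gene_length_range
    for chrom, n in zip(chrom_names(cfg), per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        free = cfg.chrom_length - int(lengths.sum()) - (n + 1)
        if free < 0:
            raise ValueError(
                f"cannot pack {n} genes of total length {lengths.sum()} "
                f"into {chrom} ({cfg.chrom_length} bp)")
        props = rng.dirichlet(np.ones(n + 1))
        gaps = np.floor(props * free).astype(int) + 1
        start = 0
        for i in range(n):
            start += gaps[i]
            gene_no += 1
            rows.append({"gene_id": f"g{gene_no:04d}", "chrom": chrom,
                         "start": start + 1, "end": start + int(lengths[i]),
                         "strand": "+" if rng.random() < 0.5 else "-"})
            start += int(lengths[i])
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand"])
    return genome, genes


def make_planted_dmrs(cfg: SimConfig, genes: pd.DataFrame,
                      n_unlinked: Mapping[str, int],
                      delta: Mapping[str, float],
                      linked_genes: Mapping[str, Sequence[str]] | None = None
                      ) -> list:
    """Choose tile-aligned planted DMRs on the caller's window grid.

    Linked DMRs take the tile containing the gene midpoint (guaranteed
    body overlap); unlinked DMRs are drawn from tiles at least
    flank + one tile clear of every gene, so they can never associate
    with a gene.  All chosen tiles are distinct.
    """
    rng = _rng(cfg, 3)
    w = cfg.window
    linked_genes = linked_genes or {}
    by_gene = genes.set_index("gene_id")
    taken = set()
    planted = []

    for ctx in CONTEXTS:
        for gid in linked_genes.get(ctx, []):
            g = by_gene.loc[gid]
            tile = int((g["start"] + g["end"]) // 2 - 1) // w
            key = (g["chrom"], tile)
            if key in taken:
                raise ValueError(f"tile collision planting DMR on {gid}")
            taken.add(key)
            planted.append(PlantedDMR(
                chrom=g["chrom"], start=tile * w + 1, end=(tile + 1) * w,
                context=ctx, delta=float(delta[ctx]), linked_gene=gid))

    n_tiles = cfg.chrom_length // w
    forbidden = {chrom: set() for chrom in chrom_names(cfg)}
    margin = cfg.flank + w
    for g in genes.itertuples(index=False):
        lo = max(0, (g.start - margin - 1) // w)
        hi = min(n_tiles - 1, (g.end + margin - 1) // w)
        forbidden[g.chrom].update(range(lo, hi + 1))
    candidates = [(chrom, t) for chrom in chrom_names(cfg)
                  for t in range(n_tiles)
                  if t not in forbidden[chrom] and (chrom, t) not in taken]
    rng.shuffle(candidates)
    pos = 0
    for ctx in CONTEXTS:
        need = int(n_unlinked.get(ctx, 0))
        if pos + need > len(candidates):
            raise ValueError("not enough intergenic tiles for planted DMRs")
        for chrom, tile in candidates[pos: pos + need]:
            planted.append(PlantedDMR(
                chrom=chrom, start=tile * w + 1, end=(tile + 1) * w,
                context=ctx, delta=float(delta[ctx]), linked_gene=None))
        pos += need
    return planted


def planted_dmr_table(planted: Sequence[PlantedDMR]) -> pd.DataFrame:
    rows = [dataclasses.asdict(p) for p in planted]
    cols = ["chrom", "start", "end", "context", "delta", "linked_gene"]
    return pd.DataFrame(rows, columns=cols)


def planted_deg_table(planted: Sequence[PlantedDEG]) -> pd.DataFrame:
    rows = [dataclasses.asdict(p) for p in planted]
    return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change",
                                       "direction"])


def _site_table(genome: Mapping[str, str]) -> dict:
    """Per-chromosome cytosine site frames (pos, strand, context, tri)."""
    return {chrom: classify_genome(seq) for chrom, seq in genome.items()}


def _base_probability(cfg: SimConfig, chrom: str, sites: pd.DataFrame,
                      genes: pd.DataFrame) -> np.ndarray:
    """Underlying methylation probability per site (before non-conversion)."""
    if chrom == CONTROL_CHROM:
        return np.zeros(len(sites))
    gsub = genes[genes["chrom"] == chrom].sort_values("start")
    pos = sites["pos"].to_numpy()
    if len(gsub) == 0:
        in_body = np.zeros(len(sites), dtype=bool)
    else:
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        in_body = (idx >= 0) & (pos <= ends[np.maximum(idx, 0)])
    p = np.empty(len(sites))
    for ctx in CONTEXTS:
        flank_level, body_level = cfg.base_levels[ctx]
        mask = (sites["context"] == ctx).to_numpy()
        p[mask] = np.where(in_body[mask], body_level, flank_level)
    return p


def generate_methylome(cfg: SimConfig, genome: Mapping[str, str],
                       genes: pd.DataFrame
                       ) -> tuple[dict, pd.DataFrame]:
    """Per-sample cytosine reports plus the planted-DMR truth table.

    Coverage ~ Poisson(depth); methylated count ~ Binomial(coverage,
    p_obs) with p_obs = p + (1-p) * non-conversion, where p is the
    context/region base level, shifted by the planted delta (clipped to
    [0,1] with a warning) inside planted windows for treatment samples.
    Returns ({(condition, replicate): report frame}, truth table).
    """
    cfg.validate()
    site_tables = _site_table(genome)
    base_p = {chrom: _base_probability(cfg, chrom, sites, genes)
              for chrom, sites in site_tables.items()}

    treat_p = {chrom: p.copy() for chrom, p in base_p.items()}
    for dmr in cfg.planted_dmrs:
        sites = site_tables[dmr.chrom]
        mask = ((sites["pos"].to_numpy() >= dmr.start)
                & (sites["pos"].to_numpy() <= dmr.end)
                & (sites["context"].to_numpy() == dmr.context))
        shifted = base_p[dmr.chrom][mask] + dmr.delta
        if np.any((shifted < 0) | (shifted > 1)):
            warnings.warn(
                f"planted delta at {dmr.chrom}:{dmr.start}-{dmr.end} "
                f"pushes methylation outside [0,1]; clipping")
        treat_p[dmr.chrom][mask] = np.clip(shifted, 0.0, 1.0)

    reports = {}
    for cond_idx, (condition, probs) in enumerate(
            (("control", base_p), ("treatment", treat_p))):
        for rep in range(1, cfg.n_replicates + 1):
            rng = _rng(cfg, 1, cond_idx, rep)
            frames = []
            for chrom, sites in site_tables.items():
                p = probs[chrom]
                if cfg.replicate_jitter > 0:
                    p = np.clip(p + rng.normal(0, cfg.replicate_jitter,
                                               size=p.shape), 0.0, 1.0)
                p_obs = p + (1.0 - p) * cfg.conversion_failure
                cov = rng.poisson(cfg.depth, size=len(sites))
                meth = rng.binomial(cov, p_obs)
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos": sites["pos"].to_numpy(),
                    "strand": sites["strand"].to_numpy(),
                    "meth": meth, "unmeth": cov - meth,
                    "context": sites["context"].to_numpy(),
                    "tri": sites["tri"].to_numpy()}))
            reports[(condition, rep)] = pd.concat(
                frames, ignore_index=True)[REPORT_COLUMNS]
    return reports, planted_dmr_table(cfg.planted_dmrs)


def generate_counts(cfg: SimConfig, genes: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted DEGs.

    Per-gene mean scales with gene length (mean_expression fragments per
    kb) times a log-normal per-gene baseline factor (sd
    ``expression_log_sd`` on the natural-log scale) — real transcriptomes
    span orders of magnitude, and without that spread replicate
    correlations would be meaningless.  Treatment means are multiplied by
    2^log2fc for planted DEGs.  With nb_dispersion = 0 counts are
    Poisson.  Returns (counts genes x samples, sample sheet, planted-DEG
    truth table).
    """
    cfg.validate()
    lengths = (genes["end"] - genes["start"] + 1).to_numpy(float)
    gene_rng = _rng(cfg, 4)
    baseline = pd.Series(
        np.exp(gene_rng.normal(0.0, cfg.expression_log_sd,
                               size=len(genes))),
        index=genes["gene_id"])
    fold = pd.Series(0.0, index=genes["gene_id"])
    seen = set()
    for deg in cfg.planted_degs:
        if deg.gene_id in seen:
            raise ValueError(f"duplicate planted DEG {deg.gene_id}")
        seen.add(deg.gene_id)
        fold[deg.gene_id] = deg.log2_fold_change
        # planted DEGs sit at the configured mean expression: the truth
        # object is "a gene expressed at mean_expression with this fold
        # change", not a fold change on an arbitrarily silent gene
        baseline[deg.gene_id] = 1.0
    mu_base = cfg.mean_expression * lengths / 1000.0 * baseline.to_numpy()
    mu_treat = mu_base * np.power(2.0, fold.to_numpy())

    columns = {}
    sheet = []
    for cond_idx, (condition, mu) in enumerate(
            (("control", mu_base), ("treatment", mu_treat))):
        for rep in range(1, cfg.n_replicates + 1):
            rng = _rng(cfg, 2, cond_idx, rep)
            if cfg.nb_dispersion > 0:
                r = 1.0 / cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            name = f"{condition}_{rep}"
            columns[name] = counts
            sheet.append({"sample": name, "condition": condition,
                          "replicate": rep})
    counts = pd.DataFrame(columns, index=genes["gene_id"])
    counts.index.name = "gene_id"
    return counts, pd.DataFrame(sheet), planted_deg_table(cfg.planted_degs)
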