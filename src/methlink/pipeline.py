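"""End-to-end pipeline: methylome stats -> DMRs -> DEGs -> DMGs -> summaries.

``run_pipeline`` orchestrates the full analysis from files on disk and
writes every stage's table as TSV plus a run manifest (configuration,
input checksums, library versions, per-stage row counts).  ``demo``
generates a complete synthetic study with planted truth, runs the
pipeline on it, and scores the calls against the truth tables —
a self-contained end-to-end check that needs no external data.

All defaults are the study thresholds: 200-bp windows, per-site coverage
floor 4, CG/CHG >= 5 sites & |diff| >= 0.25, CHH >= 15 & |diff| >= 0.15,
q <= 0.05, DEGs at p < 0.001 & |log2FC| >= 2, 2-kb flanks.  Outputs are
byte-identical across reruns with the same inputs and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dmr, expression, integrate, io, methylome, synthdata

logger = logging.getLogger("methlink")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""


@dataclasses.dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run (defaults = study values)."""

    genome: str = ""
    annotation: str = ""
    methylome_sheet: str = ""       # TSV: sample, condition, replicate, path
    counts: str = ""
    sample_sheet: str = ""          # TSV: sample, condition, replicate
    term_map: str = ""              # optional TSV: gene_id, term
    family_map: str = ""            # optional TSV: gene_id, family
    out_dir: str = "methlink_out"
    comparison: str = "treatment-vs-control"

    window_size: int = 200
    step: int = 0                   # 0 -> non-overlapping tiles
    min_sites_cg: int = 5
    min_sites_chg: int = 5
    min_sites_chh: int = 15
    min_diff_cg: float = 0.25
    min_diff_chg: float = 0.25
    min_diff_chh: float = 0.15
    max_q: float = 0.05
    min_cov: int = 4
    deg_p_max: float = 0.001
    deg_min_abs_lfc: float = 2.0
    flank: int = 2000
    flank_bins: int = 20
    body_bins: int = 20
    non_conversion: float = 0.01
    seed: int = 0
    control_chrom: str = synthdata.CONTROL_CHROM

    @property
    def criteria(self) -> dmr.DMRCriteria:
        return dmr.DMRCriteria(
            window_size=self.window_size,
            step=self.step or None,
            min_sites={"CG": self.min_sites_cg, "CHG": self.min_sites_chg,
                       "CHH": self.min_sites_chh},
            min_abs_diff={"CG": self.min_diff_cg, "CHG": self.min_diff_chg,
                          "CHH": self.min_diff_chh},
            max_q=self.max_q, min_cov=self.min_cov)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path, **overrides):
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path} line {lineno}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path} line {lineno}: unknown key {key!r}")
                kwargs[key] = casts[types[key]](value)
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _require(path, what: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise PipelineError(f"missing {what} file: {path!r}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write TSV outputs + manifest under out_dir.

    Returns the result bundle as a dict of DataFrames/values.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    counts_log: dict = {}
    checksums: dict = {}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return deco

    @stage("load-inputs")
    def _():
        genome_path = _require(config.genome, "genome FASTA")
        annot_path = _require(config.annotation, "gene annotation")
        checksums["genome"] = _sha256(genome_path)
        checksums["annotation"] = _sha256(annot_path)
        bundle["genome"] = io.read_fasta(genome_path)
        bundle["genes"] = io.read_genes(annot_path)
        bundle["chrom_lengths"] = {c: len(s) for c, s in
                                   bundle["genome"].items()
                                   if c != config.control_chrom}
        sheet_path = _require(config.methylome_sheet, "methylome sample sheet")
        checksums["methylome_sheet"] = _sha256(sheet_path)
        sheet = io.read_tsv(sheet_path)
        reports = {}
        for row in sheet.itertuples(index=False):
            rpath = _require(row.path, f"cytosine report for {row.sample}")
            checksums[f"report:{row.sample}"] = _sha256(rpath)
            reports[(row.condition, int(row.replicate))] = \
                methylome.read_cx_report(rpath)
        bundle["reports"] = reports
        counts_log["n_samples_methylome"] = len(reports)
        counts_log["n_sites_read"] = int(sum(len(r) for r in reports.values()))
        counts_log["n_genes_annotated"] = len(bundle["genes"])

    @stage("methylome-stats")
    def _():
        reports = bundle["reports"]
        summaries = []
        conv_rows = []
        for condition in ("control", "treatment"):
            pooled = pd.concat([r for (c, _), r in reports.items()
                                if c == condition], ignore_index=True)
            main = pooled[pooled["chrom"] != config.control_chrom]
            filtered = methylome.filter_by_coverage(main, config.min_cov)
            summary = methylome.context_proportions(
                filtered, non_conversion=config.non_conversion)
            for ctx in methylome.CONTEXTS:
                summaries.append({
                    "condition": condition, "context": ctx,
                    "n_called_sites": summary.site_counts[ctx],
                    "site_proportion": summary.proportions[ctx],
                    "weighted_level": summary.weighted_levels[ctx]})
            bundle[f"summary_{condition}"] = summary
            bundle[f"metaprofile_{condition}"] = methylome.metaprofile(
                filtered, bundle["genes"], flank=config.flank,
                flank_bins=config.flank_bins, body_bins=config.body_bins)
            ctrl = pooled[pooled["chrom"] == config.control_chrom]
            if len(ctrl):
                conv_rows.append({"condition": condition,
                                  "conversion_rate":
                                      methylome.conversion_rate(ctrl)})
        bundle["methylation_summary"] = pd.DataFrame(summaries)
        bundle["conversion_rates"] = pd.DataFrame(
            conv_rows, columns=["condition", "conversion_rate"])
        pooled_all = pd.concat(list(reports.values()), ignore_index=True)
        pooled_all = pooled_all[pooled_all["chrom"] != config.control_chrom]
        bundle["chromosome_profile"] = methylome.chromosome_profile(
            methylome.filter_by_coverage(pooled_all, config.min_cov),
            bundle["genes"], bundle["chrom_lengths"])
        counts_log["n_sites_pass_coverage"] = int(len(
            methylome.filter_by_coverage(pooled_all, config.min_cov)))

    @stage("dmr-calling")
    def _():
        reports = bundle["reports"]
        control = [r for (c, _), r in sorted(reports.items())
                   if c == "control"]
        treatment = [r for (c, _), r in sorted(reports.items())
                     if c == "treatment"]
        windows = dmr.find_dmrs(control, treatment, bundle["chrom_lengths"],
                                config.criteria)
        bundle["dmr_windows"] = windows
        bundle["dmrs"] = windows[windows["is_dmr"]].reset_index(drop=True)
        counts_log["n_windows_tested"] = int(windows["p"].notna().sum())
        counts_log["n_dmrs"] = int(len(bundle["dmrs"]))

    @stage("expression")
    def _():
        counts_path = _require(config.counts, "counts matrix")
        sheet_path = _require(config.sample_sheet, "expression sample sheet")
        checksums["counts"] = _sha256(counts_path)
        checksums["sample_sheet"] = _sha256(sheet_path)
        counts = io.read_tsv(counts_path, index_col=0)
        sheet = io.read_tsv(sheet_path)
        genes = bundle["genes"]
        lengths = pd.Series((genes["end"] - genes["start"] + 1).to_numpy(),
                            index=genes["gene_id"])
        sizes = None
        if "library_size" in sheet.columns:
            sizes = sheet.set_index("sample")["library_size"]
        table = expression.de_table(counts, sheet, lengths, sizes)
        table = expression.call_degs(table, config.deg_p_max,
                                     config.deg_min_abs_lfc)
        fpkm_tab = expression.fpkm(counts, lengths, sizes)
        logf = expression.log_fpkm(fpkm_tab)
        bundle["fpkm"] = fpkm_tab
        bundle["de_table"] = table
        bundle["degs"] = table[table["is_deg"]].reset_index(drop=True)
        bundle["pearson"] = expression.pearson_matrix(logf)
        scores, explained = expression.pca_scores(logf)
        bundle["pca_scores"] = scores
        bundle["pca_explained"] = explained
        counts_log["n_genes_counted"] = int(len(counts))
        counts_log["n_degs"] = int(len(bundle["degs"]))

    @stage("integration")
    def _():
        assoc = integrate.map_dmr_to_genes(bundle["dmrs"], bundle["genes"],
                                           flank=config.flank)
        dmgs = integrate.call_dmgs(assoc, bundle["de_table"],
                                   comparison=config.comparison)
        bundle["dmr_gene_associations"] = assoc
        bundle["dmgs"] = dmgs
        counts_log["n_dmr_gene_associations"] = int(len(assoc))
        counts_log["n_dmgs"] = int(len(dmgs))
        if config.family_map:
            fam_path = _require(config.family_map, "TF family map")
            checksums["family_map"] = _sha256(fam_path)
            fam = io.read_tsv(fam_path)
            bundle["tf_summary"] = integrate.tf_family_summary(dmgs, fam)
        if config.term_map:
            term_path = _require(config.term_map, "gene-term map")
            checksums["term_map"] = _sha256(term_path)
            g2t = io.read_tsv(term_path)
            enr = {}
            for ctx in methylome.CONTEXTS:
                sel = dmgs.loc[dmgs["context"] == ctx, "gene_id"]
                enr[ctx] = integrate.enrich(sel, g2t)
            bundle["enrichment"] = enr

    @stage("write-outputs")
    def _():
        io.write_tsv(bundle["methylation_summary"],
                     out / "methylation_summary.tsv")
        io.write_tsv(bundle["conversion_rates"], out / "conversion_rates.tsv")
        io.write_tsv(bundle["chromosome_profile"],
                     out / "chromosome_profile.tsv")
        for condition in ("control", "treatment"):
            io.write_tsv(bundle[f"metaprofile_{condition}"],
                         out / f"metaprofile_{condition}.tsv")
        io.write_tsv(bundle["dmr_windows"], out / "dmr_windows.tsv")
        io.write_tsv(bundle["dmrs"], out / "dmrs.tsv")
        io.write_tsv(dmr.dmrs_to_bed(bundle["dmr_windows"]),
                     out / "dmrs.bed")
        io.write_tsv(bundle["fpkm"], out / "fpkm.tsv", index=True)
        io.write_tsv(bundle["de_table"].reset_index(drop=True),
                     out / "de_table.tsv")
        io.write_tsv(bundle["degs"], out / "degs.tsv")
        io.write_tsv(bundle["pearson"], out / "pearson.tsv", index=True)
        io.write_tsv(bundle["pca_scores"], out / "pca_scores.tsv", index=True)
        io.write_tsv(bundle["dmr_gene_associations"],
                     out / "dmr_gene_associations.tsv")
        io.write_tsv(bundle["dmgs"], out / "dmgs.tsv")
        if "tf_summary" in bundle:
            io.write_tsv(bundle["tf_summary"], out / "tf_summary.tsv")
        for ctx, enr in bundle.get("enrichment", {}).items():
            io.write_tsv(enr, out / f"enrichment_{ctx}.tsv")
        manifest = {
            "package": "methlink",
            "version": __version__,
            "config": {f.name: getattr(config, f.name)
                       for f in dataclasses.fields(config)},
            "input_checksums": dict(sorted(checksums.items())),
            "library_versions": {
                "numpy": np.__version__, "pandas": pd.__version__},
            "stage_counts": dict(sorted(counts_log.items())),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        bundle["manifest"] = manifest

    return bundle


# ---------------------------------------------------------------------------
# synthetic demo

DEMO_DELTAS = {"CG": -0.40, "CHG": +0.40, "CHH": +0.30}


def _demo_config(seed: int, n_linked: int, n_unlinked: int,
                 n_extra_degs: int, deg_lfc: float) -> synthdata.SimConfig:
    cfg = synthdata.SimConfig(seed=seed, control_chrom_length=20_000)
    _, genes = synthdata.generate_genome(cfg)
    rng = np.random.default_rng([seed, 9])
    # pick link targets with distinct midpoint tiles, then extra DEG genes
    order = list(rng.permutation(genes["gene_id"].to_numpy()))
    by_gene = genes.set_index("gene_id")
    taken_tiles, linked = set(), {ctx: [] for ctx in methylome.CONTEXTS}
    pool = []
    for gid in order:
        g = by_gene.loc[gid]
        tile = (g["chrom"], int((g["start"] + g["end"]) // 2 - 1) // cfg.window)
        if tile in taken_tiles:
            continue
        taken_tiles.add(tile)
        pool.append(gid)
    need = n_linked * len(methylome.CONTEXTS)
    if len(pool) < need + n_extra_degs:
        raise ValueError("demo genome too small for requested planting")
    for i, ctx in enumerate(methylome.CONTEXTS):
        linked[ctx] = pool[i * n_linked:(i + 1) * n_linked]
    cfg.planted_dmrs = synthdata.make_planted_dmrs(
        cfg, genes, n_unlinked={ctx: n_unlinked for ctx in methylome.CONTEXTS},
        delta=DEMO_DELTAS, linked_genes=linked)
    deg_genes = pool[need:need + n_extra_degs] + [g for ctx in
                                                  methylome.CONTEXTS
                                                  for g in linked[ctx]]
    cfg.planted_degs = [
        synthdata.PlantedDEG(gene_id=g,
                             log2_fold_change=deg_lfc if i % 2 == 0
                             else -deg_lfc,
                             direction="up" if i % 2 == 0 else "down")
        for i, g in enumerate(sorted(deg_genes))]
    return cfg


def _demo_maps(genes: pd.DataFrame, cfg: synthdata.SimConfig,
               seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene->pathway and gene->TF-family maps."""
    rng = np.random.default_rng([seed, 10])
    gene_ids = genes["gene_id"].to_numpy()
    linked = sorted({d.linked_gene for d in cfg.planted_dmrs
                     if d.linked_gene})
    terms = [f"pathway_{i:02d}" for i in range(8)]
    rows = [{"gene_id": g, "term": "pathway_hormone_signalling"}
            for g in linked]
    rows += [{"gene_id": g, "term": terms[int(rng.integers(0, len(terms)))]}
             for g in gene_ids]
    term_map = pd.DataFrame(rows).drop_duplicates(ignore_index=True)

    families = ["AP2/ERF", "WRKY", "NAC", "HSF", "bHLH", "MYB", "TIFY", "C2C2"]
    tf_genes = sorted(set(linked[: max(1, len(linked) // 2)])
                      | set(rng.choice(gene_ids, size=min(30, len(gene_ids)),
                                       replace=False)))
    fam_map = pd.DataFrame({
        "gene_id": tf_genes,
        "family": [families[int(rng.integers(0, len(families)))]
                   for _ in tf_genes]})
    return term_map, fam_map


def _score_calls(bundle: dict, truth_dmrs: pd.DataFrame,
                 truth_degs: pd.DataFrame, flank: int = 2000) -> dict:
    """Sensitivity/precision of DMR, DEG and DMG calls vs planted truth."""
    called = bundle["dmrs"]
    called_keys = set(zip(called["chrom"], called["start"],
                          called["context"]))
    truth_keys = set(zip(truth_dmrs["chrom"], truth_dmrs["start"],
                         truth_dmrs["context"]))
    report = {}
    for ctx in methylome.CONTEXTS:
        t = {k for k in truth_keys if k[2] == ctx}
        c = {k for k in called_keys if k[2] == ctx}
        report[f"dmr_sensitivity_{ctx}"] = (len(t & c) / len(t)) if t else \
            float("nan")
        report[f"dmr_precision_{ctx}"] = (len(t & c) / len(c)) if c else \
            float("nan")
    report["dmr_sensitivity"] = (len(truth_keys & called_keys)
                                 / len(truth_keys)) if truth_keys else \
        float("nan")
    report["dmr_precision"] = (len(truth_keys & called_keys)
                               / len(called_keys)) if called_keys else \
        float("nan")

    deg_called = set(bundle["degs"]["gene_id"])
    deg_truth = set(truth_degs["gene_id"])
    report["deg_sensitivity"] = (len(deg_truth & deg_called)
                                 / len(deg_truth)) if deg_truth else \
        float("nan")
    report["deg_precision"] = (len(deg_truth & deg_called)
                               / len(deg_called)) if deg_called else \
        float("nan")

    # expected DMGs: recovered planted DMRs associated (body +/- flank,
    # same rule as the pipeline) with genes recovered as planted DEGs
    recovered = truth_dmrs[[
        (c, s, x) in called_keys
        for c, s, x in zip(truth_dmrs["chrom"], truth_dmrs["start"],
                           truth_dmrs["context"])]]
    expected = set()
    if len(recovered):
        assoc = integrate.map_dmr_to_genes(
            recovered.assign(direction=""), bundle["genes"], flank=flank)
        for row in assoc.itertuples(index=False):
            if row.gene_id in (deg_truth & deg_called):
                expected.add((row.gene_id, row.context))
    observed = set(zip(bundle["dmgs"]["gene_id"], bundle["dmgs"]["context"]))
    report["dmg_expected"] = len(expected)
    report["dmg_observed"] = len(observed)
    report["dmg_exact_match"] = float(expected == observed)
    return report


def demo(seed: int = 7, out_dir: str = "methlink_demo", n_linked: int = 4,
         n_unlinked: int = 8, n_extra_degs: int = 8,
         deg_lfc: float = 3.0) -> dict:
    """Self-contained synthetic run: generate, pipeline, score vs truth.

    Writes the generated inputs under ``out_dir/inputs``, pipeline outputs
    under ``out_dir/results`` and a truth-vs-called report under
    ``out_dir/truth_report.json``.  Returns the result bundle extended
    with the truth tables and the report.
    """
    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    cfg = _demo_config(seed, n_linked, n_unlinked, n_extra_degs, deg_lfc)
    genome, genes = synthdata.generate_genome(cfg)
    reports, truth_dmrs = synthdata.generate_methylome(cfg, genome, genes)
    counts, sheet, truth_degs = synthdata.generate_counts(cfg, genes)
    term_map, fam_map = _demo_maps(genes, cfg, seed)

    io.write_fasta(genome, inputs / "genome.fa")
    io.write_gff3(genes, inputs / "genes.gff3")
    io.write_bed6(genes, inputs / "genes.bed")
    meth_rows = []
    for (condition, rep), frame in sorted(reports.items()):
        path = inputs / f"cx_{condition}_{rep}.tsv"
        methylome.write_cx_report(frame, path)
        meth_rows.append({"sample": f"{condition}_{rep}",
                          "condition": condition, "replicate": rep,
                          "path": str(path)})
    io.write_tsv(pd.DataFrame(meth_rows), inputs / "methylome_sheet.tsv")
    io.write_tsv(counts, inputs / "counts.tsv", index=True)
    io.write_tsv(sheet, inputs / "sample_sheet.tsv")
    io.write_tsv(term_map, inputs / "term_map.tsv")
    io.write_tsv(fam_map, inputs / "family_map.tsv")
    io.write_tsv(truth_dmrs, inputs / "truth_dmrs.tsv")
    io.write_tsv(truth_degs, inputs / "truth_degs.tsv")

    config = PipelineConfig(
        genome=str(inputs / "genome.fa"),
        annotation=str(inputs / "genes.gff3"),
        methylome_sheet=str(inputs / "methylome_sheet.tsv"),
        counts=str(inputs / "counts.tsv"),
        sample_sheet=str(inputs / "sample_sheet.tsv"),
        term_map=str(inputs / "term_map.tsv"),
        family_map=str(inputs / "family_map.tsv"),
        out_dir=str(out / "results"),
        seed=seed)
    bundle = run_pipeline(config)

    report = _score_calls(bundle, truth_dmrs, truth_degs,
                          flank=config.flank)
    with open(out / "truth_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle.update({"truth_dmrs": truth_dmrs, "truth_degs": truth_degs,
                   "truth_report": report, "sim_config": cfg,
                   "pipeline_config": config})
    return bundle
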