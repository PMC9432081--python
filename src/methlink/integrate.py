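"""Methylome-transcriptome integration: DMGs and downstream summaries.

A differentially methylated gene (DMG) is a differentially expressed gene
(DEG) associated with at least one DMR of a given context.  Association
uses the same regional scheme as the methylation metaprofile: a DMR is
linked to a gene when it overlaps the gene body extended by a 2-kb flank
on each side; the genic region label (upstream2k / body / downstream2k)
is assigned from the sub-region containing the DMR midpoint, with
"upstream" meaning 5' of the gene on its own strand and boundary
positions belonging to the body.

Downstream summaries: three-set Venn partitions of DMG sets across
comparisons, expression-direction consistency of shared DMGs,
transcription-factor family tallies, hypergeometric (upper-tail)
pathway/term enrichment with BH q-values, qPCR relative quantification
(2^-ddCt) and RNA-seq/qPCR direction concordance.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust

REGIONS = ("upstream2k", "body", "downstream2k")


@dataclasses.dataclass
class VennPartition:
    """Exact 7-region partition of three sets."""

    a_only: set
    b_only: set
    c_only: set
    ab: set
    ac: set
    bc: set
    abc: set

    @property
    def shared(self) -> set:
        return self.abc

    @property
    def region_sizes(self) -> dict:
        return {k: len(getattr(self, k))
                for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")}

    @property
    def union_size(self) -> int:
        return sum(self.region_sizes.values())


def map_dmr_to_genes(dmrs: pd.DataFrame, genes: pd.DataFrame,
                     flank: int = 2000) -> pd.DataFrame:
    """Associate DMRs with genes they overlap within gene body +/- flank.

    ``dmrs`` needs chrom/start/end/context (1-based inclusive) plus any
    carry-through columns (e.g. direction); ``genes`` needs
    gene_id/chrom/start/end/strand.  A DMR may hit several genes.  The
    region label is decided by the DMR midpoint: before the gene start on
    the 5' side -> upstream2k, past the end -> downstream2k, otherwise
    body (strand-aware; midpoint exactly on a gene boundary is body).
    """
    rows = []
    dmrs = dmrs.reset_index(drop=True)
    for chrom, gsub in genes.groupby("chrom", sort=False):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        d_start = dsub["start"].to_numpy()
        d_end = dsub["end"].to_numpy()
        mid = (d_start + d_end) // 2
        for g in gsub.itertuples(index=False):
            hit = (d_end >= g.start - flank) & (d_start <= g.end + flank)
            if not hit.any():
                continue
            m = mid[hit]
            before = m < g.start
            after = m > g.end
            if g.strand == "-":
                before, after = after, before
            region = np.where(before, "upstream2k",
                              np.where(after, "downstream2k", "body"))
            for i, (didx, reg) in enumerate(zip(dsub.index[hit], region)):
                row = {"gene_id": g.gene_id, "dmr_index": int(didx),
                       "region": reg}
                rows.append(row)
    assoc = pd.DataFrame(rows, columns=["gene_id", "dmr_index", "region"])
    if not assoc.empty:
        assoc = assoc.merge(
            dmrs[[c for c in ("chrom", "start", "end", "context", "direction")
                  if c in dmrs.columns]],
            left_on="dmr_index", right_index=True)
    return assoc


def call_dmgs(associations: pd.DataFrame, deg_table: pd.DataFrame,
              comparison: str = "", regions: Iterable[str] | None = None
              ) -> pd.DataFrame:
    """DMGs: DEGs with >= 1 associated DMR, one row per (gene, context).

    ``associations`` comes from :func:`map_dmr_to_genes`; ``deg_table``
    from :func:`methlink.expression.call_degs`.  ``regions`` optionally
    restricts which genic regions count (default: any).  Methylation
    direction is that of the associated DMRs ('mixed' when they disagree).
    """
    degs = deg_table[deg_table["is_deg"]]
    if associations.empty or degs.empty:
        return pd.DataFrame(columns=["gene_id", "context", "n_dmrs",
                                     "regions", "meth_direction",
                                     "expr_direction", "comparison"])
    assoc = associations[associations["gene_id"].isin(degs["gene_id"])]
    if regions is not None:
        assoc = assoc[assoc["region"].isin(set(regions))]
    rows = []
    for (gene, ctx), sub in assoc.groupby(["gene_id", "context"], sort=True):
        meth_dirs = set(sub["direction"]) if "direction" in sub else set()
        meth_dirs.discard("")
        meth = meth_dirs.pop() if len(meth_dirs) == 1 else (
            "mixed" if meth_dirs else "")
        rows.append({
            "gene_id": gene, "context": ctx,
            "n_dmrs": sub["dmr_index"].nunique(),
            "regions": ",".join(sorted(set(sub["region"]))),
            "meth_direction": meth,
            "expr_direction": degs.loc[degs["gene_id"] == gene,
                                       "direction"].iloc[0],
            "comparison": comparison,
        })
    return pd.DataFrame(rows)


def venn3(set_a: Iterable, set_b: Iterable, set_c: Iterable) -> VennPartition:
    """Exact 7-region partition of three sets (e.g. DMGs per year)."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return VennPartition(
        a_only=a - b - c, b_only=b - a - c, c_only=c - a - b,
        ab=(a & b) - c, ac=(a & c) - b, bc=(b & c) - a, abc=abc)


def direction_consistency(directions: pd.DataFrame) -> dict:
    """Classify genes by expression direction across comparisons.

    ``directions``: genes x comparisons with values 'up'/'down' (NaN or ''
    = missing).  A gene is consistent when every comparison agrees;
    genes with any missing direction are flagged and excluded from the
    counts.  Returns dict with n_up, n_down, n_inconsistent, flagged.
    """
    vals = directions.replace("", np.nan)
    missing = vals.isna().any(axis=1)
    flagged = list(vals.index[missing])
    ok = vals[~missing]
    n_up = int((ok == "up").all(axis=1).sum())
    n_down = int((ok == "down").all(axis=1).sum())
    n_inconsistent = int(len(ok) - n_up - n_down)
    return {"n_up": n_up, "n_down": n_down,
            "n_inconsistent": n_inconsistent, "flagged": flagged}


def tf_family_summary(dmgs: pd.DataFrame,
                      family_map: pd.DataFrame) -> pd.DataFrame:
    """Tally DMGs with a TF-family label by (context, family, direction).

    ``family_map`` is a 2-column frame gene_id -> family.  DMGs without a
    family label are ignored (they are not TFs).
    """
    if dmgs.empty:
        return pd.DataFrame(columns=["context", "family", "direction", "n"])
    merged = dmgs.merge(family_map, on="gene_id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["context", "family", "direction", "n"])
    out = (merged.groupby(["context", "family", "expr_direction"], sort=True)
                 .size().reset_index(name="n")
                 .rename(columns={"expr_direction": "direction"}))
    return out


def enrich(selected: Iterable, gene2term: pd.DataFrame,
           universe: Iterable | None = None) -> pd.DataFrame:
    """Hypergeometric upper-tail term enrichment with BH q-values.

    ``gene2term``: 2-column frame (gene_id, term).  The universe defaults
    to all genes with >= 1 term annotation; an explicit universe restricts
    both the selected set and the term memberships.  For each term,
    p = P[X >= overlap] with X ~ Hypergeom(universe, term size, selected
    size).  Terms with no universe member are skipped with a warning.
    Results are sorted by p (then term id); the "top 20" of an enrichment
    figure are the first 20 rows.
    """
    g2t = gene2term.rename(columns=dict(zip(gene2term.columns,
                                            ["gene_id", "term"])))
    if universe is None:
        universe = set(g2t["gene_id"])
    else:
        universe = set(universe)
        g2t = g2t[g2t["gene_id"].isin(universe)]
    selected = set(selected) & universe
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for term, sub in g2t.groupby("term", sort=True):
        members = set(sub["gene_id"])
        if not members:
            warnings.warn(f"term {term!r} has no universe members; skipped")
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_sel)) \
            if n_sel else 1.0
        rows.append({"term": term, "overlap": k, "selected_size": n_sel,
                     "term_size": len(members), "universe_size": m, "p": p})
    out = pd.DataFrame(rows, columns=["term", "overlap", "selected_size",
                                      "term_size", "universe_size", "p"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
        out = out.sort_values(["p", "term"], kind="mergesort",
                              ignore_index=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def relative_quantification(ct_target_treatment: float,
                            ct_ref_treatment: float,
                            ct_target_control: float,
                            ct_ref_control: float) -> float:
    """qPCR fold change by the comparative-Ct method, 2^-ddCt.

    ddCt = (Ct_target - Ct_ref) under treatment minus the same difference
    under control; a fold of 4 corresponds to ddCt = -2.
    """
    ddct = ((ct_target_treatment - ct_ref_treatment)
            - (ct_target_control - ct_ref_control))
    return float(2.0 ** (-ddct))


def platform_concordance(qpcr_folds: Mapping[str, float],
                         rnaseq_lfc: Mapping[str, float]) -> tuple[int, int]:
    """Direction agreement between qPCR fold changes and RNA-seq log2FC.

    A pair is consistent when sign(log2 qPCR fold) equals sign(RNA-seq
    log2fc); a zero on either side is inconsistent with any non-zero
    sign (and with zero it is consistent).  Unpaired genes are excluded
    with a warning.  Returns (n_consistent, n_total).
    """
    qpcr = dict(qpcr_folds)
    rna = dict(rnaseq_lfc)
    shared = sorted(set(qpcr) & set(rna))
    missing = sorted((set(qpcr) | set(rna)) - set(shared))
    if missing:
        warnings.warn(f"unpaired genes excluded from concordance: {missing}")
    n_cons = 0
    for g in shared:
        s_q = np.sign(np.log2(qpcr[g])) if qpcr[g] > 0 else -1.0
        s_r = np.sign(rna[g])
        if s_q == s_r:
            n_cons += 1
    return n_cons, len(shared)
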