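"""Descriptive statistics for whole-genome bisulfite (WGBS) methylomes.

Plant genomes carry cytosine methylation in three sequence contexts — CG,
CHG and CHH (H = A, C or T), read 5'→3' on the cytosine's own strand.  This
module parses per-cytosine report tables (Bismark cytosine-report style),
classifies contexts from genome sequence, and computes the descriptive
quantities of a typical WGBS landscape figure: genome-wide weighted
methylation levels per context, proportions of methylated sites per
context, chromosome-scale profiles against gene density, gene-centred
metaprofiles (upstream flank / length-normalised body / downstream flank),
and the bisulfite conversion rate from an unmethylated spike-in control.

Coordinates are 1-based inclusive throughout, matching the cytosine-report
and GFF3 conventions; ``pos`` is the position of the cytosine on the
forward-strand axis regardless of which strand it lies on.

A "weighted" methylation level is the read-count-weighted mean:
``sum(meth) / sum(meth + unmeth)`` over a set of cytosines.  Windows or
bins without any covered cytosine are reported as NaN — an explicit
missing flag, never conflated with a level of 0.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTEXTS = ("CG", "CHG", "CHH")

#: Column layout of a 7-column cytosine report:
#: chrom, 1-based position, strand, methylated count, unmethylated count,
#: context label (CG/CHG/CHH), trinucleotide.
REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class NoDataError(ValueError):
    """Raised when a statistic is requested over an empty record set."""


class ReportParseError(ValueError):
    """Raised for a malformed cytosine-report line; names the line number."""


@dataclasses.dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine observation."""

    chrom: str
    pos: int          # 1-based
    strand: str       # '+' or '-'
    meth_count: int
    unmeth_count: int
    context: str      # CG | CHG | CHH

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclasses.dataclass
class MethylationSummary:
    """Per-context site counts, site proportions and weighted levels."""

    site_counts: dict
    proportions: dict       # over called/covered sites; NaN when no site called
    weighted_levels: dict   # read-weighted level per context; NaN when no data
    mode: str               # 'called' or 'covered'


def read_cx_report(path) -> pd.DataFrame:
    """Read a 7-column cytosine report into a DataFrame (``REPORT_COLUMNS``).

    Lines are validated (integer position >= 1, strand in {+,-}, counts
    >= 0, context in {CG, CHG, CHH}); the first malformed line raises
    :class:`ReportParseError` naming its 1-based line number.  An empty
    file yields an empty frame with the standard columns.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=REPORT_COLUMNS).astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64})
    if df.shape[1] != len(REPORT_COLUMNS):
        raise ReportParseError(
            f"{path}: expected {len(REPORT_COLUMNS)} tab-separated columns, "
            f"found {df.shape[1]}")
    df.columns = REPORT_COLUMNS

    def _bad_line(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 1
            raise ReportParseError(f"{path} line {line}: {what}")

    for col in ("pos", "meth", "unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        _bad_line(numeric.isna() | (numeric % 1 != 0),
                  f"non-integer value in column '{col}'")
        _bad_line(numeric < 0, f"negative value in column '{col}'")
        df[col] = numeric.astype(np.int64)
    _bad_line(df["pos"] < 1, "position must be >= 1")
    _bad_line(~df["strand"].isin(["+", "-"]), "strand must be '+' or '-'")
    _bad_line(~df["context"].isin(CONTEXTS),
              "context must be one of CG, CHG, CHH")
    return df


def write_cx_report(df: pd.DataFrame, path) -> None:
    """Write a report DataFrame back to the 7-column TSV layout."""
    df.loc[:, REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def iter_records(df: pd.DataFrame) -> Iterable[CytosineRecord]:
    """Yield :class:`CytosineRecord` objects from a report frame."""
    for row in df.itertuples(index=False):
        yield CytosineRecord(row.chrom, int(row.pos), row.strand,
                             int(row.meth), int(row.unmeth), row.context)


def classify_context(seq: str, pos: int, strand: str):
    """Context of the cytosine at 1-based ``pos`` on ``strand`` of ``seq``.

    Returns 'CG', 'CHG', 'CHH', or None when the base at that position on
    the given strand is not a cytosine.  Within 2 bp of the 3' end of the
    strand, missing downstream bases are treated as H.
    """
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    s = seq.upper()
    if strand == "+":
        if s[pos - 1] != "C":
            return None
        nxt1 = s[pos] if pos < len(s) else "H"
        nxt2 = s[pos + 1] if pos + 1 < len(s) else "H"
    elif strand == "-":
        # cytosine on '-' strand shows as G on the forward sequence; the
        # 3-mer runs 5'→3' on the '-' strand, i.e. leftwards on the axis
        if s[pos - 1] != "G":
            return None
        nxt1 = _COMPLEMENT.get(s[pos - 2], "H") if pos >= 2 else "H"
        nxt2 = _COMPLEMENT.get(s[pos - 3], "H") if pos >= 3 else "H"
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if nxt1 == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def classify_genome(seq: str) -> pd.DataFrame:
    """Vectorised context classification of every cytosine on both strands.

    Returns a frame with columns pos (1-based), strand, context, tri
    (trinucleotide 5'→3' on the cytosine's strand, N-padded at sequence
    ends), sorted by position then strand.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    n = len(arr)
    pad = np.concatenate([[b"N"] * 2, arr, [b"N"] * 2])
    is_c = arr == b"C"
    is_g = arr == b"G"

    frames = []
    for strand, mask, off, comp in (("+", is_c, +1, False), ("-", is_g, -1, True)):
        pos0 = np.flatnonzero(mask)
        if pos0.size == 0:
            continue
        b1 = pad[pos0 + 2 + off]
        b2 = pad[pos0 + 2 + 2 * off]
        if comp:
            b1 = _complement_bytes(b1)
            b2 = _complement_bytes(b2)
        ctx = np.where(b1 == b"G", "CG", np.where(b2 == b"G", "CHG", "CHH"))
        base = np.full(pos0.size, "C")
        tri = np.char.add(np.char.add(base, b1.astype("U1")), b2.astype("U1"))
        frames.append(pd.DataFrame({"pos": pos0 + 1, "strand": strand,
                                    "context": ctx, "tri": tri}))
    if not frames:
        return pd.DataFrame(columns=["pos", "strand", "context", "tri"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort",
                           ignore_index=True)


def _complement_bytes(b: np.ndarray) -> np.ndarray:
    out = np.full(b.shape, b"N", dtype="S1")
    for x, y in ((b"A", b"T"), (b"T", b"A"), (b"C", b"G"), (b"G", b"C")):
        out[b == x] = y
    return out


def filter_by_coverage(records: pd.DataFrame, min_cov: int = 4) -> pd.DataFrame:
    """Keep records with meth+unmeth coverage >= ``min_cov`` (order kept)."""
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if min_cov == 0:
        return records
    return records[(records["meth"] + records["unmeth"]) >= min_cov]


def weighted_level(records: pd.DataFrame, context: str | None = None) -> float:
    """Read-weighted methylation level: sum(meth)/sum(meth+unmeth).

    ``context`` restricts to one context; raises :class:`NoDataError`
    rather than returning 0 when no covered record matches.
    """
    sub = records if context is None else records[records["context"] == context]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    if len(sub) == 0 or total == 0:
        raise NoDataError(
            f"no covered records{' for context ' + context if context else ''}")
    return float(sub["meth"].sum()) / total


def _weighted_levels_by_context(records: pd.DataFrame) -> dict:
    out = {}
    for ctx in CONTEXTS:
        try:
            out[ctx] = weighted_level(records, ctx)
        except NoDataError:
            out[ctx] = float("nan")
    return out


def call_methylated_sites(records: pd.DataFrame, non_conversion: float = 0.01,
                          alpha: float = 0.05) -> pd.Series:
    """Boolean mask of sites called methylated.

    A covered site is called methylated when a one-sided binomial test of
    its methylated count against the bisulfite non-conversion (false
    methylation) rate rejects, after Benjamini–Hochberg correction at
    ``alpha`` across all covered sites.
    """
    cov = records["meth"] + records["unmeth"]
    called = pd.Series(False, index=records.index)
    covered = cov > 0
    if covered.any():
        p = stats.binom.sf(records.loc[covered, "meth"] - 1,
                           cov[covered], non_conversion)
        reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        called.loc[covered] = reject
    return called


def context_proportions(records: pd.DataFrame, non_conversion: float = 0.01,
                        alpha: float = 0.05,
                        mode: str = "called") -> MethylationSummary:
    """Per-context proportions of methylated sites plus weighted levels.

    ``mode='called'`` counts sites passing the binomial methylation call
    (see :func:`call_methylated_sites`); ``mode='covered'`` counts all
    covered sites.  Proportions sum to 1 over CG/CHG/CHH whenever any site
    qualifies, and are NaN otherwise.
    """
    if mode == "called":
        keep = call_methylated_sites(records, non_conversion, alpha)
    elif mode == "covered":
        keep = (records["meth"] + records["unmeth"]) > 0
    else:
        raise ValueError("mode must be 'called' or 'covered'")
    kept = records[keep]
    counts = {ctx: int((kept["context"] == ctx).sum()) for ctx in CONTEXTS}
    total = sum(counts.values())
    props = {ctx: (counts[ctx] / total if total else float("nan"))
             for ctx in CONTEXTS}
    return MethylationSummary(site_counts=counts, proportions=props,
                              weighted_levels=_weighted_levels_by_context(records),
                              mode=mode)


def chromosome_profile(records: pd.DataFrame, genes: pd.DataFrame,
                       chrom_lengths: Mapping[str, int],
                       window: int = 1_000_000) -> pd.DataFrame:
    """Windowed gene density and per-context weighted levels per chromosome.

    Chromosomes are tiled from position 1 with ``window``-bp windows (last
    partial window included).  Gene density is the number of genes whose
    midpoint falls in the window; levels are NaN where a window has no
    covered cytosine of that context.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window))
        rec = records[records["chrom"] == chrom]
        gen = genes[genes["chrom"] == chrom]
        mid = ((gen["start"] + gen["end"]) // 2).to_numpy()
        gene_win = np.bincount((mid - 1) // window, minlength=n_win)
        widx = (rec["pos"].to_numpy() - 1) // window
        for w in range(n_win):
            row = {"chrom": chrom, "start": w * window + 1,
                   "end": min((w + 1) * window, length),
                   "n_genes": int(gene_win[w])}
            sub = rec[widx == w]
            for ctx in CONTEXTS:
                try:
                    row[f"level_{ctx}"] = weighted_level(sub, ctx)
                except NoDataError:
                    row[f"level_{ctx}"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def metaprofile(records: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000,
                flank_bins: int = 20, body_bins: int = 20) -> pd.DataFrame:
    """Gene-centred methylation metaprofile per context.

    Pools read counts over all genes into ``flank_bins`` fixed-width
    upstream bins, ``body_bins`` length-normalised gene-body bins and
    ``flank_bins`` downstream bins, oriented 5'→3' (minus-strand genes are
    reversed so bin 0 is always 5'-most).  Flanks are implicitly clipped
    at chromosome ends (no cytosines exist beyond them).  Returns one row
    per bin with segment labels and per-context weighted levels (NaN where
    a bin collected no coverage).
    """
    nbins = 2 * flank_bins + body_bins
    meth_acc = np.zeros((nbins, len(CONTEXTS)))
    cov_acc = np.zeros((nbins, len(CONTEXTS)))
    ctx_code = {c: i for i, c in enumerate(CONTEXTS)}

    for chrom, rec in records.groupby("chrom", sort=False):
        rec = rec.sort_values("pos", kind="mergesort")
        pos = rec["pos"].to_numpy()
        meth = rec["meth"].to_numpy(dtype=float)
        cov = meth + rec["unmeth"].to_numpy(dtype=float)
        ctx = rec["context"].map(ctx_code).to_numpy()
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            lo, hi = g.start - flank, g.end + flank
            i0, i1 = np.searchsorted(pos, [lo, hi + 1])
            if i0 == i1:
                continue
            p = pos[i0:i1]
            glen = g.end - g.start + 1
            bins = np.empty(p.size, dtype=np.int64)
            up = p < g.start
            down = p > g.end
            body = ~up & ~down
            bins[up] = (p[up] - lo) * flank_bins // flank
            bins[body] = flank_bins + np.minimum(
                body_bins - 1, (p[body] - g.start) * body_bins // glen)
            bins[down] = (flank_bins + body_bins
                          + (p[down] - g.end - 1) * flank_bins // flank)
            if g.strand == "-":
                bins = nbins - 1 - bins
            np.add.at(meth_acc, (bins, ctx[i0:i1]), meth[i0:i1])
            np.add.at(cov_acc, (bins, ctx[i0:i1]), cov[i0:i1])

    segment = (["upstream"] * flank_bins + ["body"] * body_bins
               + ["downstream"] * flank_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(cov_acc > 0, meth_acc / cov_acc, np.nan)
    out = pd.DataFrame({"bin": np.arange(nbins), "segment": segment})
    for ctx, i in ctx_code.items():
        out[f"level_{ctx}"] = levels[:, i]
        out[f"coverage_{ctx}"] = cov_acc[:, i]
    return out


def conversion_rate(control_records: pd.DataFrame) -> float:
    """Bisulfite conversion rate from a fully-unmethylated control.

    Every read cytosine on the control is truly unmethylated, so the
    conversion rate is sum(unmeth)/sum(coverage).
    """
    total = int(control_records["meth"].sum() + control_records["unmeth"].sum())
    if len(control_records) == 0 or total == 0:
        raise NoDataError("no covered control records for conversion rate")
    return float(control_records["unmeth"].sum()) / total
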