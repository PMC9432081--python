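"""Sliding-window differentially methylated region (DMR) caller.

The caller tiles each chromosome with fixed-width windows (200 bp by
default, step = width, i.e. non-overlapping tiles; an overlapping step is
supported), pools read counts per window / context / group over replicates
after a per-site coverage floor, tests each window with a two-sided
Fisher's exact test on the pooled 2x2 count table, converts p-values to
q-values with the Benjamini-Hochberg step-up within each context, and
applies per-context criteria:

=======  =============  ===========  ======
context  min sites (in  min |level   max q
         both groups)   difference|
=======  =============  ===========  ======
CG       5              0.25         0.05
CHG      5              0.25         0.05
CHH      15             0.15         0.05
=======  =============  ===========  ======

with a per-site coverage floor of 4 reads.  All comparisons are inclusive
(>=, <=).  "Sites" are distinct covered cytosine positions of the window's
context.  The level difference is treatment minus control; a DMR with a
positive difference is hypermethylated, negative hypomethylated.

The two-sided Fisher p-value uses the minimum-likelihood definition (the
sum of all hypergeometric outcomes no more probable than the observed
table, with a 1+1e-7 relative tolerance on the comparison), the same
convention as R's fisher.test and scipy; it is implemented here as a
vectorised routine so that hundreds of thousands of windows are testable
in seconds.

Overlapping significant windows are not merged by default; an explicit
merge step is available for browser-style region output.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .methylome import CONTEXTS, filter_by_coverage

_REL_TOL = 1.0 + 1e-7  # relative tolerance of the minimum-likelihood rule


def _hypergeom_pmf(k, M, K, n):
    """Hypergeometric pmf via log-gamma (vectorised, ~1e-12 relative error)."""
    from scipy.special import gammaln

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return np.exp(lchoose(K, k) + lchoose(M - K, n - k) - lchoose(M, n))


@dataclasses.dataclass
class DMRCriteria:
    """Window geometry and per-context DMR thresholds."""

    window_size: int = 200
    step: int | None = None                  # None -> non-overlapping tiles
    min_sites: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"CG": 5, "CHG": 5, "CHH": 15})
    min_abs_diff: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.25, "CHH": 0.15})
    max_q: float = 0.05
    min_cov: int = 4

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        step = self.effective_step
        if not 1 <= step <= self.window_size:
            raise ValueError("step must be in [1, window_size]")
        if self.max_q <= 0 or self.min_cov < 0:
            raise ValueError("thresholds must be positive")
        for ctx in CONTEXTS:
            if self.min_sites[ctx] < 1 or self.min_abs_diff[ctx] <= 0:
                raise ValueError("per-context thresholds must be positive")

    @property
    def effective_step(self) -> int:
        return self.window_size if self.step is None else self.step


def make_windows(chrom_lengths: Mapping[str, int],
                 criteria: DMRCriteria) -> pd.DataFrame:
    """Window grid: starts at 1, advances by step, last partial included."""
    rows = []
    w, step = criteria.window_size, criteria.effective_step
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        for i, start in enumerate(range(1, length + 1, step)):
            rows.append((chrom, i, start, min(start + w - 1, length)))
    return pd.DataFrame(rows, columns=["chrom", "window", "start", "end"])


def _window_ids(pos: np.ndarray, window: int, step: int):
    """Window indices covering each position; returns (row_idx, win_idx).

    With step == window each position maps to exactly one tile; with an
    overlapping step a position belongs to every window whose span
    contains it.
    """
    if step == window:
        return np.arange(pos.size), (pos - 1) // step
    reps = -(-window // step)
    rows, wins = [], []
    base = (pos - 1) // step
    for j in range(reps):
        w = base - j
        ok = (w >= 0) & (pos >= w * step + 1) & (pos <= w * step + window)
        rows.append(np.flatnonzero(ok))
        wins.append(w[ok])
    return np.concatenate(rows), np.concatenate(wins)


def pool_windows(group_reports: Sequence[pd.DataFrame], criteria: DMRCriteria,
                 chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Pool one group's replicate reports into per-window count sums.

    Each replicate record must pass the per-site coverage floor before
    pooling; counts are then summed over replicates and over sites within
    the window.  ``n_sites`` counts distinct (position, strand) cytosines
    of the window's context that passed coverage in >= 1 replicate.
    """
    df = pd.concat(group_reports, ignore_index=True)
    df = filter_by_coverage(df, criteria.min_cov)
    df = df[df["chrom"].isin(chrom_lengths)]
    if df.empty:
        return pd.DataFrame(columns=["chrom", "window", "context",
                                     "meth", "unmeth", "n_sites"])
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        rows, wins = _window_ids(sub["pos"].to_numpy(),
                                 criteria.window_size, criteria.effective_step)
        expanded = sub.iloc[rows].copy()
        expanded["window"] = wins
        parts.append(expanded)
    df = pd.concat(parts, ignore_index=True)
    site = df["pos"].to_numpy() * 2 + (df["strand"].to_numpy() == "+")
    df = df.assign(site=site)
    pooled = (df.groupby(["chrom", "window", "context"], sort=True)
                .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"),
                     n_sites=("site", "nunique"))
                .reset_index())
    return pooled


def pool_window(group_records: Sequence[pd.DataFrame], chrom: str,
                start: int, end: int, context: str,
                min_cov: int = 4) -> dict:
    """Pooled counts/level for a single explicit window (convenience).

    Returns dict with meth, unmeth, n_sites and level (NaN when no site
    passes coverage).
    """
    df = pd.concat(group_records, ignore_index=True)
    df = filter_by_coverage(df, min_cov)
    df = df[(df["chrom"] == chrom) & (df["pos"] >= start)
            & (df["pos"] <= end) & (df["context"] == context)]
    meth, unmeth = int(df["meth"].sum()), int(df["unmeth"].sum())
    n_sites = df[["pos", "strand"]].drop_duplicates().shape[0]
    level = meth / (meth + unmeth) if meth + unmeth > 0 else float("nan")
    return {"meth": meth, "unmeth": unmeth, "n_sites": n_sites,
            "level": level}


def fisher_exact_2x2(m1, u1, m2, u2, max_block: int = 4_000_000) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for tables [[m1,u1],[m2,u2]].

    Minimum-likelihood two-sided definition; rows with zero total in
    either group get NaN (the test is undefined there).
    """
    a = np.atleast_1d(np.asarray(m1, dtype=np.int64))
    b = np.atleast_1d(np.asarray(u1, dtype=np.int64))
    c = np.atleast_1d(np.asarray(m2, dtype=np.int64))
    d = np.atleast_1d(np.asarray(u2, dtype=np.int64))
    if np.any(np.concatenate([a, b, c, d]) < 0):
        raise ValueError("counts must be non-negative")
    M = a + b + c + d
    n_row = a + b
    K = a + c
    lo = np.maximum(0, n_row + K - M)
    hi = np.minimum(n_row, K)
    p = np.full(a.shape, np.nan)
    ok = (n_row > 0) & (c + d > 0)
    idx = np.flatnonzero(ok)
    if idx.size:
        width = (hi[idx] - lo[idx] + 1)
        order = np.argsort(width, kind="mergesort")
        idx = idx[order]
        width = width[order]
        start = 0
        while start < idx.size:
            w = int(width[min(idx.size - 1, start)])
            stop = start
            # grow chunk while the padded block stays within budget
            while stop < idx.size and (stop - start + 1) * int(width[stop]) <= max_block:
                stop += 1
            stop = max(stop, start + 1)
            sel = idx[start:stop]
            wmax = int(width[stop - 1])
            k = lo[sel, None] + np.arange(wmax)[None, :]
            valid = k <= hi[sel, None]
            pmf = _hypergeom_pmf(np.where(valid, k, lo[sel, None]),
                                 M[sel, None], K[sel, None], n_row[sel, None])
            obs = _hypergeom_pmf(a[sel], M[sel], K[sel], n_row[sel])
            mask = valid & (pmf <= obs[:, None] * _REL_TOL)
            p[sel] = np.minimum(1.0, (pmf * mask).sum(axis=1))
            start = stop
    return p


def test_window(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p for one window's pooled 2x2 table.

    Raises ValueError if either group has zero total coverage (the window
    is ineligible rather than p = anything).
    """
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        raise ValueError("zero-coverage group: window ineligible for testing")
    return float(fisher_exact_2x2(meth_a, unmeth_a, meth_b, unmeth_b)[0])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN entries passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if p[ok].min() < 0 or p[ok].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        _, q[ok], _, _ = multipletests(p[ok], method="fdr_bh")
    return q


def call_dmrs(windows: pd.DataFrame, criteria: DMRCriteria) -> pd.DataFrame:
    """Apply per-context DMR criteria to tested+adjusted windows.

    Expects columns context, n_sites_control, n_sites_treatment, diff, q.
    Sets is_dmr (all three criteria, inclusive comparisons) and direction
    ('hyper' when treatment level exceeds control, else 'hypo'; empty for
    non-DMRs).
    """
    out = windows.copy()
    min_sites = out["context"].map(criteria.min_sites)
    min_diff = out["context"].map(criteria.min_abs_diff)
    out["is_dmr"] = ((out["n_sites_control"] >= min_sites)
                     & (out["n_sites_treatment"] >= min_sites)
                     & (out["diff"].abs() >= min_diff)
                     & (out["q"] <= criteria.max_q)
                     & out["q"].notna())
    direction = np.where(out["diff"] > 0, "hyper", "hypo")
    out["direction"] = np.where(out["is_dmr"], direction, "")
    return out


def find_dmrs(control_reports: Sequence[pd.DataFrame],
              treatment_reports: Sequence[pd.DataFrame],
              chrom_lengths: Mapping[str, int],
              criteria: DMRCriteria | None = None) -> pd.DataFrame:
    """End-to-end DMR scan: pool, test, BH-adjust per context, apply criteria.

    Returns one row per (chrom, window, context) with any coverage in
    either group: pooled counts, site counts, levels, diff (treatment -
    control), p, q, is_dmr, direction.  Windows covered in only one group
    carry NaN p/q and are never DMRs.
    """
    criteria = criteria or DMRCriteria()
    pooled_c = pool_windows(control_reports, criteria, chrom_lengths)
    pooled_t = pool_windows(treatment_reports, criteria, chrom_lengths)
    merged = pooled_c.merge(pooled_t, on=["chrom", "window", "context"],
                            how="outer", suffixes=("_control", "_treatment"))
    for col in ("meth_control", "unmeth_control", "n_sites_control",
                "meth_treatment", "unmeth_treatment", "n_sites_treatment"):
        merged[col] = merged[col].fillna(0).astype(np.int64)

    step, w = criteria.effective_step, criteria.window_size
    merged["start"] = merged["window"] * step + 1
    lengths = merged["chrom"].map(dict(chrom_lengths))
    merged["end"] = np.minimum(merged["start"] + w - 1, lengths)

    cov_c = merged["meth_control"] + merged["unmeth_control"]
    cov_t = merged["meth_treatment"] + merged["unmeth_treatment"]
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["level_control"] = np.where(
            cov_c > 0, merged["meth_control"] / cov_c, np.nan)
        merged["level_treatment"] = np.where(
            cov_t > 0, merged["meth_treatment"] / cov_t, np.nan)
    merged["diff"] = merged["level_treatment"] - merged["level_control"]

    merged["p"] = np.nan
    eligible = (cov_c > 0) & (cov_t > 0)
    if eligible.any():
        sub = merged[eligible]
        merged.loc[eligible, "p"] = fisher_exact_2x2(
            sub["meth_control"], sub["unmeth_control"],
            sub["meth_treatment"], sub["unmeth_treatment"])
    merged["q"] = np.nan
    for ctx in CONTEXTS:
        sel = merged["context"] == ctx
        if sel.any():
            merged.loc[sel, "q"] = bh_adjust(merged.loc[sel, "p"])
    out = call_dmrs(merged, criteria)
    return out.sort_values(["chrom", "window", "context"],
                           kind="mergesort", ignore_index=True)


def merge_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent same-context DMR windows into regions.

    Off by default in the pipeline (window-level calls are reported);
    provided for browser-style region summaries.  Counts are summed,
    levels recomputed from merged counts, q reported as the minimum.
    """
    rows = []
    sig = dmrs[dmrs["is_dmr"]].sort_values(["context", "chrom", "start"])
    for (ctx, chrom), sub in sig.groupby(["context", "chrom"], sort=True):
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start <= cur["end"] + 1 \
                    and r.direction == cur["direction"]:
                cur["end"] = max(cur["end"], r.end)
                for f in ("meth_control", "unmeth_control",
                          "meth_treatment", "unmeth_treatment"):
                    cur[f] += getattr(r, f)
                cur["q"] = min(cur["q"], r.q)
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": r.start, "end": r.end,
                       "context": ctx, "direction": r.direction,
                       "meth_control": r.meth_control,
                       "unmeth_control": r.unmeth_control,
                       "meth_treatment": r.meth_treatment,
                       "unmeth_treatment": r.unmeth_treatment,
                       "q": r.q, "n_windows": 1}
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["level_control"] = out["meth_control"] / (
            out["meth_control"] + out["unmeth_control"])
        out["level_treatment"] = out["meth_treatment"] / (
            out["meth_treatment"] + out["unmeth_treatment"])
        out["diff"] = out["level_treatment"] - out["level_control"]
    return out


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view of DMR windows (0-based half-open starts)."""
    sig = dmrs[dmrs["is_dmr"]]
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(sig["q"].to_numpy(float), 1e-300))
    return pd.DataFrame({
        "chrom": sig["chrom"], "start": sig["start"] - 1, "end": sig["end"],
        "name": sig["context"], "score": np.round(score, 4), "strand": ".",
        "level_control": sig["level_control"],
        "level_treatment": sig["level_treatment"],
        "diff": sig["diff"], "p": sig["p"], "q": sig["q"],
        "n_sites_control": sig["n_sites_control"],
        "n_sites_treatment": sig["n_sites_treatment"],
        "direction": sig["direction"],
    }).reset_index(drop=True)
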