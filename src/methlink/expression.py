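"""Gene-expression quantification, DEG calling and replicate QC.

Counts are normalised as FPKM (fragments per kilobase of gene per million
mapped fragments).  Differential expression between two conditions uses a
self-contained exact binomial test on replicate-pooled counts with a
library-size offset: under the null of equal expression, the treatment
share of a gene's pooled fragments is binomial with success probability
equal to the treatment share of the pooled library.  The two-sided
p-value uses the minimum-likelihood definition (same convention as
scipy.stats.binomtest).  This deliberately trades edgeR-style dispersion
modelling for a deterministic, exactly checkable statistic; absolute DEG
counts on overdispersed data will differ from a negative-binomial fit,
but threshold logic and downstream integration are unaffected.

DEGs require p < 0.001 (strict) and |log2 fold change| >= 2 (inclusive).
The fold change is log2 of the ratio of condition-mean FPKMs, with a
pseudo-value of EPS_FPKM substituted for a zero mean so the ratio is
always defined (a zero mean never silently becomes a finite level).

QC helpers: sample-sample Pearson correlation of log2(FPKM+1) and PCA
scores with canonicalised component signs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

#: pseudo-FPKM substituted for a zero condition mean in fold changes
EPS_FPKM = 1e-3

SAMPLE_SHEET_COLUMNS = ["sample", "condition", "replicate"]


def library_sizes(counts: pd.DataFrame,
                  sizes: pd.Series | None = None) -> pd.Series:
    """Library size per sample; defaults to the column sum of counts."""
    if sizes is None:
        sizes = counts.sum(axis=0).astype(float)
    else:
        sizes = sizes.astype(float).reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    return sizes


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         sizes: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = count / ((length/1e3) * (library_size/1e6)).

    ``counts`` is genes x samples; ``gene_lengths`` in bp indexed by gene.
    """
    sizes = library_sizes(counts, sizes)
    lengths = gene_lengths.astype(float).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    denom = np.outer(lengths / 1e3, sizes / 1e6)
    return pd.DataFrame(counts.to_numpy(float) / denom,
                        index=counts.index, columns=counts.columns)


def binom_two_sided(k, n, p0, max_block: int = 4_000_000) -> np.ndarray:
    """Vectorised exact two-sided binomial p (minimum-likelihood rule).

    P-value = sum of P(X=j) over all j in 0..n with P(X=j) <= P(X=k),
    X ~ Binomial(n, p0), with a 1+1e-7 relative tolerance; matches
    scipy.stats.binomtest(alternative='two-sided').  n = 0 gives p = 1.
    The pmf is evaluated in log space via gammaln (fast and accurate to
    ~1e-12 relative error even for large n).
    """
    from scipy.special import gammaln

    def log_pmf(j, nn):
        return (gammaln(nn + 1) - gammaln(j + 1) - gammaln(nn - j + 1)
                + j * np.log(p0) + (nn - j) * np.log1p(-p0))

    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if np.any((k < 0) | (k > n)):
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    p = np.ones(k.shape, dtype=float)
    idx = np.flatnonzero(n > 0)
    if idx.size:
        order = np.argsort(n[idx], kind="mergesort")
        idx = idx[order]
        start = 0
        while start < idx.size:
            stop = start
            while stop < idx.size and \
                    (stop - start + 1) * int(n[idx[stop]] + 1) <= max_block:
                stop += 1
            stop = max(stop, start + 1)
            sel = idx[start:stop]
            nmax = int(n[sel].max())
            j = np.arange(nmax + 1)[None, :]
            valid = j <= n[sel, None]
            pmf = np.exp(log_pmf(np.where(valid, j, 0), n[sel, None]))
            obs = np.exp(log_pmf(k[sel], n[sel]))
            mask = valid & (pmf <= obs[:, None] * (1 + 1e-7))
            p[sel] = np.minimum(1.0, (pmf * mask).sum(axis=1))
            start = stop
    return p


def de_test(counts_gene: pd.Series, sample_sheet: pd.DataFrame,
            sizes: pd.Series, treatment: str = "treatment",
            control: str = "control") -> tuple[float, float]:
    """(p, pooled-count log2 ratio) for one gene — thin scalar wrapper.

    The table-level :func:`de_table` is the workhorse; this exposes the
    same pooled binomial test for a single gene's counts.
    """
    t_samples = sample_sheet.loc[sample_sheet["condition"] == treatment, "sample"]
    c_samples = sample_sheet.loc[sample_sheet["condition"] == control, "sample"]
    kt = float(counts_gene[t_samples].sum())
    kc = float(counts_gene[c_samples].sum())
    lib_t = float(sizes[t_samples].sum())
    lib_c = float(sizes[c_samples].sum())
    n = int(kt + kc)
    if n == 0:
        return 1.0, 0.0
    p0 = lib_t / (lib_t + lib_c)
    p = float(binom_two_sided(int(kt), n, p0)[0])
    ratio = np.log2(max(kt / lib_t, 1e-300) / max(kc / lib_c, 1e-300))
    return p, float(ratio)


def de_table(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
             gene_lengths: pd.Series, sizes: pd.Series | None = None,
             treatment: str = "treatment", control: str = "control",
             eps: float = EPS_FPKM) -> pd.DataFrame:
    """Per-gene FPKM means, log2 fold change and exact-test p-value.

    log2fc compares mean treatment FPKM to mean control FPKM (zero means
    replaced by ``eps``); p comes from the pooled exact binomial test.
    All-zero genes get p = 1, log2fc = 0.
    """
    sizes = library_sizes(counts, sizes)
    fpkm_tab = fpkm(counts, gene_lengths, sizes)
    t_samples = sample_sheet.loc[sample_sheet["condition"] == treatment,
                                 "sample"].tolist()
    c_samples = sample_sheet.loc[sample_sheet["condition"] == control,
                                 "sample"].tolist()
    if not t_samples or not c_samples:
        raise ValueError("need >= 1 replicate per condition")
    mean_t = fpkm_tab[t_samples].mean(axis=1)
    mean_c = fpkm_tab[c_samples].mean(axis=1)
    lfc = np.log2(mean_t.clip(lower=eps) / mean_c.clip(lower=eps))

    pooled_t = counts[t_samples].sum(axis=1).to_numpy(np.int64)
    pooled_c = counts[c_samples].sum(axis=1).to_numpy(np.int64)
    n = pooled_t + pooled_c
    p0 = float(sizes[t_samples].sum() / (sizes[t_samples].sum()
                                         + sizes[c_samples].sum()))
    p = binom_two_sided(pooled_t, n, p0)
    zero = n == 0
    p[zero] = 1.0
    lfc = lfc.to_numpy(float)
    lfc[zero] = 0.0

    out = pd.DataFrame({
        "gene_id": counts.index,
        "mean_fpkm_control": mean_c.to_numpy(float),
        "mean_fpkm_treatment": mean_t.to_numpy(float),
        "log2fc": lfc,
        "p": p,
        "pooled_control": pooled_c,
        "pooled_treatment": pooled_t,
    }).set_index("gene_id", drop=False)
    out.index.name = None
    return out


def call_degs(table: pd.DataFrame, p_max: float = 0.001,
              min_abs_lfc: float = 2.0) -> pd.DataFrame:
    """Flag DEGs: p strictly below ``p_max`` and |log2fc| >= ``min_abs_lfc``."""
    out = table.copy()
    out["is_deg"] = (out["p"] < p_max) & (out["log2fc"].abs() >= min_abs_lfc)
    direction = np.where(out["log2fc"] > 0, "up", "down")
    out["direction"] = np.where(out["is_deg"], direction, "")
    return out


def log_fpkm(fpkm_tab: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1), the scale used for replicate QC."""
    return np.log2(fpkm_tab + 1.0)


def pearson_matrix(log_fpkm_tab: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of log-scaled FPKM.

    Zero-variance samples yield NaN entries (flagged, not imputed).
    Requires >= 2 genes.
    """
    if log_fpkm_tab.shape[0] < 2:
        raise ValueError("need >= 2 genes for sample correlation")
    x = log_fpkm_tab.to_numpy(float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    cols = log_fpkm_tab.columns
    return pd.DataFrame(r, index=cols, columns=cols)


def pca_scores(log_fpkm_tab: pd.DataFrame,
               n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on principal components of the gene space.

    Genes are mean-centred across samples (mandatory); scores come from
    the SVD of the centred samples x genes matrix.  Component signs are
    canonicalised so the largest-magnitude gene loading of each component
    is positive.  Returns (scores DataFrame samples x PCs, explained
    variance per component); explained variances sum to the total
    variance of the centred data.
    """
    if log_fpkm_tab.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA")
    x = log_fpkm_tab.to_numpy(float).T          # samples x genes
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]),
                      np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip
    scores = u * s
    n_samples = x.shape[0]
    explained = s ** 2 / max(n_samples - 1, 1)
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=log_fpkm_tab.columns, columns=cols),
            explained)
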