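"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops against the
mathematical definitions (exact integer enumeration, direct string
inspection, hand-coded step-up), independent of the vectorised library
code paths it checks.
"""
from __future__ import annotations

import math
from fractions import Fraction
from math import comb, lgamma

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


# --- Fisher's exact test -------------------------------------------------

def fisher_p_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    Minimum-likelihood rule with the standard 1+1e-7 relative tolerance,
    evaluated in exact rational arithmetic.
    """
    M, n, K = a + b + c + d, a + b, a + c
    lo, hi = max(0, n + K - M), min(n, K)
    obs = comb(K, a) * comb(M - K, n - a)
    total = 0
    for k in range(lo, hi + 1):
        w = comb(K, k) * comb(M - K, n - k)
        if w * 10**7 <= obs * (10**7 + 1):
            total += w
    return float(Fraction(total, comb(M, n)))


def _lchoose(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def fisher_p_lgamma(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct log-space hypergeometric summation.

    Float-based variant for large pooled counts where exact integer
    enumeration is too slow; same minimum-likelihood definition.
    """
    M, n, K = a + b + c + d, a + b, a + c
    lo, hi = max(0, n + K - M), min(n, K)
    base = _lchoose(M, n)
    logs = [_lchoose(K, k) + _lchoose(M - K, n - k) - base
            for k in range(lo, hi + 1)]
    obs = _lchoose(K, a) + _lchoose(M - K, n - a) - base
    thresh = obs + math.log(1 + 1e-7)
    return min(1.0, sum(math.exp(l) for l in logs if l <= thresh))


# --- binomial test -------------------------------------------------------

def binom_p_exact(k: int, n: int, p0: Fraction) -> float:
    """Two-sided exact binomial p (minimum-likelihood), rational arithmetic."""
    if n == 0:
        return 1.0
    p0 = Fraction(p0)
    pmf = [comb(n, j) * p0**j * (1 - p0)**(n - j) for j in range(n + 1)]
    obs = pmf[k]
    total = sum(w for w in pmf if w <= obs * Fraction(10**7 + 1, 10**7))
    return float(min(Fraction(1), total))


# --- Benjamini-Hochberg --------------------------------------------------

def bh_stepup(pvalues) -> list:
    """Hand-coded BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


# --- hypergeometric enrichment ------------------------------------------

def hypergeom_upper_exact(overlap: int, universe: int, term: int,
                          selected: int) -> float:
    """P[X >= overlap] by exact enumeration (universe <= a few hundred)."""
    total = sum(comb(term, k) * comb(universe - term, selected - k)
                for k in range(overlap, min(term, selected) + 1))
    return float(Fraction(total, comb(universe, selected)))


# --- context classification ----------------------------------------------

def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def classify_bruteforce(seq: str, pos: int, strand: str):
    """Context by direct 3-mer inspection; '-' strand via full revcomp."""
    if strand == "-":
        return classify_bruteforce(revcomp(seq), len(seq) - pos + 1, "+")
    sub = (seq[pos - 1:pos + 2] + "NN")[:3]
    if sub[0] != "C":
        return None
    if sub[1] == "G":
        return "CG"
    if sub[2] == "G":
        return "CHG"
    return "CHH"


# --- whole DMR scan ------------------------------------------------------

def dmr_scan_bruteforce(control_reports, treatment_reports, chrom_lengths,
                        criteria) -> set:
    """Re-enumerate every tile, re-pool, re-test, re-adjust, re-check.

    Plain dict/loop implementation of the non-overlapping-tile scan;
    returns the set of (chrom, window_index, context) called DMR.
    """
    w = criteria.window_size
    assert criteria.effective_step == w, "oracle covers tiles only"

    def pool(reports):
        counts, sites = {}, {}
        for rep in reports:
            for row in rep.itertuples(index=False):
                if row.meth + row.unmeth < criteria.min_cov:
                    continue
                if row.chrom not in chrom_lengths:
                    continue
                key = (row.chrom, (row.pos - 1) // w, row.context)
                m, u = counts.get(key, (0, 0))
                counts[key] = (m + row.meth, u + row.unmeth)
                sites.setdefault(key, set()).add((row.pos, row.strand))
        return counts, sites

    counts_c, sites_c = pool(control_reports)
    counts_t, sites_t = pool(treatment_reports)

    pvals = {}
    for key in set(counts_c) & set(counts_t):
        mc, uc = counts_c[key]
        mt, ut = counts_t[key]
        pvals[key] = fisher_p_lgamma(mc, uc, mt, ut)

    qvals = {}
    for ctx in ("CG", "CHG", "CHH"):
        keys = [k for k in pvals if k[2] == ctx]
        qs = bh_stepup([pvals[k] for k in keys])
        qvals.update(dict(zip(keys, qs)))

    called = set()
    for key, q in qvals.items():
        ctx = key[2]
        mc, uc = counts_c[key]
        mt, ut = counts_t[key]
        diff = mt / (mt + ut) - mc / (mc + uc)
        if (len(sites_c[key]) >= criteria.min_sites[ctx]
                and len(sites_t[key]) >= criteria.min_sites[ctx]
                and abs(diff) >= criteria.min_abs_diff[ctx]
                and q <= criteria.max_q):
            called.add(key)
    return called
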