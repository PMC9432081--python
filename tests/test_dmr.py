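import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from methlink import synthdata
from methlink.dmr import (DMRCriteria, bh_adjust, call_dmrs, fisher_exact_2x2,
                          find_dmrs, make_windows, merge_dmrs, pool_window,
                          test_window as fisher_window_p)

from conftest import small_config
from oracles import bh_stepup, dmr_scan_bruteforce, fisher_p_exact


# --- window grid ----------------------------------------------------------

@pytest.mark.parametrize("length,window,step,n,last_len", [
    (1000, 200, 200, 5, 200),
    (1001, 200, 200, 6, 1),
    (1000, 200, 100, 10, 100),
])
def test_make_windows_tiling(length, window, step, n, last_len):
    crit = DMRCriteria(window_size=window, step=step)
    grid = make_windows({"c": length}, crit)
    assert len(grid) == n
    assert grid["start"].iloc[0] == 1
    last = grid.iloc[-1]
    assert last["end"] == length
    assert last["end"] - last["start"] + 1 == last_len


# --- pooling --------------------------------------------------------------

def test_pool_window_levels_and_diff():
    a = pd.DataFrame({"chrom": "c", "pos": [10, 20], "strand": "+",
                      "meth": [3, 1], "unmeth": [1, 3], "context": "CG",
                      "tri": "CGA"})
    b = pd.DataFrame({"chrom": "c", "pos": [10, 20], "strand": "+",
                      "meth": [4, 4], "unmeth": [0, 0], "context": "CG",
                      "tri": "CGA"})
    pa = pool_window([a], "c", 1, 200, "CG")
    pb = pool_window([b], "c", 1, 200, "CG")
    assert pa["level"] == 0.5 and pb["level"] == 1.0
    assert pb["level"] - pa["level"] == 0.5
    assert pa["n_sites"] == 2
    empty = pool_window([a], "c", 201, 400, "CG")
    assert empty["n_sites"] == 0 and np.isnan(empty["level"])


def test_pool_window_replicate_additivity():
    whole = pd.DataFrame({"chrom": "c", "pos": [10], "strand": "+",
                          "meth": [6], "unmeth": [2], "context": "CG",
                          "tri": "CGA"})
    half1 = whole.assign(meth=3, unmeth=1)
    half2 = whole.assign(meth=3, unmeth=1)
    merged = pool_window([whole], "c", 1, 200, "CG", min_cov=0)
    split = pool_window([half1, half2], "c", 1, 200, "CG", min_cov=0)
    assert (merged["meth"], merged["unmeth"]) == (split["meth"],
                                                  split["unmeth"])
    assert split["n_sites"] == 1  # same position counted once


# --- Fisher test ----------------------------------------------------------

def test_fisher_extreme_table_matches_enumeration():
    p = fisher_window_p(10, 0, 0, 10)
    assert p == pytest.approx(fisher_p_exact(10, 0, 0, 10), rel=1e-10)
    assert p == pytest.approx(1.0824e-5, rel=1e-3)


def test_fisher_symmetric_and_empty_signal_tables():
    assert fisher_window_p(5, 5, 5, 5) == pytest.approx(1.0)
    assert fisher_window_p(0, 10, 0, 10) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fisher_window_p(0, 0, 3, 5)


def test_fisher_vectorised_matches_exact_enumeration(rng):
    tables = rng.integers(0, 40, size=(200, 4))
    tables = tables[(tables[:, 0] + tables[:, 1] > 0)
                    & (tables[:, 2] + tables[:, 3] > 0)]
    got = fisher_exact_2x2(*tables.T)
    for row, p in zip(tables, got):
        assert p == pytest.approx(fisher_p_exact(*map(int, row)),
                                  rel=1e-9, abs=1e-300), row


def test_fisher_vectorised_matches_scipy(rng):
    """Independent cross-check against scipy's two-sided implementation."""
    tables = rng.integers(0, 60, size=(100, 4)) + [[1, 0, 0, 1]]
    got = fisher_exact_2x2(*tables.T)
    for row, p in zip(tables, got):
        expected = scipy_fisher(row.reshape(2, 2))[1]
        assert p == pytest.approx(expected, rel=1e-7)


def test_fisher_large_counts_stable():
    p = fisher_exact_2x2([5000], [5000], [5200], [4800])[0]
    assert 0 < p < 1
    assert p == pytest.approx(scipy_fisher([[5000, 5000],
                                            [5200, 4800]])[1], rel=1e-6)


# --- BH adjustment --------------------------------------------------------

def test_bh_textbook_example():
    q = bh_adjust([0.005, 0.01, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04], rtol=1e-12)


def test_bh_degenerate_inputs():
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)


def test_bh_matches_hand_stepup(rng):
    p = rng.random(50)
    np.testing.assert_allclose(bh_adjust(p), bh_stepup(list(p)), rtol=1e-12)


def test_bh_passes_nan_through():
    q = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and not np.isnan(q[0])


# --- criteria boundaries --------------------------------------------------

def _window_row(context, n_sites, diff, q):
    return {"chrom": "c", "window": 0, "start": 1, "end": 200,
            "context": context, "n_sites_control": n_sites,
            "n_sites_treatment": n_sites, "diff": diff, "q": q}


BOUNDARY_CASES = [
    # (context, n_sites, |diff|, q, expected verdict)
    ("CG", 5, 0.25, 0.05, True),
    ("CG", 4, 0.25, 0.05, False),      # one site short
    ("CG", 5, 0.249, 0.05, False),     # diff epsilon under
    ("CG", 5, 0.25, 0.0501, False),    # q epsilon over
    ("CHG", 5, 0.25, 0.05, True),
    ("CHG", 4, 0.5, 0.001, False),
    ("CHG", 6, 0.249, 0.01, False),
    ("CHG", 5, 0.25, 0.051, False),
    ("CHH", 15, 0.15, 0.05, True),
    ("CHH", 14, 0.15, 0.04, False),
    ("CHH", 15, 0.1499, 0.04, False),
    ("CHH", 15, 0.15, 0.0500001, False),
]


@pytest.mark.parametrize("context,n_sites,diff,q,expected", BOUNDARY_CASES)
def test_criteria_boundaries_inclusive(context, n_sites, diff, q, expected):
    windows = pd.DataFrame([_window_row(context, n_sites, diff, q)])
    out = call_dmrs(windows, DMRCriteria())
    assert bool(out["is_dmr"].iloc[0]) is expected


def test_direction_follows_sign_of_difference():
    rows = [_window_row("CG", 6, 0.5, 0.001),
            _window_row("CG", 6, -0.5, 0.001)]
    out = call_dmrs(pd.DataFrame(rows), DMRCriteria())
    assert out["direction"].tolist() == ["hyper", "hypo"]


# --- end-to-end scan properties -------------------------------------------

@pytest.fixture(scope="module")
def scanned_study():
    cfg = small_config(seed=31, chrom_length=40_000, n_genes=8, depth=15,
                       control_chrom_length=0)
    _, genes = synthdata.generate_genome(cfg)
    cfg.planted_dmrs = synthdata.make_planted_dmrs(
        cfg, genes, n_unlinked={"CG": 3, "CHG": 3, "CHH": 3},
        delta={"CG": -0.4, "CHG": 0.4, "CHH": 0.3})
    genome, genes = synthdata.generate_genome(cfg)
    reports, truth = synthdata.generate_methylome(cfg, genome, genes)
    control = [reports[("control", r)] for r in (1, 2, 3)]
    treatment = [reports[("treatment", r)] for r in (1, 2, 3)]
    lengths = {c: len(s) for c, s in genome.items()}
    return control, treatment, lengths, truth


def test_scan_matches_bruteforce_oracle(scanned_study):
    control, treatment, lengths, _ = scanned_study
    crit = DMRCriteria()
    windows = find_dmrs(control, treatment, lengths, crit)
    called = set(map(tuple, windows.loc[windows["is_dmr"],
                                        ["chrom", "window",
                                         "context"]].to_numpy()))
    oracle = dmr_scan_bruteforce(control, treatment, lengths, crit)
    assert called == oracle and len(oracle) > 0


def test_swapping_groups_flips_directions_only(scanned_study):
    control, treatment, lengths, _ = scanned_study
    fwd = find_dmrs(control, treatment, lengths)
    rev = find_dmrs(treatment, control, lengths)
    key = ["chrom", "window", "context"]
    merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
    assert len(merged) == len(fwd)
    np.testing.assert_allclose(merged["diff_f"], -merged["diff_r"],
                               atol=1e-12)
    np.testing.assert_allclose(merged["p_f"], merged["p_r"],
                               rtol=1e-9, equal_nan=True)
    np.testing.assert_allclose(merged["q_f"], merged["q_r"],
                               rtol=1e-9, equal_nan=True)
    both = merged[merged["is_dmr_f"]]
    assert (both["is_dmr_r"]).all()
    assert (both["direction_f"] != both["direction_r"]).all()


def test_tightening_thresholds_is_monotone(scanned_study):
    control, treatment, lengths, _ = scanned_study
    base = find_dmrs(control, treatment, lengths, DMRCriteria())
    base_set = set(map(tuple, base.loc[base["is_dmr"],
                                       ["chrom", "window",
                                        "context"]].to_numpy()))
    tighter = [
        DMRCriteria(min_sites={"CG": 8, "CHG": 8, "CHH": 20}),
        DMRCriteria(min_abs_diff={"CG": 0.35, "CHG": 0.35, "CHH": 0.25}),
        DMRCriteria(max_q=0.01),
        DMRCriteria(min_cov=8),
    ]
    for crit in tighter:
        out = find_dmrs(control, treatment, lengths, crit)
        out_set = set(map(tuple, out.loc[out["is_dmr"],
                                         ["chrom", "window",
                                          "context"]].to_numpy()))
        assert out_set <= base_set


def test_planted_windows_recovered(scanned_study):
    control, treatment, lengths, truth = scanned_study
    windows = find_dmrs(control, treatment, lengths)
    called = set(zip(windows.loc[windows["is_dmr"], "chrom"],
                     windows.loc[windows["is_dmr"], "start"],
                     windows.loc[windows["is_dmr"], "context"]))
    truth_keys = set(zip(truth["chrom"], truth["start"], truth["context"]))
    assert truth_keys <= called


def test_merge_dmrs_preserves_counts(scanned_study):
    control, treatment, lengths, _ = scanned_study
    windows = find_dmrs(control, treatment, lengths)
    merged = merge_dmrs(windows)
    sig = windows[windows["is_dmr"]]
    assert merged["n_windows"].sum() == len(sig)
    assert merged["meth_treatment"].sum() == sig["meth_treatment"].sum()


def test_zero_coverage_window_is_ineligible():
    a = pd.DataFrame({"chrom": "c", "pos": [10], "strand": "+",
                      "meth": [5], "unmeth": [0], "context": "CG",
                      "tri": "CGA"})
    b = a.assign(pos=500)  # other window only
    out = find_dmrs([a], [b], {"c": 1000}, DMRCriteria(min_cov=1))
    assert out["p"].isna().all()
    assert not out["is_dmr"].any()
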