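
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methlink import methylome
from methlink.methylome import (NoDataError, ReportParseError,
                                classify_context, classify_genome,
                                context_proportions, conversion_rate,
                                chromosome_profile, filter_by_coverage,
                                metaprofile, read_cx_report, weighted_level)

from oracles import classify_bruteforce


# --- report parsing ------------------------------------------------------

def test_read_cx_report_parses_valid_line(tmp_path):
    path = tmp_path / "cx.tsv"
    path.write_text("chrA1\t1042\t+\t3\t1\tCG\tCGT\n")
    df = read_cx_report(path)
    assert len(df) == 1
    row = df.iloc[0]
    assert (row["chrom"], row["pos"], row["strand"]) == ("chrA1", 1042, "+")
    assert (row["meth"], row["unmeth"], row["context"]) == (3, 1, "CG")


def test_read_cx_report_empty_file(tmp_path):
    path = tmp_path / "cx.tsv"
    path.write_text("")
    assert len(read_cx_report(path)) == 0


@pytest.mark.parametrize("line,what", [
    ("chrA1\t1042\t+\t-3\t1\tCG\tCGT", "negative"),
    ("chrA1\t1042\t*\t3\t1\tCG\tCGT", "strand"),
    ("chrA1\t1042\t+\t3\t1\tCXX\tCGT", "context"),
    ("chrA1\tx\t+\t3\t1\tCG\tCGT", "non-integer"),
])
def test_read_cx_report_rejects_malformed_lines(tmp_path, line, what):
    path = tmp_path / "cx.tsv"
    path.write_text("chrA1\t1\t+\t1\t1\tCG\tCGT\n" + line + "\n")
    with pytest.raises(ReportParseError, match="line 2"):
        read_cx_report(path)


def test_report_roundtrip(tmp_path, toy_report):
    path = tmp_path / "cx.tsv"
    methylome.write_cx_report(toy_report, path)
    back = read_cx_report(path)
    pd.testing.assert_frame_equal(back, toy_report)


# --- context classification ---------------------------------------------

@pytest.mark.parametrize("seq,pos,strand,expected", [
    ("ACGTA", 2, "+", "CG"),
    ("ACAGT", 2, "+", "CHG"),
    ("ACTTT", 2, "+", "CHH"),
    ("TCGA", 3, "-", "CG"),      # G on forward = C on reverse, then G,A
    ("ACGTA", 1, "+", None),     # A is not a cytosine
    ("ACGTA", 3, "-", "CG"),     # the minus-strand partner of the CG
    ("CA", 1, "+", "CHH"),       # truncated 3' end treated as H
    ("GC", 1, "-", "CHH"),       # truncated on the minus strand too
])
def test_classify_context_definitions(seq, pos, strand, expected):
    assert classify_context(seq, pos, strand) == expected


def test_classify_context_out_of_range():
    with pytest.raises(IndexError):
        classify_context("ACGT", 5, "+")


def test_classify_context_matches_bruteforce_everywhere(rng):
    """Exhaustive agreement with direct 3-mer inspection on both strands."""
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    for pos in range(1, len(seq) + 1):
        for strand in "+-":
            assert classify_context(seq, pos, strand) == \
                classify_bruteforce(seq, pos, strand), (pos, strand)


def test_classify_genome_agrees_with_scalar(rng):
    seq = "".join(rng.choice(list("ACGT"), size=800))
    table = classify_genome(seq)
    # every cytosine on either strand appears exactly once
    expected = {(p, s): classify_bruteforce(seq, p, s)
                for p in range(1, len(seq) + 1) for s in "+-"}
    expected = {k: v for k, v in expected.items() if v is not None}
    got = {(int(r.pos), r.strand): r.context
           for r in table.itertuples(index=False)}
    assert got == expected


# --- coverage filter and weighted level ----------------------------------

def test_filter_by_coverage_boundary(toy_report):
    kept = filter_by_coverage(toy_report, 4)
    assert (kept["meth"] + kept["unmeth"] >= 4).all()
    assert 10 in kept["pos"].values        # coverage exactly 4 is kept
    kept0 = filter_by_coverage(toy_report, 0)
    pd.testing.assert_frame_equal(kept0, toy_report)


def test_filter_keeps_exact_threshold():
    df = pd.DataFrame({"chrom": ["c"] * 2, "pos": [1, 2],
                       "strand": ["+", "+"], "meth": [2, 2],
                       "unmeth": [2, 1], "context": ["CG", "CG"],
                       "tri": ["CGA", "CGA"]})
    kept = filter_by_coverage(df, 4)
    assert kept["pos"].tolist() == [1]


def test_weighted_level_formula(toy_report):
    cg = toy_report[toy_report["context"] == "CG"]
    # (3+1+8) / (4+4+8)
    assert weighted_level(cg) == pytest.approx(12 / 16)
    assert weighted_level(toy_report, "CHG") == 1.0
    with pytest.raises(NoDataError):
        weighted_level(toy_report.iloc[0:0])


def test_weighted_level_scale_anchor():
    df = pd.DataFrame({"chrom": "c", "pos": np.arange(1, 1001),
                       "strand": "+", "meth": 0, "unmeth": 1,
                       "context": "CG", "tri": "CGA"})
    df.loc[:667, "meth"], df.loc[:667, "unmeth"] = 1, 0
    assert weighted_level(df, "CG") == pytest.approx(0.668)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                min_size=1, max_size=30).filter(
                    lambda v: sum(a + b for a, b in v) > 0))
def test_weighted_level_invariant_to_order_and_splitting(pairs):
    df = pd.DataFrame({"chrom": "c", "pos": np.arange(1, len(pairs) + 1),
                       "strand": "+", "meth": [a for a, _ in pairs],
                       "unmeth": [b for _, b in pairs], "context": "CG",
                       "tri": "CGA"})
    level = weighted_level(df)
    shuffled = df.sample(frac=1, random_state=0)
    assert weighted_level(shuffled) == pytest.approx(level)
    # split every record into two half-records at the same site
    split = pd.concat([df.assign(meth=df["meth"] // 2,
                                 unmeth=df["unmeth"] // 2),
                       df.assign(meth=df["meth"] - df["meth"] // 2,
                                 unmeth=df["unmeth"] - df["unmeth"] // 2)])
    assert weighted_level(split) == pytest.approx(level)


# --- site calling and proportions ----------------------------------------

def test_context_proportions_counting():
    n = {"CG": 10, "CHG": 10, "CHH": 20}
    frames = []
    pos = 1
    for ctx, k in n.items():
        frames.append(pd.DataFrame({
            "chrom": "c", "pos": np.arange(pos, pos + k), "strand": "+",
            "meth": 30, "unmeth": 0, "context": ctx, "tri": "CNN"}))
        pos += k
    df = pd.concat(frames, ignore_index=True)
    summary = context_proportions(df)
    assert summary.proportions == pytest.approx(
        {"CG": 0.25, "CHG": 0.25, "CHH": 0.5})
    assert sum(summary.proportions.values()) == pytest.approx(1.0)


def test_context_proportions_no_called_sites():
    df = pd.DataFrame({"chrom": "c", "pos": [1, 2], "strand": "+",
                       "meth": [0, 0], "unmeth": [30, 30],
                       "context": ["CG", "CHH"], "tri": "CNN"})
    summary = context_proportions(df)
    assert all(np.isnan(v) for v in summary.proportions.values())


def test_proportion_level_inversion(small_study):
    """Abundant low-level CHH sites: high site share, low weighted level."""
    pooled = pd.concat([small_study["reports"][("control", r)]
                        for r in (1, 2, 3)], ignore_index=True)
    pooled = pooled[pooled["chrom"] != "chrUn_lambda"]
    summary = context_proportions(filter_by_coverage(pooled, 4))
    assert summary.proportions["CHH"] > summary.proportions["CG"]
    assert summary.weighted_levels["CHH"] < summary.weighted_levels["CG"]
    assert summary.weighted_levels["CG"] > summary.weighted_levels["CHG"]


# --- chromosome profile ---------------------------------------------------

def test_chromosome_profile_tiling_and_uniform_level():
    length = 2_500_000
    pos = np.arange(1, length, 5000)
    df = pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                       "meth": 3, "unmeth": 7, "context": "CG",
                       "tri": "CGA"})
    genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["c"],
                          "start": [100], "end": [2000], "strand": ["+"]})
    prof = chromosome_profile(df, genes, {"c": length})
    assert len(prof) == 3
    assert prof["end"].iloc[-1] == length
    assert prof["end"].iloc[-1] - prof["start"].iloc[-1] + 1 == 500_000
    assert np.allclose(prof["level_CG"], 0.3)
    assert prof["n_genes"].tolist() == [1, 0, 0]
    assert prof["level_CHH"].isna().all()


# --- metaprofile ----------------------------------------------------------

def _uniform_records(genes, chrom_len, level, step=7):
    pos = np.arange(1, chrom_len + 1, step)
    meth = np.full(pos.size, int(level * 10))
    return pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                         "meth": meth, "unmeth": 10 - meth,
                         "context": "CG", "tri": "CGA"})


def test_metaprofile_uniform_methylome_is_flat():
    genes = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": "c",
                          "start": [5000, 20000], "end": [9000, 26000],
                          "strand": ["+", "-"]})
    rec = _uniform_records(genes, 40000, 0.5)
    prof = metaprofile(rec, genes)
    assert np.allclose(prof["level_CG"].dropna(), 0.5)
    assert len(prof) == 60
    assert prof["segment"].tolist() == (["upstream"] * 20 + ["body"] * 20
                                        + ["downstream"] * 20)


def test_metaprofile_minus_strand_mirrors_plus():
    plus = pd.DataFrame({"gene_id": ["g"], "chrom": "c", "start": [5000],
                         "end": [8000], "strand": ["+"]})
    minus = plus.assign(strand="-")
    rng = np.random.default_rng(1)
    pos = np.arange(2000, 11000, 3)
    meth = rng.integers(0, 11, size=pos.size)
    rec = pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                        "meth": meth, "unmeth": 10 - meth, "context": "CG",
                        "tri": "CGA"})
    p1 = metaprofile(rec, plus)["level_CG"].to_numpy()
    p2 = metaprofile(rec, minus)["level_CG"].to_numpy()
    np.testing.assert_allclose(p1, p2[::-1])


def test_metaprofile_short_gene_not_dropped():
    genes = pd.DataFrame({"gene_id": ["tiny"], "chrom": "c",
                          "start": [3000], "end": [3009], "strand": ["+"]})
    rec = pd.DataFrame({"chrom": "c", "pos": np.arange(3000, 3010),
                        "strand": "+", "meth": 5, "unmeth": 5,
                        "context": "CG", "tri": "CGA"})
    prof = metaprofile(rec, genes)
    body = prof[prof["segment"] == "body"]
    assert body["coverage_CG"].sum() == 100  # every site landed in a body bin


def test_metaprofile_flank_body_dip(small_study):
    """Flank-high / body-low generator produces the canonical dip."""
    pooled = pd.concat([small_study["reports"][("control", r)]
                        for r in (1, 2, 3)], ignore_index=True)
    pooled = filter_by_coverage(
        pooled[pooled["chrom"] != "chrUn_lambda"], 4)
    prof = metaprofile(pooled, small_study["genes"])
    body = prof.loc[prof["segment"] == "body", "level_CG"]
    flank = prof.loc[prof["segment"] != "body", "level_CG"]
    assert body.mean() < flank.mean()


# --- conversion rate ------------------------------------------------------

def test_conversion_rate_arithmetic():
    df = pd.DataFrame({"chrom": "L", "pos": [1, 2], "strand": "+",
                       "meth": [5, 5], "unmeth": [495, 495],
                       "context": "CHH", "tri": "CTT"})
    assert conversion_rate(df) == pytest.approx(0.99)
    full = df.assign(meth=0, unmeth=100)
    assert conversion_rate(full) == 1.0
    with pytest.raises(NoDataError):
        conversion_rate(df.iloc[0:0])


def test_conversion_rate_recovers_generator_failure(small_study):
    """Unmethylated spike-in estimates 1 - non-conversion within 3 SE."""
    pooled = pd.concat(list(small_study["reports"].values()),
                       ignore_index=True)
    ctrl = pooled[pooled["chrom"] == "chrUn_lambda"]
    rate = conversion_rate(ctrl)
    n = float((ctrl["meth"] + ctrl["unmeth"]).sum())
    se = np.sqrt(0.99 * 0.01 / n)
    assert abs(rate - 0.99) < 3 * se
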