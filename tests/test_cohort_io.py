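"""Format round trips, validation errors and the clinical fixtures."""

import numpy as np
import pandas as pd
import pytest

from neostrat import (CohortIOError, cohort_summary, load_table1_cohort,
                      load_table2_paired, read_annotation, read_expression,
                      read_paired_vcf, read_seg, write_annotation,
                      write_expression, write_paired_vcf, write_seg)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_round_trip(toy_expression, tmp_path):
    p = tmp_path / "e.tsv"
    write_expression(toy_expression, p)
    back = read_expression(p)
    pd.testing.assert_frame_equal(back, toy_expression)


def test_expression_single_cell(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("gene\ts1\ng1\t-2.5\n")
    m = read_expression(p)
    assert m.shape == (1, 1) and m.iloc[0, 0] == -2.5


def test_expression_duplicate_gene_named_in_error(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("gene\ts1\ngX\t1.0\ngX\t2.0\n")
    with pytest.raises(CohortIOError, match="gX"):
        read_expression(p)


def test_expression_non_numeric_rejected(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("gene\ts1\ng1\tnotanumber\n")
    with pytest.raises(CohortIOError):
        read_expression(p)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_annotation_round_trip(tmp_path):
    ann = load_table2_paired()
    p = tmp_path / "a.tsv"
    write_annotation(ann, p)
    back = read_annotation(p)
    pd.testing.assert_frame_equal(back, ann)


def test_table2_fixture_counts():
    ann = load_table2_paired()
    assert len(ann) == 44
    assert ann["patient_id"].nunique() == 22
    assert (ann.groupby("patient_id")["timepoint"].agg(set)
            == {"pre", "post"}).all()


def test_annotation_nri_bounds(tmp_path):
    ann = load_table2_paired().copy()
    ann.loc[0, "nri"] = 1.2
    p = tmp_path / "a.tsv"
    write_annotation(ann, p)
    with pytest.raises(CohortIOError, match="nri"):
        read_annotation(p)


def test_annotation_unknown_subtype(tmp_path):
    ann = load_table2_paired().copy()
    ann.loc[0, "subtype"] = "HER2pos"
    p = tmp_path / "a.tsv"
    write_annotation(ann, p)
    with pytest.raises(CohortIOError, match="subtype"):
        read_annotation(p)


def test_empty_optional_fields_parse_as_missing(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("sample_id\tpatient_id\tsubtype\ttimepoint\tnri\tpcr\t"
                 "rfs_time\trfs_event\tpurity\n"
                 "s1\tp1\tTN\tpre\tNA\tNA\tNA\tNA\tNA\n")
    ann = read_annotation(p)
    assert ann.loc[0, ["nri", "rfs_time", "purity"]].isna().all()
    assert pd.isna(ann.loc[0, "pcr"])


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def test_table1_pcr_percentages():
    s = cohort_summary(load_table1_cohort())
    assert s.subtype_counts == {"ERpos": 200, "TN": 117}
    assert s.pcr_counts["ERpos"] == {"yes": 7, "no": 183, "missing": 10}
    assert s.pcr_counts["TN"] == {"yes": 46, "no": 65, "missing": 6}
    assert s.pcr_pct["ERpos"] == pytest.approx(3.5)
    assert round(s.pcr_pct["TN"], 1) == 39.3
    # alternative denominator over determined cases only
    s2 = cohort_summary(load_table1_cohort(), denominator="nonmissing")
    assert s2.pcr_pct["ERpos"] == pytest.approx(100 * 7 / 190)


def test_summary_invariant_to_row_order():
    ann = load_table1_cohort()
    shuffled = ann.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a, b = cohort_summary(ann), cohort_summary(shuffled)
    assert a.pcr_counts == b.pcr_counts and a.pcr_pct == b.pcr_pct


def test_all_missing_pcr_reports_missing_not_zero():
    ann = load_table1_cohort().copy()
    ann["pcr"] = np.nan
    s = cohort_summary(ann)
    assert np.isnan(s.pcr_pct["TN"]) and np.isnan(s.pcr_pct["ERpos"])


def test_paired_counts_from_table2():
    s = cohort_summary(load_table2_paired())
    assert s.paired_counts == {"ERpos": 16, "TN": 6}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=GENE,Number=1,Type=String,Description="g">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="e">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpre\tpost
chr1\t100\t.\tA\tT\t.\tPASS\tGENE=TP53;EFFECT=coding\tAD:DP\t10,10:20\t20,0:20
chr1\t200\t.\tG\tC\t.\tPASS\tGENE=APC;EFFECT=coding\tAD:DP\t30,0:30\t0,0:0
"""


def test_vcf_vaf_arithmetic(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_TEXT)
    v = read_paired_vcf(p)
    assert v.loc[0, "vaf_pre"] == pytest.approx(0.5)
    assert v.loc[0, "vaf_post"] == pytest.approx(0.0)
    assert v.loc[0, "gene"] == "TP53"
    # DP=0 yields missing VAF, not a division error
    assert np.isnan(v.loc[1, "vaf_post"]) and v.loc[1, "dp_post"] == 0


def test_vcf_round_trip_matches_simulator(paired_case, tmp_path):
    p = tmp_path / "somatic.vcf"
    write_paired_vcf(paired_case.variants, p, contigs={"chr1": 10**6,
                                                       "chr2": 10**6,
                                                       "chr3": 10**6,
                                                       "chr4": 10**6})
    back = read_paired_vcf(p)
    orig = paired_case.variants.sort_values(
        ["chromosome", "position"]).reset_index(drop=True)
    assert len(back) == len(orig)
    for tp in ("pre", "post"):
        np.testing.assert_allclose(back[f"vaf_{tp}"].fillna(-1),
                                   orig[f"vaf_{tp}"].fillna(-1), atol=1e-9)
    # sampled VAFs stay within binomial error of purity * clonal VAF
    truth = pd.DataFrame(paired_case.truth["variants"]).set_index("gene")
    merged = back.set_index("gene").join(truth["clonal_vaf"])
    shared = truth.index[truth["sharing"] == "shared"]
    expected = merged.loc[shared, "clonal_vaf"] * paired_case.truth["purity_pre"]
    se = np.sqrt(expected * (1 - expected) / merged.loc[shared, "dp_pre"])
    assert (np.abs(merged.loc[shared, "vaf_pre"] - expected) < 5 * se + 0.01).all()


def test_vcf_wrong_sample_count_rejected(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_TEXT.replace("\tpre\tpost", "\tpre")
                 .replace("\t10,10:20\t20,0:20", "\t10,10:20")
                 .replace("\t30,0:30\t0,0:0", "\t30,0:30"))
    with pytest.raises(CohortIOError, match="2 sample columns"):
        read_paired_vcf(p)


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

def _seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end",
                                       "n_probes", "mean"])


def test_seg_round_trip(tmp_path):
    seg = _seg_frame([("delta", "chr1", 1, 1000, 10, 0.0),
                      ("delta", "chr1", 1001, 2000, 12, -1.0)])
    p = tmp_path / "d.seg"
    write_seg(seg, p)
    back = read_seg(p)
    pd.testing.assert_frame_equal(back, seg)
    assert len(p.read_text().strip().splitlines()) == 3  # header + 2 rows


def test_seg_overlap_rejected(tmp_path):
    seg = _seg_frame([("delta", "chr1", 1, 1000, 10, 0.0),
                      ("delta", "chr1", 900, 2000, 12, -1.0)])
    with pytest.raises(CohortIOError, match="overlap"):
        write_seg(seg, tmp_path / "d.seg")
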