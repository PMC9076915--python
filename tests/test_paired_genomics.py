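"""Purity adjustment, delta segmentation, variant rules and frequency tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neostrat import (CnProfile, SimConfig, aberration_frequency_test,
                      classify_variant_sharing, filter_somatic_variants,
                      paired_delta, purity_adjust_logr, purity_adjust_vaf,
                      recurrent_gene_table, segment_delta, segment_values,
                      simulate_paired_genomics)
from neostrat.synthetic_cohort import _mix_logr


# ---------------------------------------------------------------------------
# purity adjustment
# ---------------------------------------------------------------------------

def test_logr_adjust_identity_at_full_purity():
    x = np.linspace(-3, 3, 13)
    np.testing.assert_allclose(purity_adjust_logr(x, 1.0), x, atol=1e-12)


def test_logr_adjust_inverts_forward_mixing():
    obs = _mix_logr(np.array([1.0]), 0.5)
    assert obs[0] == pytest.approx(np.log2(1.5))
    assert purity_adjust_logr(obs, 0.5)[0] == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(purity=st.floats(0.2, 1.0), r=st.floats(-2.0, 2.0))
def test_logr_roundtrip_property(purity, r):
    back = purity_adjust_logr(_mix_logr(np.array([r]), purity), purity)[0]
    assert abs(back - r) < 1e-9


def test_logr_deep_loss_floored():
    # an observed loss so deep the mixture cannot explain it hits the floor
    out = purity_adjust_logr(-5.0, 0.5)
    assert out == pytest.approx(np.log2(0.01))


def test_logr_adjust_monotone():
    x = np.linspace(-4, 4, 200)
    y = purity_adjust_logr(x, 0.4)
    assert (np.diff(y) >= 0).all()


def test_vaf_adjust_values_and_cap():
    assert purity_adjust_vaf(0.3, 1.0) == pytest.approx(0.3)
    assert purity_adjust_vaf(0.2, 0.5) == pytest.approx(0.4)
    assert purity_adjust_vaf(0.8, 0.5) == pytest.approx(1.0)


def test_zero_purity_rejected():
    with pytest.raises(ValueError):
        purity_adjust_logr(0.0, 0.0)
    with pytest.raises(ValueError):
        purity_adjust_vaf(0.1, 0.0)


# ---------------------------------------------------------------------------
# paired delta
# ---------------------------------------------------------------------------

def _profile(logr, purity=1.0, chrom="chr1"):
    n = len(logr)
    probes = pd.DataFrame({"chromosome": [chrom] * n,
                           "position": np.arange(1, n + 1)})
    return CnProfile(probes=probes, logr=np.asarray(logr, float), purity=purity)


def test_identical_profiles_zero_delta():
    p = _profile(np.random.default_rng(0).normal(0, 0.3, 50), purity=0.7)
    d = paired_delta(p, p)
    np.testing.assert_allclose(d["delta"], 0.0, atol=1e-12)


def test_grid_mismatch_rejected():
    a = _profile([0.0, 0.1, 0.2])
    b = _profile([0.0, 0.1, 0.2])
    b.probes.loc[1, "position"] = 99
    with pytest.raises(ValueError, match="discordant"):
        paired_delta(a, b)
    c = _profile([0.0, 0.1])
    with pytest.raises(ValueError, match="length"):
        paired_delta(a, c)


def test_planted_loss_appears_as_negative_delta(paired_case):
    d = paired_delta(paired_case.pre, paired_case.post)
    lb = paired_case.truth["loss_block"]
    in_block = ((d["chromosome"] == lb["chromosome"])
                & d["position"].between(lb["start"], lb["end"]))
    assert d.loc[in_block, "delta"].mean() == pytest.approx(-1.0, abs=0.15)
    assert abs(d.loc[~in_block, "delta"].mean()) < 0.1


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_all_zero_delta_single_segment_per_chromosome():
    probes = pd.DataFrame({"chromosome": ["chr1"] * 40 + ["chr2"] * 40,
                           "position": list(range(1, 41)) * 2})
    seg = segment_values(probes, np.zeros(80))
    assert len(seg) == 2
    assert (seg["mean"] == 0.0).all()
    assert (seg["n_probes"] == 40).all()


def test_step_signal_recovered():
    rng = np.random.default_rng(42)
    x = np.concatenate([np.zeros(100), -np.ones(100)])
    x += rng.normal(0, 0.1, 200)
    probes = pd.DataFrame({"chromosome": "chr1",
                           "position": np.arange(1, 201)})
    seg = segment_values(probes, x).sort_values("start")
    assert len(seg) == 2
    assert abs(seg.iloc[0]["end"] - 100) <= 3
    assert seg.iloc[0]["mean"] == pytest.approx(0.0, abs=0.1)
    assert seg.iloc[1]["mean"] == pytest.approx(-1.0, abs=0.1)


def test_infinite_threshold_never_splits():
    rng = np.random.default_rng(1)
    probes = pd.DataFrame({"chromosome": "chr1",
                           "position": np.arange(1, 301)})
    seg = segment_values(probes, rng.normal(0, 1, 300),
                         t_threshold=math.inf)
    assert len(seg) == 1


def test_segments_tile_probes_with_exact_means(paired_case):
    d = paired_delta(paired_case.pre, paired_case.post)
    seg = segment_delta(d)
    total = 0
    for _, s in seg.iterrows():
        member = d[(d["chromosome"] == s["chromosome"])
                   & d["position"].between(s["start"], s["end"])]
        assert len(member) == s["n_probes"]
        assert s["mean"] == pytest.approx(member["delta"].mean(), abs=1e-12)
        total += len(member)
    assert total == len(d)


def test_min_probes_validated():
    probes = pd.DataFrame({"chromosome": "chr1", "position": [1, 2, 3]})
    with pytest.raises(ValueError):
        segment_values(probes, np.zeros(3), min_probes=1)


# ---------------------------------------------------------------------------
# variant rules
# ---------------------------------------------------------------------------

def test_retention_rule_on_toy_table(toy_variants):
    kept = filter_somatic_variants(toy_variants)
    assert sorted(kept["gene"]) == ["v1", "v2", "v5"]


def test_retention_removes_noncoding_and_low_af(toy_variants):
    kept = filter_somatic_variants(toy_variants)
    assert "v4" not in kept["gene"].tolist()   # non-coding despite high AF
    assert "v3" not in kept["gene"].tolist()   # both below 10%
    assert "v6" not in kept["gene"].tolist()   # exactly 10% is not > 10%


@settings(max_examples=60, deadline=None, derandomize=True)
@given(cut=st.floats(0.0, 0.5))
def test_retention_monotone_in_cutoff(cut):
    rng = np.random.default_rng(8)
    var = pd.DataFrame({
        "gene": [f"v{i}" for i in range(40)],
        "effect_class": rng.choice(["coding", "non_coding"], 40),
        "vaf_pre": rng.uniform(0, 0.6, 40),
        "vaf_post": rng.uniform(0, 0.6, 40),
        "dp_pre": 100, "dp_post": 100,
    })
    n_lo = len(filter_somatic_variants(var, af_cutoff=cut))
    n_hi = len(filter_somatic_variants(var, af_cutoff=min(cut + 0.1, 1.0)))
    assert n_hi <= n_lo


def test_sharing_three_state_rule():
    var = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "effect_class": "coding",
        "vaf_pre": [0.4, 0.3, 0.3, 0.0],
        "vaf_post": [0.4, 0.0, 0.05, 0.3],
        "dp_pre": [100, 100, 100, 100],
        "dp_post": [100, 100, 100, 100],
    })
    out = classify_variant_sharing(var)
    assert out["sharing"].tolist() == ["shared", "pre_only",
                                       "indeterminate", "post_only"]


def test_sharing_absence_needs_depth():
    var = pd.DataFrame({"gene": ["a"], "effect_class": ["coding"],
                        "vaf_pre": [0.4], "vaf_post": [0.0],
                        "dp_pre": [100], "dp_post": [5]})
    out = classify_variant_sharing(var)
    assert out["sharing"].iloc[0] == "indeterminate"


def test_sharing_symmetric_under_column_swap():
    rng = np.random.default_rng(9)
    var = pd.DataFrame({
        "gene": [f"v{i}" for i in range(30)],
        "effect_class": "coding",
        "vaf_pre": rng.uniform(0, 0.5, 30),
        "vaf_post": rng.uniform(0, 0.5, 30),
        "dp_pre": rng.integers(5, 200, 30),
        "dp_post": rng.integers(5, 200, 30),
    })
    a = classify_variant_sharing(var)["sharing"]
    swapped = var.rename(columns={"vaf_pre": "vaf_post", "vaf_post": "vaf_pre",
                                  "dp_pre": "dp_post", "dp_post": "dp_pre"})
    b = classify_variant_sharing(swapped)["sharing"]
    mapping = {"pre_only": "post_only", "post_only": "pre_only",
               "shared": "shared", "indeterminate": "indeterminate"}
    assert (a.map(mapping) == b).all()


def test_invalid_thresholds_rejected(toy_variants):
    with pytest.raises(ValueError):
        classify_variant_sharing(toy_variants, present_af=0.05, absent_af=0.1)


# ---------------------------------------------------------------------------
# frequency tests
# ---------------------------------------------------------------------------

def test_frequency_test_boundaries():
    assert aberration_frequency_test(0, 16, 0.2) == pytest.approx(1.0)
    assert aberration_frequency_test(10, 10, 0.5) == pytest.approx(2.0 ** -10)


def test_frequency_binomial_tail_matches_brute_force():
    from math import comb

    k, n, f = 7, 16, 0.19
    expected = sum(comb(n, j) * f**j * (1 - f) ** (n - j)
                   for j in range(k, n + 1))
    assert aberration_frequency_test(k, n, f) == pytest.approx(expected,
                                                               abs=1e-12)


def test_frequency_fisher_against_reference_cohort():
    from scipy.stats import fisher_exact

    p = aberration_frequency_test(7, 16, 0.2, ref_n=250)
    _, expected = fisher_exact([[7, 9], [50, 200]], alternative="greater")
    assert p == pytest.approx(expected, rel=1e-12)


def test_frequency_invalid_counts():
    with pytest.raises(ValueError):
        aberration_frequency_test(5, 4, 0.1)


# ---------------------------------------------------------------------------
# recurrent gene table
# ---------------------------------------------------------------------------

def _adjusted_segments(case):
    from neostrat import purity_adjust_logr as adj

    frames = []
    for tp, prof in (("pre", case.pre), ("post", case.post)):
        seg = segment_values(prof.probes, adj(prof.logr, prof.purity),
                             sample=tp)
        seg["timepoint"] = tp
        frames.append(seg)
    return pd.concat(frames, ignore_index=True)


def test_planted_pre_only_loss_counted_pre_not_post(paired_case):
    lb = paired_case.truth["loss_block"]
    regions = {"CDKN1B": (lb["chromosome"], lb["start"], lb["end"])}
    variants = filter_somatic_variants(paired_case.variants)
    variants = variants[variants["gene"] != "CDKN1B"]  # CN signal only
    seg = _adjusted_segments(paired_case)
    tab = recurrent_gene_table(variants, seg, regions)
    assert tab.loc["CDKN1B", "n_pre"] == 1
    assert tab.loc["CDKN1B", "n_post"] == 0


def test_shared_variant_counted_both_timepoints(paired_case):
    seg = _adjusted_segments(paired_case)
    tab = recurrent_gene_table(
        filter_somatic_variants(paired_case.variants), seg,
        {"TP53": ("chr9", 1, 10)})  # region off the probe span: variant only
    assert tab.loc["TP53", "n_pre"] == 1 and tab.loc["TP53", "n_post"] == 1


def test_no_signal_gives_zero_counts():
    seg = pd.DataFrame({"sample": ["pre"], "chromosome": ["chr1"],
                        "start": [1], "end": [1000], "n_probes": [100],
                        "mean": [0.0], "timepoint": ["pre"]})
    var = pd.DataFrame(columns=["gene", "effect_class", "vaf_pre", "vaf_post",
                                "dp_pre", "dp_post"])
    tab = recurrent_gene_table(var, seg, {"G1": ("chr1", 10, 20)})
    assert tab.loc["G1", "n_pre"] == 0 and tab.loc["G1", "n_post"] == 0
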