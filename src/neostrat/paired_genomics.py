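"""Paired pre/post-treatment genomic comparison.

Bulk copy-number and variant signals are mixtures of tumor and normal
cells. At tumor purity p, a probe with true tumor log2 ratio r is observed
as log2(p * 2^r + (1 - p)); a clonal heterozygous variant of cancer-cell
fraction VAF is observed at p * VAF. This module inverts both mixtures
(with an epsilon floor against deep losses), forms the probe-wise
pre-minus-post delta of purity-adjusted log ratios, segments the delta by
recursive binary splitting with a two-sample t stop rule, applies the
retention filter for somatic variants (coding effect and >10% allele
frequency in either sample), classifies variant sharing
(shared / pre_only / post_only / indeterminate), tests recurrent-aberration
frequencies against reference-cohort rates, and tabulates per-gene
aberration status per timepoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

#: floor for the adjusted copy-number ratio (protects log2 of deep losses)
LOGR_EPSILON = 0.01
#: allele-frequency retention cutoff (strictly greater-than)
AF_RETENTION_CUTOFF = 0.10
#: adjusted-logR thresholds calling amplification / loss (~single copy)
AMP_THRESHOLD = 0.8
DEL_THRESHOLD = -0.8


@dataclass
class CnProfile:
    """Ordered probe-level copy-number log ratios with tumor purity.

    ``probes``: frame with chromosome and 1-based position, strictly
    increasing within chromosome; ``logr``: log2 tumor/normal ratio per
    probe; ``purity``: tumor-cell fraction in (0, 1].
    """

    probes: pd.DataFrame
    logr: np.ndarray
    purity: float

    def __post_init__(self):
        self.logr = np.asarray(self.logr, dtype=float)
        if len(self.logr) != len(self.probes):
            raise ValueError("logr length must match probe count")
        if not np.isfinite(self.logr).all():
            raise ValueError("non-finite logR values")
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")
        for _, grp in self.probes.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError("probe positions must be strictly increasing "
                                 "within each chromosome")


def read_cn_profile(path, purity: float) -> CnProfile:
    """Read a probe TSV (chrom, pos, logr) into a CnProfile."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        chrom, pos, logr = cols["chrom"], cols["pos"], cols["logr"]
    except KeyError as exc:
        raise ValueError(f"probe TSV must have chrom/pos/logr columns: {exc}")
    probes = pd.DataFrame({"chromosome": df[chrom], "position": df[pos]})
    return CnProfile(probes=probes, logr=df[logr].to_numpy(dtype=float),
                     purity=purity)


def write_cn_profile(profile: CnProfile, path) -> None:
    pd.DataFrame({
        "chrom": profile.probes["chromosome"],
        "pos": profile.probes["position"],
        "logr": profile.logr,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# purity adjustment
# ---------------------------------------------------------------------------

def purity_adjust_logr(logr_obs, purity: float, epsilon: float = LOGR_EPSILON):
    """Invert the tumor/normal mixture of a copy-number log ratio.

    logr_adj = log2(max((2^logr_obs - (1 - purity)) / purity, epsilon)).
    Monotone in logr_obs; values floored at epsilon are genuine deep losses
    or noise excursions below the invertible range.
    """
    if not (0 < purity <= 1):
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    ratio = (np.exp2(np.asarray(logr_obs, dtype=float)) - (1.0 - purity)) / purity
    return np.log2(np.maximum(ratio, epsilon))


def purity_adjust_vaf(vaf_obs, purity: float):
    """Scale an observed allele frequency to the tumor compartment.

    Under copy-neutral heterozygosity the tumor-cell VAF is vaf_obs /
    purity, capped at 1 (values above 1 indicate the assumption is violated
    — e.g. LOH — and are clipped).
    """
    if not (0 < purity <= 1):
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    return np.minimum(np.asarray(vaf_obs, dtype=float) / purity, 1.0)


# ---------------------------------------------------------------------------
# paired delta and segmentation
# ---------------------------------------------------------------------------

def paired_delta(pre: CnProfile, post: CnProfile) -> pd.DataFrame:
    """Probe-wise purity-adjusted pre-minus-post log-ratio difference.

    Both profiles must share an identical probe grid. A restored
    pre-treatment loss therefore shows as a negative delta. Returns a frame
    with chromosome, position and delta.
    """
    a, b = pre.probes.reset_index(drop=True), post.probes.reset_index(drop=True)
    if len(a) != len(b) or not (
            a["chromosome"].eq(b["chromosome"]).all()
            and a["position"].eq(b["position"]).all()):
        mism = (a["chromosome"].ne(b["chromosome"])
                | a["position"].ne(b["position"])) if len(a) == len(b) else None
        if mism is not None and mism.any():
            i = int(np.argmax(mism.to_numpy()))
            raise ValueError(
                "probe grids differ; first discordant probe at index "
                f"{i}: {a.iloc[i].tolist()} vs {b.iloc[i].tolist()}")
        raise ValueError(f"probe grids differ in length: {len(a)} vs {len(b)}")
    delta = (purity_adjust_logr(pre.logr, pre.purity)
             - purity_adjust_logr(post.logr, post.purity))
    out = a.copy()
    out["delta"] = delta
    return out


def _t_statistic(sum_l, ss_l, n_l, sum_r, ss_r, n_r) -> float:
    """Pooled two-sample t for a candidate split (inf on a clean step)."""
    m_l, m_r = sum_l / n_l, sum_r / n_r
    sse = (ss_l - sum_l ** 2 / n_l) + (ss_r - sum_r ** 2 / n_r)
    dof = n_l + n_r - 2
    if dof <= 0:
        return 0.0
    sp2 = max(sse / dof, 0.0)
    denom = math.sqrt(sp2 * (1.0 / n_l + 1.0 / n_r))
    if denom == 0:
        return math.inf if m_l != m_r else 0.0
    return (m_l - m_r) / denom


def _best_split(x: np.ndarray, min_probes: int):
    """Best split index (left size) and its |t| over admissible splits."""
    n = len(x)
    if n < 2 * min_probes:
        return None, 0.0
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total, total_sq = csum[-1], csq[-1]
    best_i, best_t = None, 0.0
    for i in range(min_probes, n - min_probes + 1):
        t = _t_statistic(csum[i - 1], csq[i - 1], i,
                         total - csum[i - 1], total_sq - csq[i - 1], n - i)
        if abs(t) > best_t:
            best_i, best_t = i, abs(t)
    return best_i, best_t


def _segment_chrom(x: np.ndarray, min_probes: int, t_threshold: float):
    """Recursive binary segmentation: list of (start_idx, end_idx) tiles."""
    def rec(lo: int, hi: int):
        i, t = _best_split(x[lo:hi], min_probes)
        if i is None or t <= t_threshold:
            return [(lo, hi)]
        return rec(lo, lo + i) + rec(lo + i, hi)

    return rec(0, len(x))


def segment_values(probes: pd.DataFrame, values: np.ndarray,
                   min_probes: int = 10, t_threshold: float = 4.0,
                   sample: str = "delta") -> pd.DataFrame:
    """Segment a probe-level signal per chromosome.

    Recursive binary segmentation: the split maximizing the two-sample t
    statistic between left and right means is accepted when |t| exceeds
    ``t_threshold`` and both sides hold at least ``min_probes`` probes;
    accepted splits recurse. The output tiles the probe set; ``mean`` is
    the exact arithmetic mean of member values.
    """
    if min_probes < 2:
        raise ValueError("min_probes must be >= 2")
    values = np.asarray(values, dtype=float)
    probes = probes.reset_index(drop=True)
    rows = []
    for chrom, grp in probes.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        x = values[idx]
        pos = grp["position"].to_numpy()
        for lo, hi in _segment_chrom(x, min_probes, t_threshold):
            rows.append({
                "sample": sample,
                "chromosome": chrom,
                "start": int(pos[lo]),
                "end": int(pos[hi - 1]),
                "n_probes": hi - lo,
                "mean": float(x[lo:hi].mean()),
            })
    return pd.DataFrame(rows)


def segment_delta(delta: pd.DataFrame, min_probes: int = 10,
                  t_threshold: float = 4.0, sample: str = "delta") -> pd.DataFrame:
    """Segment a paired pre-minus-post delta (see :func:`segment_values`)."""
    return segment_values(delta[["chromosome", "position"]],
                          delta["delta"].to_numpy(),
                          min_probes=min_probes, t_threshold=t_threshold,
                          sample=sample)


# ---------------------------------------------------------------------------
# somatic variants
# ---------------------------------------------------------------------------

def filter_somatic_variants(variants: pd.DataFrame,
                            af_cutoff: float = AF_RETENTION_CUTOFF) -> pd.DataFrame:
    """Retention filter: coding effect and VAF strictly above the cutoff in
    either the pre- or post-treatment sample (missing VAFs count as
    below)."""
    vaf_pre = variants["vaf_pre"].fillna(0.0)
    vaf_post = variants["vaf_post"].fillna(0.0)
    keep = ((vaf_pre > af_cutoff) | (vaf_post > af_cutoff)) \
        & (variants["effect_class"] == "coding")
    return variants[keep].copy()


def classify_variant_sharing(variants: pd.DataFrame,
                             present_af: float = 0.10,
                             absent_af: float = 0.02,
                             absent_min_depth: int = 20) -> pd.DataFrame:
    """Three-state presence per sample, combined into a sharing label.

    A variant is present in a sample when VAF >= ``present_af``, absent
    when VAF <= ``absent_af`` with depth >= ``absent_min_depth`` (calling
    absence needs adequate coverage), and uncertain otherwise. Sharing is
    shared / pre_only / post_only for the decisive combinations and
    indeterminate whenever either sample is uncertain.
    """
    if not absent_af < present_af:
        raise ValueError("absent_af must be below present_af")
    out = variants.copy()
    states = {}
    for tp in ("pre", "post"):
        vaf = out[f"vaf_{tp}"].to_numpy(dtype=float)
        dp = out[f"dp_{tp}"].to_numpy(dtype=float)
        present = vaf >= present_af
        absent = (np.nan_to_num(vaf, nan=0.0) <= absent_af) & (dp >= absent_min_depth)
        # missing VAF with adequate depth means no alt reads: absent
        absent |= np.isnan(vaf) & (dp >= absent_min_depth)
        state = np.full(len(out), "uncertain", dtype=object)
        state[absent] = "absent"
        state[np.nan_to_num(vaf, nan=0.0) >= present_af] = "present"
        states[tp] = state
    sharing = np.full(len(out), "indeterminate", dtype=object)
    sharing[(states["pre"] == "present") & (states["post"] == "present")] = "shared"
    sharing[(states["pre"] == "present") & (states["post"] == "absent")] = "pre_only"
    sharing[(states["pre"] == "absent") & (states["post"] == "present")] = "post_only"
    out["sharing"] = sharing
    return out


def aberration_frequency_test(k: int, n: int, ref_freq: float,
                              ref_n: int | None = None) -> float:
    """One-sided test of an aberration frequency against a reference cohort.

    With a reference cohort size, Fisher's exact test (greater) on the 2x2
    table of aberrated counts; otherwise the exact binomial upper tail
    P(X >= k | n, ref_freq).
    """
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0 <= ref_freq <= 1):
        raise ValueError("ref_freq must lie in [0, 1]")
    if ref_n is None:
        return float(binomtest(k, n, ref_freq, alternative="greater").pvalue)
    ref_k = round(ref_freq * ref_n)
    _, p = fisher_exact([[k, n - k], [ref_k, ref_n - ref_k]],
                        alternative="greater")
    return float(p)


# ---------------------------------------------------------------------------
# recurrent aberrations
# ---------------------------------------------------------------------------

def recurrent_gene_table(variants: pd.DataFrame, segments: pd.DataFrame,
                         gene_regions: dict,
                         amp_threshold: float = AMP_THRESHOLD,
                         del_threshold: float = DEL_THRESHOLD,
                         present_af: float = AF_RETENTION_CUTOFF) -> pd.DataFrame:
    """Per-gene aberration counts per timepoint.

    A gene is aberrated at a timepoint when a retained variant is present
    there (VAF >= ``present_af``) or its region overlaps a segment of the
    purity-adjusted profile for that timepoint whose mean exceeds the
    amplification threshold or falls below the loss threshold.

    ``segments`` must carry a ``timepoint`` column ('pre'/'post'), and may
    carry ``patient``; ``gene_regions`` maps gene -> (chromosome, start,
    end). Counts are numbers of patients aberrated (1 per patient at most).
    """
    var = variants.copy()
    seg = segments.copy()
    for df in (var, seg):
        if "patient" not in df.columns:
            df["patient"] = "case"
    if "timepoint" not in seg.columns:
        raise ValueError("segments need a 'timepoint' column")

    probe_span = {}
    for (chrom, tp_pat), grp in seg.groupby(["chromosome",
                                             seg["patient"] + ":" + seg["timepoint"]]):
        probe_span[(chrom, tp_pat)] = (grp["start"].min(), grp["end"].max())

    rows = []
    for gene, (chrom, start, end) in gene_regions.items():
        counts = {"pre": set(), "post": set()}
        gv = var[(var["gene"] == gene)]
        for _, v in gv.iterrows():
            for tp in ("pre", "post"):
                vaf = v.get(f"vaf_{tp}")
                if pd.notna(vaf) and vaf >= present_af:
                    counts[tp].add(v["patient"])
        gseg = seg[(seg["chromosome"] == chrom)
                   & (seg["start"] <= end) & (seg["end"] >= start)]
        covered = any(chrom == c for c, _ in probe_span)
        if not covered:
            warnings.warn(f"gene {gene} region {chrom}:{start}-{end} outside "
                          "the probe span; counted as not covered", stacklevel=2)
        for _, srow in gseg.iterrows():
            if srow["mean"] >= amp_threshold or srow["mean"] <= del_threshold:
                counts[srow["timepoint"]].add(srow["patient"])
        rows.append({"gene": gene, "chromosome": chrom,
                     "start": start, "end": end,
                     "n_pre": len(counts["pre"]), "n_post": len(counts["post"])})
    return pd.DataFrame(rows).set_index("gene")
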