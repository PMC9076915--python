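"""Readers, writers and packaged clinical fixtures.

The pipeline touches four plain-text formats:

* expression matrices — TSV, genes in rows (first column gene id), samples in
  columns, log2 scale;
* sample annotation — TSV with one row per sample and the clinical covariates
  (subtype, timepoint, NRI, pCR, recurrence-free survival, tumor purity);
* paired somatic variants — VCF 4.2 with exactly two sample columns (pre,
  post) carrying AD/DP, and GENE/EFFECT annotations in INFO;
* copy-number segments — SEG (sample, chrom, start, end, n_probes, mean),
  1-based inclusive coordinates.

Two clinical tables of the neoadjuvant cohort ship as packaged fixtures:
``table1_cohort.tsv`` (the 317-patient pre-treatment cohort, expanded
deterministically to per-sample rows from the published subtype x pCR counts)
and ``table2.tsv`` (the 22 patients with matched pre/post samples, 44 sample
rows, with DNA- and RNA-isolation tumor percentages).

Missing values are written as ``NA`` everywhere.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBTYPES = ("ERpos", "TN")
TIMEPOINTS = ("pre", "post")

ANNOTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "subtype",
    "timepoint",
    "nri",
    "pcr",
    "rfs_time",
    "rfs_event",
    "purity",
]

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "n_probes", "mean"]


class CohortIOError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV.

    The first column holds gene identifiers, the header row sample
    identifiers. Returns a float DataFrame indexed by gene with sample
    columns; row and column order are preserved.

    Raises :class:`CohortIOError` on duplicate gene/sample ids, non-numeric
    cells or non-finite values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=[], keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CohortIOError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise CohortIOError(f"duplicate sample id {dup!r} in {path}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise CohortIOError(f"non-numeric expression value in {path}: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise CohortIOError(f"non-finite expression value in {path}")
    values.index.name = "gene"
    return values


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def validate_expression(expr: pd.DataFrame) -> None:
    """Assert the ExpressionMatrix invariants (unique ids, finite values)."""
    if expr.index.duplicated().any():
        raise CohortIOError("duplicate gene ids")
    if expr.columns.duplicated().any():
        raise CohortIOError("duplicate sample ids")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise CohortIOError("non-finite expression values")


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV and enforce the column contracts.

    Required columns: sample_id, patient_id, subtype (ERpos|TN), timepoint
    (pre|post), nri, pcr, rfs_time, rfs_event, purity. ``NA`` denotes
    missing. Extra columns are preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"annotation missing columns: {missing}")
    for col in ("nri", "rfs_time", "rfs_event", "purity"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortIOError(f"duplicate sample_id {dup!r}")
    bad_subtype = set(df["subtype"].dropna()) - set(SUBTYPES)
    if bad_subtype:
        raise CohortIOError(f"unknown subtype code(s): {sorted(bad_subtype)}")
    bad_tp = set(df["timepoint"].dropna()) - set(TIMEPOINTS)
    if bad_tp:
        raise CohortIOError(f"unknown timepoint(s): {sorted(bad_tp)}")
    nri = df["nri"].dropna()
    if ((nri < 0) | (nri > 1)).any():
        bad = nri[(nri < 0) | (nri > 1)].iloc[0]
        raise CohortIOError(f"nri out of [0, 1]: {bad}")
    purity = df["purity"].dropna()
    if ((purity <= 0) | (purity > 1)).any():
        raise CohortIOError("purity out of (0, 1]")
    if (df["rfs_time"].notna() != df["rfs_event"].notna()).any():
        raise CohortIOError("rfs_event must be present iff rfs_time is present")
    tneg = df["rfs_time"].dropna()
    if (tneg < 0).any():
        raise CohortIOError("negative rfs_time")
    pcr = df["pcr"].dropna()
    bad_pcr = set(pcr) - {"yes", "no"}
    if bad_pcr:
        raise CohortIOError(f"unknown pcr value(s): {sorted(bad_pcr)}")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _fixture_path(name: str):
    return importlib.resources.files("neostrat.data") / name


def load_table1_cohort() -> pd.DataFrame:
    """The 317-patient pre-treatment cohort (per-sample expansion of the
    published subtype x pCR counts: ER+ 183 no / 7 yes / 10 missing,
    TN 65 no / 46 yes / 6 missing)."""
    return read_annotation(_fixture_path("table1_cohort.tsv"))


def load_table2_paired() -> pd.DataFrame:
    """The 22 patients with matched pre/post-chemotherapy samples (44 sample
    rows). ``purity`` is the DNA-isolation tumor percentage (used for
    genomics); ``purity_rna`` the RNA-isolation percentage (used for
    expression)."""
    return read_annotation(_fixture_path("table2.tsv"))


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-subtype response and pairing counts.

    ``pcr_pct`` follows the published convention of dividing by the full
    subtype size including samples with missing pCR status (so ER+ is
    7/200 = 3.5%); ``pcr_pct_nonmissing`` divides by determined cases only.
    Percentages are NaN (missing) when no pCR status is determined.
    """

    n_total: int
    subtype_counts: dict = field(default_factory=dict)
    pcr_counts: dict = field(default_factory=dict)       # subtype -> {yes,no,missing}
    pcr_pct: dict = field(default_factory=dict)          # subtype -> % yes of all
    pcr_pct_nonmissing: dict = field(default_factory=dict)
    median_nri: dict = field(default_factory=dict)       # subtype -> median or NaN
    paired_counts: dict = field(default_factory=dict)    # subtype -> n patients pre+post


def cohort_summary(annotation: pd.DataFrame,
                   denominator: str = "all") -> CohortSummary:
    """Summarise a cohort annotation table.

    Counts pre-treatment samples per subtype, tallies pCR yes/no/missing,
    computes the pCR percentage (``denominator='all'`` uses the full subtype
    column including missing, matching the published table; ``'nonmissing'``
    uses determined cases only), the median NRI over non-missing values, and
    the number of patients with both a pre and a post sample per subtype.
    """
    if annotation.empty:
        raise CohortIOError("empty annotation")
    if denominator not in ("all", "nonmissing"):
        raise ValueError("denominator must be 'all' or 'nonmissing'")
    pre = annotation[annotation["timepoint"] == "pre"]
    out = CohortSummary(n_total=int(pre["patient_id"].nunique()))
    for subtype, grp in pre.groupby("subtype"):
        n = len(grp)
        yes = int((grp["pcr"] == "yes").sum())
        no = int((grp["pcr"] == "no").sum())
        miss = int(grp["pcr"].isna().sum())
        out.subtype_counts[subtype] = n
        out.pcr_counts[subtype] = {"yes": yes, "no": no, "missing": miss}
        determined = yes + no
        out.pcr_pct[subtype] = 100.0 * yes / n if determined else float("nan")
        out.pcr_pct_nonmissing[subtype] = (
            100.0 * yes / determined if determined else float("nan"))
        nri = grp["nri"].dropna()
        out.median_nri[subtype] = float(nri.median()) if len(nri) else float("nan")
    # paired cohort: patients with both timepoints
    tp = annotation.groupby(["patient_id", "subtype"])["timepoint"].agg(set)
    paired = tp[tp.apply(lambda s: {"pre", "post"} <= s)]
    for subtype in annotation["subtype"].dropna().unique():
        out.paired_counts[subtype] = int(
            (paired.index.get_level_values("subtype") == subtype).sum())
    if denominator == "nonmissing":
        out.pcr_pct = dict(out.pcr_pct_nonmissing)
    return out


# ---------------------------------------------------------------------------
# paired somatic VCF
# ---------------------------------------------------------------------------

def read_paired_vcf(path) -> pd.DataFrame:
    """Read a two-sample (pre, post) somatic VCF into a variant table.

    Per sample, VAF = alt depth / DP; DP of 0 yields a missing VAF rather
    than a division error. INFO keys GENE and EFFECT populate the ``gene``
    and ``effect_class`` columns (EFFECT must be ``coding`` or
    ``non_coding``). Sample order in the VCF is taken as (pre, post).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if len(samples) != 2:
        raise CohortIOError(
            f"paired VCF must have exactly 2 sample columns, found {len(samples)}")
    records = []
    for var in vcf:
        ad = var.format("AD")
        dp = var.format("DP")
        if ad is None or dp is None:
            raise CohortIOError(
                f"missing AD/DP at {var.CHROM}:{var.POS}")
        row = {
            "chromosome": var.CHROM,
            "position": int(var.POS),
            "ref": var.REF,
            "alt": var.ALT[0] if var.ALT else ".",
            "gene": var.INFO.get("GENE", "."),
            "effect_class": var.INFO.get("EFFECT", "non_coding"),
        }
        for i, tp in enumerate(TIMEPOINTS):
            depth = int(np.atleast_1d(dp[i])[0])
            alt_depth = int(np.atleast_2d(ad)[i][-1])
            row[f"dp_{tp}"] = depth
            row[f"vaf_{tp}"] = alt_depth / depth if depth > 0 else np.nan
        records.append(row)
    vcf.close()
    df = pd.DataFrame(records, columns=[
        "chromosome", "position", "ref", "alt", "gene", "effect_class",
        "vaf_pre", "vaf_post", "dp_pre", "dp_post"])
    for tp in TIMEPOINTS:
        vaf = df[f"vaf_{tp}"].dropna()
        if ((vaf < 0) | (vaf > 1)).any():
            raise CohortIOError(f"vaf_{tp} out of [0, 1]")
    return df


def write_paired_vcf(variants: pd.DataFrame, path,
                     contigs: dict | None = None) -> None:
    """Write a variant table as a minimal two-sample VCF 4.2 (pre, post)."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="coding or non_coding">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpre\tpost",
    ]
    for _, v in variants.sort_values(["chromosome", "position"]).iterrows():
        fields = []
        for tp in TIMEPOINTS:
            dp = int(v[f"dp_{tp}"])
            vaf = v[f"vaf_{tp}"]
            alt_d = int(round(vaf * dp)) if dp > 0 and pd.notna(vaf) else 0
            fields.append(f"{dp - alt_d},{alt_d}:{dp}")
        info = f"GENE={v['gene']};EFFECT={v['effect_class']}"
        lines.append("\t".join([
            str(v["chromosome"]), str(int(v["position"])), ".", str(v["ref"]),
            str(v["alt"]), ".", "PASS", info, "AD:DP", fields[0], fields[1]]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SEG segments
# ---------------------------------------------------------------------------

def write_seg(segments: pd.DataFrame, path) -> None:
    """Write copy-number segments in SEG format (1-based inclusive).

    Segments must be sorted by (chromosome, start) within each sample and
    may not overlap on a chromosome.
    """
    seg = segments[SEG_COLUMNS].copy()
    for (sample, chrom), grp in seg.groupby(["sample", "chromosome"]):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
            raise CohortIOError(
                f"overlapping segments for sample {sample!r} on {chrom!r}")
    seg.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"SEG file missing columns: {missing}")
    return df
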