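"""Metagene scoring and HHL/LLH patient stratification.

A metagene score is the per-sample median log2 expression of the genes
assigned to one biological process (proliferation, immune response, ECM
organization). Each metagene is dichotomized at its cohort median — strictly
above the median is High, at or below is Low — and the three calls in
(proliferation, immune, ECM) order define the profile: HHL for (H, H, L),
LLH for (L, L, H), everything else "other". HHL tumors are the expected
good responders (highly proliferative, immune-infiltrated, ECM-poor); LLH
the poor responders.

Dichotomization thresholds are computed within the cohort being stratified,
so a core gene set learned on one subtype can be applied to another with
thresholds recomputed in that cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ranksums

from .synthetic_cohort import PROCESSES

_SCORE_COLS = {"proliferation": "score_prolif", "immune": "score_immune",
               "ecm": "score_ecm"}
_CALL_COLS = {"proliferation": "call_prolif", "immune": "call_immune",
              "ecm": "call_ecm"}


def metagene_scores(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Median log2 expression of each process's genes, per sample.

    ``assignment`` maps gene -> process; every process must contribute at
    least one gene present in the matrix. Returns a sample-indexed frame
    with score_prolif, score_immune, score_ecm.
    """
    out = pd.DataFrame(index=expr.columns.copy())
    out.index.name = "sample_id"
    for proc in PROCESSES:
        genes = assignment.index[assignment == proc]
        genes = [g for g in genes if g in expr.index]
        if not genes:
            raise ValueError(f"no genes assigned to process {proc!r} "
                             "are present in the expression matrix")
        out[_SCORE_COLS[proc]] = expr.loc[genes].median(axis=0)
    return out


def stratify(scores: pd.DataFrame, cohort_mask=None) -> pd.DataFrame:
    """Dichotomize metagene scores at cohort medians and assign profiles.

    ``cohort_mask`` selects the samples whose scores define the medians
    (default: all samples); calls are made for every sample in ``scores``.
    A sample is High on a process when its score is strictly above the
    cohort median, Low otherwise — so a single-sample cohort is all-Low and
    profiles ``other``. Degenerate (all-identical) scores trigger a warning
    and an all-Low call for that process.
    """
    out = scores.copy()
    if cohort_mask is None:
        cohort = scores
    else:
        cohort = scores.loc[cohort_mask]
    if cohort.empty:
        raise ValueError("cohort_mask selects no samples")
    for proc in PROCESSES:
        col = _SCORE_COLS[proc]
        ref = cohort[col].to_numpy(dtype=float)
        threshold = float(np.median(ref))
        if np.ptp(ref) == 0:
            warnings.warn(
                f"all {proc} scores identical in the stratification cohort; "
                "every sample called Low", stacklevel=2)
        out[_CALL_COLS[proc]] = np.where(out[col] > threshold, "H", "L")
    calls = out[[_CALL_COLS[p] for p in PROCESSES]].agg("".join, axis=1)
    out["profile"] = np.select([calls == "HHL", calls == "LLH"],
                               ["HHL", "LLH"], default="other")
    return out


def profile_response_tests(profiles: pd.DataFrame,
                           annotation: pd.DataFrame) -> dict:
    """Compare response between the HHL and LLH groups.

    Returns a report with group sizes, a two-sided Wilcoxon rank-sum test of
    NRI (HHL vs LLH), and a two-sided Fisher exact test of the 2x2
    responder table. A sample is a responder when the ``npcr`` annotation
    column (near-pCR call), if present, or otherwise ``pcr`` equals "yes".
    Tests whose groups are empty are skipped with a reason.
    """
    ann = annotation.set_index("sample_id").loc[profiles.index]
    report: dict = {"groups": {}}
    groups = {}
    for label in ("HHL", "LLH"):
        idx = profiles.index[profiles["profile"] == label]
        groups[label] = idx
        report["groups"][label] = int(len(idx))
    report["groups"]["other"] = int((profiles["profile"] == "other").sum())

    if len(groups["HHL"]) == 0 or len(groups["LLH"]) == 0:
        report["nri_wilcoxon"] = {"skipped": "empty HHL or LLH group"}
        report["response_fisher"] = {"skipped": "empty HHL or LLH group"}
        return report

    nri_h = ann.loc[groups["HHL"], "nri"].dropna()
    nri_l = ann.loc[groups["LLH"], "nri"].dropna()
    if len(nri_h) and len(nri_l):
        stat, p = ranksums(nri_h, nri_l)
        report["nri_wilcoxon"] = {
            "statistic": float(stat), "p": float(p),
            "n_hhl": int(len(nri_h)), "n_llh": int(len(nri_l)),
            "median_hhl": float(nri_h.median()), "median_llh": float(nri_l.median()),
        }
    else:
        report["nri_wilcoxon"] = {"skipped": "no non-missing NRI in a group"}

    resp_col = "npcr" if "npcr" in ann.columns else "pcr"
    table = np.zeros((2, 2), dtype=int)
    ok = True
    for i, label in enumerate(("HHL", "LLH")):
        status = ann.loc[groups[label], resp_col].dropna()
        if status.empty:
            ok = False
            break
        table[i, 0] = int((status == "yes").sum())
        table[i, 1] = int((status == "no").sum())
    if ok:
        odds, p = fisher_exact(table, alternative="two-sided")
        report["response_fisher"] = {
            "table": table.tolist(), "odds_ratio": float(odds), "p": float(p),
            "responder_column": resp_col,
        }
    else:
        report["response_fisher"] = {"skipped": "no determined response in a group"}
    return report
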