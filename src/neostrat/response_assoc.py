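"""Permutation-based association of gene expression with quantitative response.

Each gene's log2 expression is regressed on the response index (NRI); the
moderated statistic is d = r / (s + s0), with r the least-squares slope, s
its standard error and s0 a variance-stabilizing fudge factor chosen to
decouple d from the spread of s (Tusher-style percentile search). The null
distribution of d is built by permuting the response vector, and a
conservative symmetric-cutoff false discovery rate (pi0 = 1) is attached to
each gene, then monotonized so that q never increases with |d|.

The module also selects the FDR-thresholded "core enrichment" gene set,
groups core genes into the three response-associated processes by
average-linkage clustering on correlation distance (labelled by
user-supplied marker lists), and provides a hypergeometric gene-set overlap
test with Benjamini-Hochberg adjustment for batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .synthetic_cohort import PROCESSES


@dataclass
class SamResult:
    """Per-gene association results and the shared fudge factor.

    ``table`` columns: gene, r (slope, expression units per unit NRI),
    s (slope SE), d (moderated statistic), q (estimated FDR at the gene's
    own |d| cutoff, monotone non-increasing in |d|).
    """

    table: pd.DataFrame
    s0: float
    n_perm: int


def _slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene OLS slope of expression on y, with intercept.

    x: genes x samples; returns (slope, slope SE). Zero-variance genes get
    slope 0 and SE 0.
    """
    n = x.shape[1]
    yc = y - y.mean()
    syy = float(yc @ yc)
    xc = x - x.mean(axis=1, keepdims=True)
    r = xc @ yc / syy
    sgg = np.einsum("ij,ij->i", xc, xc)
    sse = np.maximum(sgg - r * r * syy, 0.0)
    with np.errstate(invalid="ignore"):
        s = np.sqrt(sse / max(n - 2, 1) / syy)
    zero = sgg <= 0
    r[zero] = 0.0
    s[zero] = 0.0
    return r, s


def _tusher_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor: the percentile of {s} minimizing the coefficient of
    variation of window-wise MADs of d across s-quantile windows.

    Falls back to median(s) when fewer than 100 genes are available.
    """
    ok = s > 0
    if ok.sum() < 100:
        return float(np.median(s[ok])) if ok.any() else 0.0
    s_ok, r_ok = s[ok], r[ok]
    qs = np.percentile(s_ok, np.arange(0, 101, 5))
    # windows: genes between consecutive 5%-quantiles of s
    edges = np.unique(np.percentile(s_ok, np.arange(0, 101, 5)))
    win = np.clip(np.searchsorted(edges, s_ok, side="right") - 1, 0, len(edges) - 2)
    best_cv, best_s0 = math.inf, float(np.median(s_ok))
    for cand in qs:
        d = r_ok / (s_ok + cand)
        mads = []
        for w in range(len(edges) - 1):
            dw = d[win == w]
            if len(dw) >= 3:
                mads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def sam_quantitative(expr: pd.DataFrame, y, n_perm: int = 1000,
                     seed: int = 0) -> SamResult:
    """SAM-style association of every gene with a quantitative outcome.

    Parameters
    ----------
    expr : genes x samples log2 expression matrix.
    y : response values, one per sample; NaN entries drop the sample for
        all genes (one shared mask).
    n_perm : permutations of y for the null (>= 100); when the number of
        distinct permutations n! is at most n_perm, all are enumerated.
    seed : RNG seed for the permutation draw.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != expr.shape[1]:
        raise ValueError("y length must equal the number of samples")
    mask = np.isfinite(y)
    y = y[mask]
    x = expr.to_numpy(dtype=float)[:, mask]
    n = len(y)
    if n < 3 or len(np.unique(y)) < 3:
        raise ValueError("y must have at least 3 distinct finite values")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    r, s = _slopes(x, y)
    s0 = _tusher_s0(r, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s + s0 > 0, r / (s + s0), 0.0)
    # flag constant genes by the data, not by s: float noise can leave a
    # tiny nonzero slope/SE on an exactly constant row
    zero_var = np.ptp(x, axis=1) == 0

    # permutation null
    if math.factorial(n) <= n_perm:
        perms = np.array(list(permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    abs_d = np.abs(d)
    n_genes = len(d)
    obs_ge = n_genes - np.searchsorted(np.sort(abs_d), abs_d, side="left")
    null_counts = np.empty((len(perms), n_genes), dtype=np.int64)
    for b, p in enumerate(perms):
        rb, sb = _slopes(x, y[p])
        with np.errstate(divide="ignore", invalid="ignore"):
            db = np.where(sb + s0 > 0, rb / (sb + s0), 0.0)
        null_counts[b] = n_genes - np.searchsorted(
            np.sort(np.abs(db)), abs_d, side="left")
    med_null = np.median(null_counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_ge > 0, med_null / obs_ge, 1.0)
    fdr = np.minimum(fdr, 1.0)
    # monotonize: q non-increasing in |d|
    order = np.argsort(-abs_d, kind="stable")
    q_sorted = np.minimum.accumulate(fdr[order][::-1])[::-1]
    q = np.empty_like(fdr)
    q[order] = q_sorted
    q[zero_var] = 1.0
    d = np.where(zero_var, 0.0, d)

    table = pd.DataFrame({"gene": expr.index, "r": r, "s": s, "d": d, "q": q})
    return SamResult(table=table.set_index("gene"), s0=s0, n_perm=len(perms))


def select_core_set(sam: SamResult, fdr: float) -> pd.DataFrame:
    """Genes with q < fdr, labelled by association sign, ordered |d| desc."""
    if not (0 <= fdr <= 1):
        raise ValueError("fdr must lie in [0, 1]")
    t = sam.table
    sel = t[(t["q"] < fdr) & np.isfinite(t["q"])].copy()
    sel["direction"] = np.where(sel["d"] >= 0, "positive", "negative")
    return sel.sort_values("d", key=np.abs, ascending=False, kind="stable")


def assign_processes(expr: pd.DataFrame, core_genes,
                     markers: dict | None = None, k: int = 3) -> pd.Series:
    """Cluster core genes into processes and label clusters by markers.

    Average-linkage hierarchical clustering on correlation distance
    (1 - Pearson across samples), cut at ``k`` clusters. Each cluster is
    labelled by the marker list (process -> gene list) with the largest
    overlap; ties raise; clusters matching no marker are named by size rank
    (``cluster_1`` the largest).
    """
    core_genes = [g for g in core_genes]
    if len(core_genes) < k:
        raise ValueError(f"need at least {k} core genes, got {len(core_genes)}")
    missing = set(core_genes) - set(expr.index)
    if missing:
        raise ValueError(f"core genes absent from matrix: {sorted(missing)[:5]}")
    x = expr.loc[core_genes].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    norm[norm == 0] = 1.0
    corr = (xc / norm[:, None]) @ (xc / norm[:, None]).T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = average(squareform(dist, checks=False))
    labels = fcluster(z, t=k, criterion="maxclust")

    clusters = {c: [g for g, l in zip(core_genes, labels) if l == c]
                for c in np.unique(labels)}
    names = {}
    if markers:
        for c, genes in clusters.items():
            overlaps = {p: len(set(genes) & set(mg)) for p, mg in markers.items()}
            best = max(overlaps.values())
            if best > 0:
                winners = [p for p, v in overlaps.items() if v == best]
                if len(winners) > 1:
                    raise ValueError(
                        f"ambiguous marker labelling for cluster of {len(genes)} "
                        f"genes: tie between {winners}")
                names[c] = winners[0]
    elif markers is not None:
        raise ValueError("empty marker lists supplied")
    unnamed = sorted((c for c in clusters if c not in names),
                     key=lambda c: -len(clusters[c]))
    for rank, c in enumerate(unnamed, start=1):
        names[c] = f"cluster_{rank}"
    out = pd.Series({g: names[c] for c, genes in clusters.items() for g in genes},
                    name="process")
    return out.loc[core_genes]


def geneset_overlap_test(set_a, set_b, universe_size: int) -> float:
    """Hypergeometric upper-tail probability of the observed overlap.

    P(X >= |a & b|) drawing |b| items from a universe containing |a|
    successes.
    """
    a, b = set(set_a), set(set_b)
    if max(len(a), len(b)) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    return float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def geneset_overlap_tests(pairs, universe_size: int) -> pd.DataFrame:
    """Batch of overlap tests with Benjamini-Hochberg adjustment.

    ``pairs``: mapping name -> (set_a, set_b). Returns a DataFrame with
    overlap size, p and bh_adjusted_p per test.
    """
    rows = []
    for name, (a, b) in pairs.items():
        p = geneset_overlap_test(a, b, universe_size)
        rows.append({"name": name, "overlap": len(set(a) & set(b)), "p": p})
    df = pd.DataFrame(rows).set_index("name")
    df["bh_adjusted_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
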