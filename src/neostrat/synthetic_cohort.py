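"""Synthetic neoadjuvant cohort generator.

Emulates the statistical structure the downstream analysis assumes, so that
every stage is testable without access to the deposited patient data:

* bulk log2 expression driven by three latent processes per sample —
  proliferation, immune response and extracellular-matrix (ECM)
  organization — plus unstructured null genes;
* a semi-continuous response index (NRI, 0 = no response, 1 = complete
  response) coupled to the latents with subtype-specific coefficients:
  response rises with proliferation and immune activity and falls with ECM
  expression;
* recurrence-free survival with a planted hazard ratio between the HHL
  (high proliferation / high immune / low ECM) and LLH profiles;
* paired pre/post-treatment copy-number profiles mixed with normal tissue
  at known tumor purity, including a planted pre-treatment-only loss
  (a CDKN1B-like restoration under therapy), and paired somatic variants
  with binomial read sampling including pre-only and post-only events.

All randomness flows from the single seed in :class:`SimConfig`; identical
configurations produce bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PROCESSES = ("proliferation", "immune", "ecm")


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Subtype sample sizes, NRI intercepts, sequencing depth, purity range and
    the planted hazard ratio default to the study cohort's characteristics
    (117 TN / 200 ER+; median NRI 0.67 / 0.29; >150x exome coverage; tumor
    percentages 40-90%; TN hazard ratio 0.29). Effect sizes and noise levels
    are fixed desk-scale choices documented in the methods note.
    """

    n_tn: int = 117
    n_er: int = 200
    n_genes_per_process: int = 50
    n_null_genes: int = 350
    beta_expr: float = 1.0          # expression shift per latent SD (log2 units)
    sigma_expr: float = 1.0         # per-gene noise SD (log2 units)
    # (b_prolif, b_immune, b_ecm): NRI = intercept + b_p z_p + b_i z_i - b_e z_e
    response_coefs: dict = field(default_factory=lambda: {
        "TN": (0.15, 0.10, 0.12),
        "ERpos": (0.08, 0.02, 0.03),
    })
    nri_intercepts: dict = field(default_factory=lambda: {
        "TN": 0.67, "ERpos": 0.29})
    sigma_nri: float = 0.1
    pcr_threshold: float = 0.95
    planted_log_hr: float = math.log(0.29)
    censor_rate: float = 0.3
    # paired-genomics block
    n_probes: int = 2000
    n_chromosomes: int = 4
    mean_block_probes: int = 50
    sigma_cn: float = 0.1           # probe-level logR noise SD
    purity_range: tuple = (0.4, 0.9)
    depth_mean: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tn", "n_er"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_tn + self.n_er <= 0:
            raise ValueError("cohort must contain at least one sample")
        counts = {
            "n_genes_per_process": self.n_genes_per_process,
            "n_probes": self.n_probes,
            "n_chromosomes": self.n_chromosomes,
            "mean_block_probes": self.mean_block_probes,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        v = self.n_null_genes
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(
                f"n_null_genes must be a nonnegative integer, got {v!r}")
        scalars = [self.beta_expr, self.sigma_expr, self.sigma_nri,
                   self.pcr_threshold, self.planted_log_hr, self.censor_rate,
                   self.sigma_cn, self.depth_mean, *self.purity_range]
        for st in self.response_coefs.values():
            scalars.extend(st)
        scalars.extend(self.nri_intercepts.values())
        if not all(math.isfinite(float(v)) for v in scalars):
            raise ValueError("non-finite value in SimConfig")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"purity_range must lie in (0, 1], got {self.purity_range}")
        if not (0 < self.pcr_threshold < 1):
            raise ValueError("pcr_threshold must lie in (0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["purity_range"] = list(self.purity_range)
        d["response_coefs"] = {k: list(v) for k, v in self.response_coefs.items()}
        return d


@dataclass
class LatentState:
    """Per-sample latent activities and the profile they imply.

    ``true_profile`` is HHL when (z_prolif > 0, z_immune > 0, z_ecm < 0),
    LLH for the mirrored sign pattern, and ``other`` otherwise.
    """

    table: pd.DataFrame  # sample_id, z_prolif, z_immune, z_ecm, true_profile


def _true_profile(z_p: np.ndarray, z_i: np.ndarray, z_e: np.ndarray) -> np.ndarray:
    prof = np.full(len(z_p), "other", dtype=object)
    prof[(z_p > 0) & (z_i > 0) & (z_e < 0)] = "HHL"
    prof[(z_p < 0) & (z_i < 0) & (z_e > 0)] = "LLH"
    return prof


def simulate_cohort(config: SimConfig):
    """Generate (expression, annotation, gene assignment, latent state).

    Expression of a process gene g in sample j is
    ``mu_g + beta_expr * z_proc(g),j + N(0, sigma_expr)``; null genes carry
    baseline plus noise only. NRI is the subtype intercept plus the signed
    latent combination, Gaussian noise, clamped to [0, 1]; pCR is the
    indicator NRI >= pcr_threshold.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_tn + config.n_er
    subtype = np.array(["TN"] * config.n_tn + ["ERpos"] * config.n_er)
    sample_ids = np.array([f"S{i:04d}" for i in range(n)])

    z = {p: rng.standard_normal(n) for p in PROCESSES}
    latents = LatentState(pd.DataFrame({
        "sample_id": sample_ids,
        "z_prolif": z["proliferation"],
        "z_immune": z["immune"],
        "z_ecm": z["ecm"],
        "true_profile": _true_profile(z["proliferation"], z["immune"], z["ecm"]),
    }))

    genes, assign, blocks = [], [], []
    for p in PROCESSES:
        ids = [f"{p.upper()[:4]}_{i:03d}" for i in range(config.n_genes_per_process)]
        genes += ids
        assign += [p] * len(ids)
        blocks.append((p, ids))
    null_ids = [f"NULL_{i:04d}" for i in range(config.n_null_genes)]
    genes += null_ids

    mu = rng.normal(7.0, 1.0, size=len(genes))
    expr = mu[:, None] + rng.normal(0.0, config.sigma_expr, size=(len(genes), n))
    row = 0
    for p, ids in blocks:
        expr[row:row + len(ids)] += config.beta_expr * z[p][None, :]
        row += len(ids)
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                              columns=sample_ids)

    assignment = pd.Series(assign, index=genes[: len(assign)], name="process")

    nri = np.empty(n)
    for st in np.unique(subtype):
        mask = subtype == st
        b_p, b_i, b_e = config.response_coefs[st]
        nri[mask] = (config.nri_intercepts[st]
                     + b_p * z["proliferation"][mask]
                     + b_i * z["immune"][mask]
                     - b_e * z["ecm"][mask])
    nri = np.clip(nri + rng.normal(0.0, config.sigma_nri, size=n), 0.0, 1.0)
    pcr = np.where(nri >= config.pcr_threshold, "yes", "no")

    annotation = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": sample_ids,
        "subtype": subtype,
        "timepoint": "pre",
        "nri": nri,
        "pcr": pcr,
        "rfs_time": np.nan,
        "rfs_event": np.nan,
        "purity": np.nan,
    })
    return expression, annotation, assignment, latents


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(annotation: pd.DataFrame, profiles: pd.Series,
                      planted_log_hr: float, censor_rate: float,
                      seed: int, baseline_hazard: float = 0.1) -> pd.DataFrame:
    """Plant exponential recurrence-free survival with a known hazard ratio.

    Event times are Exponential with hazard
    ``baseline_hazard * exp(planted_log_hr * I[profile])`` where LLH is the
    reference (multiplier 0), HHL gets the full planted log-HR and ``other``
    half of it. A fraction ``censor_rate`` of samples (independent
    Bernoulli) is right-censored uniformly on (0, event time). Returns a
    copy of the annotation with ``rfs_time``/``rfs_event`` filled.
    """
    ann = annotation.copy()
    missing = set(ann["sample_id"]) - set(profiles.index)
    if missing:
        raise ValueError(f"profiles missing for samples: {sorted(missing)[:5]}")
    prof = profiles.loc[ann["sample_id"]].to_numpy()
    mult = np.select([prof == "HHL", prof == "LLH"], [1.0, 0.0], default=0.5)
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(planted_log_hr * mult)
    times = rng.exponential(1.0 / hazard)
    event = np.ones(len(ann), dtype=int)
    censored = rng.random(len(ann)) < censor_rate
    ctimes = rng.uniform(0.0, times)
    times = np.where(censored, ctimes, times)
    event[censored] = 0
    ann["rfs_time"] = times
    ann["rfs_event"] = event
    return ann


# ---------------------------------------------------------------------------
# paired genomics
# ---------------------------------------------------------------------------

@dataclass
class PairedGenomicsResult:
    """Paired pre/post copy-number profiles, somatic variants and the truth.

    ``pre``/``post`` are :class:`neostrat.paired_genomics.CnProfile`;
    ``variants`` is a SomaticVariant table; ``truth`` records the planted
    copy-number blocks, clonal VAFs and sharing labels.
    """

    pre: object
    post: object
    variants: pd.DataFrame
    truth: dict

    def __iter__(self):  # allows pre, post, variants = result
        return iter((self.pre, self.post, self.variants))


#: canonical planted variants: (gene, effect_class, sharing, clonal VAF)
_PLANTED_VARIANTS = [
    ("TP53", "coding", "shared", 0.5),
    ("PIK3CA", "coding", "shared", 0.4),
    ("GATA3", "coding", "shared", 0.3),
    ("CDH1", "coding", "shared", 0.45),
    ("KMT2C", "coding", "shared", 0.35),
    ("CDKN1B", "coding", "pre_only", 0.4),
    ("RB1", "coding", "pre_only", 0.3),
    ("APC", "coding", "post_only", 0.4),
    ("CTNNB1", "coding", "post_only", 0.35),
    ("MALAT1", "non_coding", "shared", 0.5),
    ("NEAT1", "non_coding", "pre_only", 0.3),
    ("LOWFREQ1", "coding", "shared", 0.05),
]


def _mix_logr(r_true: np.ndarray, purity: float) -> np.ndarray:
    """Observed log2 ratio of a tumor/normal mixture at the given purity."""
    return np.log2(purity * np.exp2(r_true) + (1.0 - purity))


def simulate_paired_genomics(config: SimConfig) -> PairedGenomicsResult:
    """Generate one patient's paired pre/post copy-number and variant data.

    Probes are split into geometric-sized blocks over ``n_chromosomes``
    synthetic chromosomes; each block carries an integer copy-number state
    (mostly diploid, with shared gains/losses, a CCND1-like shared
    amplification and one CDKN1B-like block lost in the pre-treatment
    sample only). Observed probe logR is the purity mixture of the true
    ratio plus Gaussian noise; variant alt counts are Binomial(depth,
    purity * clonal VAF).
    """
    from .paired_genomics import CnProfile

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    # probe grid: geometric block sizes, assigned round-robin to chromosomes
    sizes = []
    total = 0
    while total < config.n_probes:
        s = int(rng.geometric(1.0 / config.mean_block_probes))
        s = min(max(s, 5), config.n_probes - total)
        sizes.append(s)
        total += s
    n_blocks = len(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    per_chrom = int(np.ceil(config.n_probes / config.n_chromosomes))
    probe_idx = np.arange(config.n_probes)
    chrom = np.array([f"chr{1 + i // per_chrom}" for i in probe_idx])
    pos = np.array([1 + 1000 * (i % per_chrom) for i in probe_idx])

    # true copy states: mostly 2; some shared events; planted pre-only loss
    cn_pre = np.full(config.n_probes, 2, dtype=float)
    cn_post = np.full(config.n_probes, 2, dtype=float)
    block_states = rng.choice([1, 2, 2, 2, 2, 2, 3, 4],
                              size=n_blocks)
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        cn_pre[sl] = cn_post[sl] = block_states[b]
    def _plantable(b: int) -> int:
        # planted blocks must sit on one chromosome and be wide enough for
        # the delta segmentation to resolve them
        while (chrom[bounds[b]] != chrom[bounds[b + 1] - 1]
               or sizes[b] < 25):
            b = (b + 1) % n_blocks
        return b

    # planted shared CCND1-like amplification: a mid-genome block at CN 6
    amp_block = _plantable(n_blocks // 3)
    sl_amp = slice(bounds[amp_block], bounds[amp_block + 1])
    cn_pre[sl_amp] = cn_post[sl_amp] = 6
    # planted pre-only single-copy loss (CDKN1B-like), restored post
    loss_block = _plantable((2 * n_blocks) // 3)
    if loss_block == amp_block:
        loss_block = _plantable((loss_block + 1) % n_blocks)
    sl_loss = slice(bounds[loss_block], bounds[loss_block + 1])
    cn_pre[sl_loss] = 1
    cn_post[sl_loss] = 2

    r_true_pre = np.log2(cn_pre / 2.0)
    r_true_post = np.log2(cn_post / 2.0)
    purity_pre, purity_post = rng.uniform(*config.purity_range, size=2)
    logr_pre = (_mix_logr(r_true_pre, purity_pre)
                + rng.normal(0.0, config.sigma_cn, config.n_probes))
    logr_post = (_mix_logr(r_true_post, purity_post)
                 + rng.normal(0.0, config.sigma_cn, config.n_probes))

    probes = pd.DataFrame({"chromosome": chrom, "position": pos})
    pre = CnProfile(probes=probes.copy(), logr=logr_pre, purity=float(purity_pre))
    post = CnProfile(probes=probes.copy(), logr=logr_post, purity=float(purity_post))

    # somatic variants
    var_rows = []
    truth_variants = []
    vchrom = rng.integers(1, config.n_chromosomes + 1, size=len(_PLANTED_VARIANTS))
    vpos = np.sort(rng.integers(1, per_chrom * 1000, size=len(_PLANTED_VARIANTS)))
    for k, (gene, effect, sharing, clonal_vaf) in enumerate(_PLANTED_VARIANTS):
        row = {"chromosome": f"chr{vchrom[k]}", "position": int(vpos[k]),
               "ref": "A", "alt": "T", "gene": gene, "effect_class": effect}
        for tp, purity in (("pre", purity_pre), ("post", purity_post)):
            present = sharing == "shared" or sharing == f"{tp}_only"
            depth = int(rng.poisson(config.depth_mean))
            p_obs = purity * clonal_vaf if present else 0.0
            alt = int(rng.binomial(depth, p_obs)) if depth > 0 else 0
            row[f"dp_{tp}"] = depth
            row[f"vaf_{tp}"] = alt / depth if depth > 0 else np.nan
        var_rows.append(row)
        truth_variants.append({"gene": gene, "effect_class": effect,
                               "sharing": sharing, "clonal_vaf": clonal_vaf})
    variants = pd.DataFrame(var_rows)

    truth = {
        "seed": int(config.seed),
        "purity_pre": float(purity_pre),
        "purity_post": float(purity_post),
        "loss_block": {
            "chromosome": str(chrom[sl_loss][0]),
            "start_probe": int(bounds[loss_block]),
            "end_probe": int(bounds[loss_block + 1] - 1),
            "start": int(pos[sl_loss][0]),
            "end": int(pos[sl_loss][-1]),
            "logr_true_pre": -1.0,
            "logr_true_post": 0.0,
        },
        "amp_block": {
            "chromosome": str(chrom[sl_amp][0]),
            "start": int(pos[sl_amp][0]),
            "end": int(pos[sl_amp][-1]),
            "logr_true": float(np.log2(3.0)),
            "gene": "CCND1",
        },
        "r_true_pre": r_true_pre.tolist(),
        "r_true_post": r_true_post.tolist(),
        "variants": truth_variants,
    }
    return PairedGenomicsResult(pre=pre, post=post, variants=variants, truth=truth)
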