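import numpy as np
import pandas as pd
import pytest

from neostrat import SimConfig, simulate_cohort, simulate_paired_genomics


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_tn=40, n_er=40, n_genes_per_process=15,
                     n_null_genes=45, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def paired_case():
    return simulate_paired_genomics(SimConfig(seed=5))


@pytest.fixture()
def toy_expression():
    genes = ["g1", "g2", "g3"]
    samples = ["s1", "s2"]
    return pd.DataFrame([[1.0, 2.0], [-2.5, 0.0], [3.0, 4.5]],
                        index=pd.Index(genes, name="gene"), columns=samples)


@pytest.fixture()
def toy_variants():
    """Six paired variants exercising the >10%/coding retention rule."""
    rows = [
        ("v1", 0.20, 0.00, "coding"),
        ("v2", 0.00, 0.20, "coding"),
        ("v3", 0.05, 0.05, "coding"),
        ("v4", 0.50, 0.50, "non_coding"),
        ("v5", 0.11, 0.00, "coding"),
        ("v6", 0.10, 0.10, "coding"),
    ]
    return pd.DataFrame([
        {"chromosome": "chr1", "position": 100 + i, "ref": "A", "alt": "T",
         "gene": name, "effect_class": eff, "vaf_pre": vp, "vaf_post": vq,
         "dp_pre": 100, "dp_post": 100}
        for i, (name, vp, vq, eff) in enumerate(rows)])
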