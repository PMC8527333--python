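import numpy as np
import pandas as pd
import pytest

from mitoupr.core_io import ExpressionMatrix
from mitoupr.synthetic_data import SyntheticConfig, generate


def make_matrix(values: dict[str, dict[str, float]], genotype_of: dict[str, str]) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from {gene: {sample: cpm}}."""
    df = pd.DataFrame(values).T
    reps: dict[str, int] = {}
    rows = []
    for sample in df.columns:
        genotype = genotype_of[sample]
        reps[genotype] = reps.get(genotype, 0) + 1
        rows.append((sample, genotype, reps[genotype]))
    meta = pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate"]).set_index("sample_id")
    return ExpressionMatrix(values=df, sample_meta=meta)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless synthetic dataset: DE calls are exact by construction."""
    cfg = SyntheticConfig(
        n_genes=120, n_signature=12, n_decoys_per_class=4,
        cv=0.0, ct_jitter_sd=0.0, n_isp1_nonresponders=2, seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study-design dataset (61 planted genes, cv 0.2, six reps)."""
    return generate(SyntheticConfig(seed=3))


@pytest.fixture
def six_genotype_matrix():
    """Two genes x six genotypes x 2 replicates with exact round numbers."""
    genotypes = ["WT", "atfs-1", "nuo-6", "nuo-6;atfs-1", "et15", "et17"]
    base = {"gA": 10.0, "gB": 40.0}
    fold = {"gA": {"nuo-6": 2.5, "et15": 2.0, "et17": 1.5, "nuo-6;atfs-1": 1.2},
            "gB": {}}
    values = {}
    genotype_of = {}
    for gene, b in base.items():
        values[gene] = {}
        for g in genotypes:
            f = fold[gene].get(g, 1.0)
            for r in (1, 2):
                sample = f"{g}_r{r}"
                genotype_of[sample] = g
                values[gene][sample] = b * f
    return make_matrix(values, genotype_of)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
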