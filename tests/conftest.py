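import numpy as np
import pandas as pd
import pytest

from ratebuffer import simdata as sd


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SimConfig(n_genes=300, seed=42, depth=2e6, n_replicates=2)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return sd.sample_gene_kinetics(small_cfg)


@pytest.fixture(scope="session")
def small_experiment(small_cfg, small_truth):
    return sd.simulate_labeling_counts(small_truth, small_cfg)


@pytest.fixture(scope="session")
def uniform_beta_experiment():
    """1000-gene experiment with uniform beta in [0.1, 1.4] and known truth."""
    rng = np.random.default_rng(5)
    n = 1000
    beta = rng.uniform(0.1, 1.4, n)
    y_ss = 100 * np.exp(rng.normal(0.0, 1.0, n))
    genes = [f"g{i:05d}" for i in range(n)]
    frames = []
    for geno in ("WT", "MUT"):
        frames.append(pd.DataFrame({
            "gene_id": genes, "genotype": geno, "alpha": beta * y_ss,
            "beta": beta, "y_ss": y_ss, "half_life_h": np.log(2) / beta,
            "category": "unchanged",
        }))
    truth = pd.concat(frames, ignore_index=True)
    cfg = sd.SimConfig(n_genes=n, seed=5, dispersion=0.02, depth=2e7)
    return truth, sd.simulate_labeling_counts(truth, cfg)
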