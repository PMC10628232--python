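import numpy as np
import pandas as pd
import pytest

from loopdiff.genome import GenomeLayout
from loopdiff import synthdata


@pytest.fixture
def small_layout():
    return GenomeLayout.from_dict({"chr1": 2_000_000, "chr2": 1_000_000})


@pytest.fixture
def base_config():
    """One 2-Mb chromosome at 25 kb: ~2,340 cis bin pairs below 1 Mb."""
    return synthdata.SimulationConfig(
        chrom_sizes={"chr1": 2_000_000},
        resolution=25_000,
        depth=500_000,
        n_tads=2,
        n_loops=8,
        n_differential=4,
        seed=0,
    )


@pytest.fixture
def truth_model(base_config):
    return synthdata.build_truth_model(base_config)


def nb_count_table(phi, m=500, n=3, mu=100.0, seed=0, lfc=None):
    """Two-group NB count table with optional per-feature log2FC vector."""
    from loopdiff.nbstats import CountTable

    rng = np.random.default_rng(seed)
    base = mu * np.exp(rng.normal(0, 0.5, m))
    lfc = np.zeros(m) if lfc is None else np.asarray(lfc)
    cols = {}
    for g, sign in (("A", -0.5), ("B", 0.5)):
        mu_g = base * 2.0 ** (sign * lfc)
        for r in range(n):
            if phi > 0:
                lam = rng.gamma(1.0 / phi, mu_g * phi)
                cols[f"{g}{r}"] = rng.poisson(lam)
            else:
                cols[f"{g}{r}"] = rng.poisson(mu_g)
    counts = pd.DataFrame(cols)
    groups = pd.Series([c[0] for c in counts.columns], index=counts.columns)
    return CountTable(counts, groups)


@pytest.fixture
def diffed_conditions():
    """Replicate matrices + groups for a model with planted differential loops."""

    def build(seed=0, n_differential=4, depth=500_000, diff_fold=4.0, n_loops=8):
        cfg = synthdata.SimulationConfig(
            chrom_sizes={"chr1": 2_000_000},
            depth=depth,
            n_tads=2,
            n_loops=n_loops,
            n_differential=n_differential,
            diff_fold=diff_fold,
            seed=seed,
        )
        model = synthdata.build_truth_model(cfg)
        mats, groups = {}, {}
        for cond in synthdata.CONDITIONS:
            for m in synthdata.sample_contact_replicates(model, cond, 2, seed=seed):
                mats[m.sample] = m
                groups[m.sample] = cond
        return model, mats, groups

    return build
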