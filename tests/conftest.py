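import numpy as np
import pandas as pd
import pytest

from hybridx import simulate as sim
from hybridx.io import CountMatrix, SampleMeta


@pytest.fixture(scope="session")
def small_expression():
    """One seeded small expression simulation shared across read-only tests."""
    cfg = sim.ExpressionSimConfig(n_genes=800, seed=11)
    return cfg, *sim.simulate_expression(cfg)


@pytest.fixture(scope="session")
def small_amplicon():
    cfg = sim.AmpliconSimConfig(ref_copies=3, true_copies=12, seed=5)
    genome, queries, truth = sim.simulate_amplicon_genome(cfg)
    depth = sim.simulate_depth(truth, cfg)
    return cfg, genome, queries, truth, depth


def two_group_nb_counts(n_genes: int, dispersion: float, seed: int, logfc=None,
                        mean_scale: float = 200.0) -> tuple[CountMatrix, np.ndarray]:
    """Minimal 3 vs 3 NB count matrix (dom vs mus, DIP) for calibration tests.

    Returns the matrix and the per-gene baseline means. ``logfc`` optionally
    gives per-gene log2 effects applied to the first group.
    """
    rng = np.random.default_rng(seed)
    base = mean_scale * rng.lognormal(0, 0.5, size=n_genes)
    shape = 1.0 / dispersion
    cols, samples = [], []
    for cross in ("dom", "mus"):
        mean = base * (2.0 ** logfc if (logfc is not None and cross == "dom") else 1.0)
        for rep in (1, 2, 3):
            lam = rng.gamma(shape, mean / shape)
            cols.append(rng.poisson(lam))
            samples.append(SampleMeta(f"{cross}_DIP_r{rep}", cross, "DIP", rep))
    counts = pd.DataFrame(
        np.column_stack(cols),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[s.sample_id for s in samples],
    )
    return CountMatrix(counts=counts, samples=samples), base


def genes_for(cm: CountMatrix, n_x: int = 0) -> pd.DataFrame:
    """Single-chromosome annotation for a constructed count matrix."""
    n = len(cm.gene_ids)
    chroms = ["X"] * n_x + ["chr1"] * (n - n_x)
    df = pd.DataFrame(
        {
            "chromosome": chroms,
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 2_000,
            "gene_id": cm.gene_ids,
            "exonic_length": np.full(n, 1_000),
        }
    )
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    df["order_index"] = np.arange(n)
    df["is_x"] = df["chromosome"] == "X"
    return df
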