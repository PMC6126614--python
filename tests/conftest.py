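import numpy as np
import pandas as pd
import pytest

import teprof


@pytest.fixture(scope="session")
def sim_dataset():
    """A modest simulated dataset with planted TE effects (seed-fixed)."""
    cfg = teprof.SimulationConfig(
        seed=11,
        n_genes=600,
        effect_sets=[
            teprof.EffectSet("TEup", 60, beta_te=1.0),
            teprof.EffectSet("TEdown", 60, beta_te=-1.0),
        ],
    )
    return teprof.simulate_counts(cfg)


@pytest.fixture
def small_counts():
    """Deterministic 4-gene x 4-sample matrix (2 strains x 2 fractions)."""
    genes = ["g1", "g2", "g3", "g4"]
    samples = ["A_total", "A_poly", "B_total", "B_poly"]
    counts = np.array(
        [
            [10, 20, 10, 10],
            [100, 100, 100, 100],
            [50, 25, 50, 50],
            [5, 5, 5, 5],
        ]
    )
    return teprof.CountMatrix(genes, samples, counts)


@pytest.fixture
def design_2x2x3():
    """Standard 12-sample sheet: 2 strains x 2 fractions x 3 replicates."""
    rows = []
    for strain in ("mutant", "rescue"):
        for fraction in ("total", "polysomal"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{strain}_{fraction}_r{rep}",
                        "strain": strain,
                        "fraction": fraction,
                        "replicate": rep,
                    }
                )
    return teprof.SampleDesign(pd.DataFrame(rows))


def make_counts_for_design(design, group_means, sf=None, seed=0, alpha=0.0):
    """Counts with exact or NB-sampled group means for a SampleDesign.

    group_means: dict {(strain, fraction): vector of per-gene means}.
    With alpha == 0 and no seed jitter the counts are the exact means
    (useful for closed-form checks).
    """
    df = design.frame
    n_genes = len(next(iter(group_means.values())))
    counts = np.zeros((n_genes, len(df)), dtype=np.int64)
    rng = np.random.default_rng(seed)
    for j, row in df.iterrows():
        mu = np.asarray(group_means[(row["strain"], row["fraction"])], dtype=float)
        if sf is not None:
            mu = mu * sf[j]
        if alpha > 0:
            lam = rng.gamma(1.0 / alpha, alpha * mu)
            counts[:, j] = rng.poisson(lam)
        else:
            counts[:, j] = np.round(mu).astype(np.int64)
    return teprof.CountMatrix(
        [f"g{i}" for i in range(n_genes)], list(df["sample_id"]), counts
    )
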