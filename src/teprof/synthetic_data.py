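"""Ground-truth simulators: NB count matrices, A254 traces, Cq tables.

Counts are drawn NB(mean = s_j * q_ij, dispersion = alpha_i) with
log2 q_ij = beta0_i + beta1_i * X_strain + beta2_i * X_fraction
          + beta3_i * X_strain * X_fraction,
where X_strain is 1 for the first configured strain and X_fraction is 1
for polysomal samples. The default scenario mirrors a two-strain,
two-fraction, three-replicate study with ~10% of genes carrying planted
fraction-specific (TE) effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_fixtures import CountMatrix, SampleDesign
from .polysome_profiles import ProfileTrace
from .qpcr import CqTable

__all__ = [
    "EffectSet",
    "SimulationConfig",
    "simulate_counts",
    "simulate_trace",
    "simulate_qpcr",
    "QpcrSimConfig",
]


@dataclass
class EffectSet:
    """A named gene subset with planted log2 coefficients."""

    name: str
    n_genes: int
    beta_strain: float = 0.0  # beta1, log2
    beta_fraction: float = 0.0  # beta2, log2
    beta_te: float = 0.0  # beta3 (interaction), log2

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")


def default_effect_sets(n_genes: int) -> list[EffectSet]:
    """~10% of genes with TE effects spanning |log2FC| in [0.25, 1.65]."""
    n_te = max(n_genes // 20, 1)
    return [
        EffectSet("TEup", n_te, beta_te=1.0),
        EffectSet("TEdown", n_te, beta_te=-1.0),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the count simulator; the seed is mandatory."""

    seed: int
    n_genes: int = 5000
    strains: tuple[str, str] = ("mutant", "rescue")
    n_replicates: int = 3
    mean_log2_mu: float = 7.5
    sd_log2_mu: float = 1.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    size_factors: list[float] | None = None
    effect_sets: list[EffectSet] = field(default_factory=list)

    fractions: tuple[str, str] = ("total", "polysomal")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per (strain, fraction) cell")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion trend parameters must be non-negative")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain names must be unique")
        n_effect = sum(e.n_genes for e in self.effect_sets)
        if n_effect > self.n_genes:
            raise ValueError("effect sets assign more genes than exist")

    @property
    def n_samples(self) -> int:
        return len(self.strains) * len(self.fractions) * self.n_replicates


def _sample_grid(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for strain in config.strains:
        for fraction in config.fractions:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{fraction}_r{rep}",
                        "strain": strain,
                        "fraction": fraction,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Draw an NB count matrix with its sample sheet and truth table.

    The truth table has one row per gene: beta0..beta3 (log2), the true
    dispersion alpha, and effect-set membership (empty string for
    background genes). Identical configs produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    grid = _sample_grid(config)
    n_genes, n_samples = config.n_genes, config.n_samples

    beta0 = rng.normal(config.mean_log2_mu, config.sd_log2_mu, size=n_genes)
    beta = np.zeros((n_genes, 3))  # beta1..beta3, log2
    membership = np.array([""] * n_genes, dtype=object)

    assignable = rng.permutation(n_genes)
    start = 0
    for eff in config.effect_sets:
        idx = assignable[start : start + eff.n_genes]
        start += eff.n_genes
        beta[idx, 0] = eff.beta_strain
        beta[idx, 1] = eff.beta_fraction
        beta[idx, 2] = eff.beta_te
        membership[idx] = eff.name

    mu_base = 2.0**beta0
    alpha = np.clip(
        config.dispersion_a0 + config.dispersion_a1 / mu_base, 0.0, None
    )

    if config.size_factors is not None:
        sf = np.asarray(config.size_factors, dtype=float)
        if sf.shape != (n_samples,):
            raise ValueError(f"need {n_samples} size factors, got {sf.shape}")
    else:
        lo, hi = config.size_factor_range
        sf = rng.uniform(lo, hi, size=n_samples)

    x_strain = (grid["strain"] == config.strains[0]).to_numpy(dtype=float)
    x_fraction = (grid["fraction"] == "polysomal").to_numpy(dtype=float)
    design_rows = np.column_stack([x_strain, x_fraction, x_strain * x_fraction])

    log2_q = beta0[:, None] + beta @ design_rows.T
    mu = sf[None, :] * 2.0**log2_q

    # gamma-Poisson mixture == NB; degenerates to Poisson as alpha -> 0
    alpha_mat = np.broadcast_to(alpha[:, None], mu.shape)
    counts = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha_mat < 1e-12
    counts[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        shape = 1.0 / alpha_mat[~tiny]
        lam = rng.gamma(shape, alpha_mat[~tiny] * mu[~tiny])
        counts[~tiny] = rng.poisson(lam)

    gene_ids = [f"gene{str(i + 1).zfill(len(str(n_genes)))}" for i in range(n_genes)]
    cm = CountMatrix(gene_ids, list(grid["sample_id"]), counts)
    design = SampleDesign(grid)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "beta0": beta0,
            "beta1": beta[:, 0],
            "beta2": beta[:, 1],
            "beta3": beta[:, 2],
            "alpha": alpha,
            "effect_set": membership.astype(str),
        }
    ).set_index("gene")
    return cm, design, truth


def simulate_trace(
    peak_spec: list[tuple[float, float, float]],
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    x_range: tuple[float, float] = (0.0, 10.0),
    step: float = 0.01,
    label: str = "",
) -> ProfileTrace:
    """Sum-of-Gaussians absorbance trace with optional white noise.

    ``peak_spec`` is a list of (center, width, area) with strictly
    increasing centers; each Gaussian integrates to its area.
    """
    if not peak_spec:
        raise ValueError("need at least one peak")
    centers = [c for c, _, _ in peak_spec]
    if len(set(centers)) != len(centers):
        raise ValueError("peak centers must be distinct")
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise ValueError("peak centers must be strictly increasing")
    if any(w <= 0 for _, w, _ in peak_spec):
        raise ValueError("peak widths must be positive")

    x = np.arange(x_range[0], x_range[1] + step / 2, step)
    y = np.full_like(x, float(baseline))
    for center, width, area in peak_spec:
        y += area / (width * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - center) / width) ** 2
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    return ProfileTrace(x, y, label=label)


@dataclass
class QpcrSimConfig:
    """Planted relative abundances per condition for the Cq simulator."""

    seed: int
    abundances: dict[str, dict[str, float]]  # condition -> gene -> relative level
    reference_genes: list[str]
    n_replicates: int = 3
    efficiency: float = 2.0
    noise_sd: float = 0.0
    base_cq: float = 25.0

    def __post_init__(self) -> None:
        if self.efficiency <= 1.0:
            raise ValueError("amplification efficiency must be > 1")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if not self.reference_genes:
            raise ValueError("need at least one reference gene")


def simulate_qpcr(config: QpcrSimConfig) -> CqTable:
    """Cq table from planted abundances; reference genes are constant.

    Cq = base_cq - log_E(abundance) + noise, so doubling the abundance at
    E = 2 lowers Cq by exactly one cycle.
    """
    rng = np.random.default_rng(config.seed)
    log_e = np.log(config.efficiency)
    rows = []
    for condition, gene_levels in config.abundances.items():
        levels = dict(gene_levels)
        for ref in config.reference_genes:
            levels.setdefault(ref, 1.0)
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{condition}_r{rep}"
            for gene, level in levels.items():
                if level <= 0:
                    raise ValueError(f"abundance must be positive ({gene!r})")
                cq = config.base_cq - np.log(level) / log_e
                if config.noise_sd > 0:
                    cq += rng.normal(0.0, config.noise_sd)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "gene": gene,
                        "cq": float(cq),
                        "efficiency": config.efficiency,
                        "is_reference": gene in config.reference_genes,
                    }
                )
    return CqTable(pd.DataFrame(rows))
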