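"""Per-gene negative-binomial GLM fitting, Wald tests, and BH adjustment.

The model for a gene is log(mu_j) = x_j' beta with NB errors at a fixed
(shrunken) dispersion. Counts are size-factor normalized before fitting,
so the mean structure is expressed on the common (normalized) scale; for a
saturated factorial design the fitted group means then equal the
arithmetic means of normalized counts regardless of dispersion, making the
interaction coefficient coincide exactly with the plug-in log2
ratio-of-ratios of group means. Coefficients and standard errors are
reported in log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dispersion import estimate_dispersions
from .io_fixtures import CountMatrix, SampleDesign
from .normalization import normalize_counts, size_factors_median_ratio

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "TestResult",
    "build_design",
    "build_oneway_design",
    "fit_nb_glm",
    "fit_nb_glm_batch",
    "wald_test",
    "adjust_bh",
    "run_de",
]

LN2 = np.log(2.0)
MAX_ABS_LOG2_COEF = 30.0  # beyond this the fit is treated as divergent


@dataclass
class DesignMatrix:
    """Sample x coefficient matrix with treatment (0/1) coding."""

    matrix: np.ndarray
    columns: list[str]
    sample_ids: list[str]
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (
            len(self.sample_ids),
            len(self.columns),
        ):
            raise ValueError("design matrix shape mismatch")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError(
                "design matrix is rank deficient (a factor combination has no samples)"
            )

    @property
    def n_coefs(self) -> int:
        return len(self.columns)


def build_design(
    design: SampleDesign, strain_ref: str, fraction_ref: str = "total"
) -> DesignMatrix:
    """Interaction design (intercept, strain, fraction, strain:fraction).

    Treatment coding with the given reference levels: the strain column is
    1 for the non-reference strain, the fraction column 1 for the
    non-reference fraction, and the interaction column their product.
    """
    df = design.frame
    strains = sorted(set(df["strain"]))
    if len(strains) != 2:
        raise ValueError(
            f"interaction design needs exactly 2 strains, got {strains}; "
            "run pairwise contrasts for more"
        )
    if strain_ref not in strains:
        raise ValueError(f"reference strain {strain_ref!r} not among {strains}")
    fractions = sorted(set(df["fraction"]))
    if len(fractions) != 2:
        raise ValueError(f"need both RNA fractions present, got {fractions}")
    if fraction_ref not in fractions:
        raise ValueError(f"reference fraction {fraction_ref!r} not among {fractions}")
    strain_alt = next(s for s in strains if s != strain_ref)
    fraction_alt = next(f for f in fractions if f != fraction_ref)
    xs = (df["strain"] == strain_alt).to_numpy(dtype=float)
    xt = (df["fraction"] == fraction_alt).to_numpy(dtype=float)
    mat = np.column_stack([np.ones(len(df)), xs, xt, xs * xt])
    return DesignMatrix(
        matrix=mat,
        columns=[
            "intercept",
            f"strain[{strain_alt}]",
            f"fraction[{fraction_alt}]",
            f"strain[{strain_alt}]:fraction[{fraction_alt}]",
        ],
        sample_ids=list(df["sample_id"]),
        reference={"strain": strain_ref, "fraction": fraction_ref},
    )


def build_oneway_design(
    design: SampleDesign, factor: str, level_alt: str, level_ref: str
) -> DesignMatrix:
    """Two-group design (intercept, factor) for a simple contrast."""
    df = design.frame
    levels = set(df[factor])
    for lv in (level_alt, level_ref):
        if lv not in levels:
            raise ValueError(f"{factor} level {lv!r} not present in design")
    x = (df[factor] == level_alt).to_numpy(dtype=float)
    mat = np.column_stack([np.ones(len(df)), x])
    return DesignMatrix(
        matrix=mat,
        columns=["intercept", f"{factor}[{level_alt}]"],
        sample_ids=list(df["sample_id"]),
        reference={factor: level_ref},
    )


@dataclass
class GLMFit:
    """Per-gene NB GLM coefficients (log2), SEs, fitted means, flags."""

    gene_ids: list[str]
    columns: list[str]
    beta: np.ndarray  # (G, p), log2 scale
    se: np.ndarray  # (G, p), log2 scale
    mu: np.ndarray  # (G, m), fitted normalized means
    converged: np.ndarray  # (G,) bool

    def coef_index(self, name: str) -> int:
        return self.columns.index(name)


def fit_nb_glm_batch(
    norm: np.ndarray,
    dm: DesignMatrix,
    alpha: np.ndarray,
    tol_log2: float = 1e-8,
    max_iter: int = 100,
    gene_ids: list[str] | None = None,
) -> GLMFit:
    """IRLS NB GLM fits for many genes at once.

    Parameters
    ----------
    norm : (G, m) size-factor-normalized counts (non-negative reals).
    dm : design matrix shared across genes.
    alpha : (G,) fixed NB dispersions (from the shrinkage step).

    Convergence is max |delta beta| < ``tol_log2`` in log2 units within
    ``max_iter`` iterations; divergent fits (|log2 coefficient| above 30)
    and all-zero genes are flagged unconverged.
    """
    y = np.asarray(norm, dtype=float)
    x = dm.matrix
    n_genes, m = y.shape
    p = x.shape[1]
    a = np.asarray(alpha, dtype=float)
    if a.shape != (n_genes,):
        raise ValueError("alpha must have one entry per gene")
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n_genes)]

    active = (y > 0).any(axis=1) & np.isfinite(a)
    beta = np.zeros((n_genes, p))
    # start from a least-squares fit on log counts (pseudocount for zeros)
    eta0 = np.log(np.maximum(y, 0.5))
    beta[active] = np.linalg.lstsq(x, eta0[active].T, rcond=None)[0].T

    converged = np.zeros(n_genes, dtype=bool)
    todo = active.copy()
    for _ in range(max_iter):
        if not todo.any():
            break
        idx = np.flatnonzero(todo)
        eta = beta[idx] @ x.T
        eta = np.clip(eta, -MAX_ABS_LOG2_COEF * LN2, MAX_ABS_LOG2_COEF * LN2)
        mu = np.exp(eta)
        w = mu / (1.0 + a[idx, None] * mu)  # expected-information weights
        z = eta + (y[idx] - mu) / mu
        xtw = x.T[None, :, :] * w[:, None, :]  # (g, p, m)
        lhs = xtw @ x  # (g, p, p)
        rhs = np.einsum("gpm,gm->gp", xtw, z)
        try:
            new_beta = np.linalg.solve(lhs, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.array(
                [np.linalg.lstsq(lh, rh, rcond=None)[0] for lh, rh in zip(lhs, rhs)]
            )
        delta = np.abs(new_beta - beta[idx]).max(axis=1) / LN2
        beta[idx] = new_beta
        done = delta < tol_log2
        converged[idx[done]] = True
        todo[idx[done]] = False

    diverged = np.abs(beta / LN2).max(axis=1) > MAX_ABS_LOG2_COEF
    converged &= ~diverged
    converged &= active

    eta = np.clip(beta @ x.T, -MAX_ABS_LOG2_COEF * LN2, MAX_ABS_LOG2_COEF * LN2)
    mu = np.exp(eta)

    # observed information: -d2l/deta2 = mu (1 + alpha y) / (1 + alpha mu)^2
    a_col = np.where(np.isfinite(a), a, 0.0)[:, None]
    w_obs = mu * (1.0 + a_col * y) / (1.0 + a_col * mu) ** 2
    xtw = x.T[None, :, :] * w_obs[:, None, :]
    info = xtw @ x
    se = np.full((n_genes, p), np.nan)
    ok = converged.copy()
    if ok.any():
        try:
            cov = np.linalg.inv(info[ok])
            var = np.einsum("gpp->gp", cov)
        except np.linalg.LinAlgError:
            var = np.full((int(ok.sum()), p), np.nan)
        var = np.where(var > 0, var, np.nan)
        se[ok] = np.sqrt(var)
    return GLMFit(
        gene_ids=list(gene_ids),
        columns=list(dm.columns),
        beta=beta / LN2,
        se=se / LN2,
        mu=mu,
        converged=converged,
    )


def fit_nb_glm(counts_gene, dm: DesignMatrix, sf, alpha: float) -> GLMFit:
    """Single-gene convenience wrapper around :func:`fit_nb_glm_batch`."""
    y = np.asarray(counts_gene, dtype=float)
    s = np.asarray(sf.to_numpy() if hasattr(sf, "to_numpy") else sf, dtype=float)
    if y.shape != s.shape or y.shape[0] != dm.matrix.shape[0]:
        raise ValueError("counts, size factors, and design must align")
    return fit_nb_glm_batch((y / s)[None, :], dm, np.array([alpha]))


@dataclass
class TestResult:
    """Wald statistics for one coefficient across genes."""

    gene_ids: list[str]
    coef: str
    log2fc: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    padj: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "log2fc": self.log2fc,
            "se": self.se,
            "stat": self.stat,
            "p": self.p,
        }
        if self.padj is not None:
            data["padj"] = self.padj
        return pd.DataFrame(data, index=self.gene_ids)


def wald_test(fit: GLMFit, coef_index: int) -> TestResult:
    """Two-sided Wald test of one coefficient: z = beta / SE."""
    beta = fit.beta[:, coef_index]
    se = fit.se[:, coef_index]
    valid = fit.converged & np.isfinite(se) & (se > 0)
    stat = np.where(valid, beta / np.where(se > 0, se, np.nan), np.nan)
    p = np.where(valid, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    return TestResult(
        gene_ids=fit.gene_ids,
        coef=fit.columns[coef_index],
        log2fc=beta,
        se=se,
        stat=stat,
        p=p,
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing (NaN) entries are excluded from the family size m and returned
    as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _testable_mask(counts: np.ndarray, min_nonzero: int = 2) -> np.ndarray:
    return (counts > 0).sum(axis=1) >= min_nonzero


def run_de(
    counts: CountMatrix,
    design: SampleDesign,
    contrast: tuple[str, str, str],
    subset: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group differential expression within an optional sample subset.

    Pipeline: subset samples -> median-ratio size factors -> dispersion
    estimation/shrinkage -> per-gene NB GLM (intercept + factor) -> Wald
    test on the factor coefficient -> BH adjustment. Genes with nonzero
    counts in fewer than 2 subset samples get missing statistics.

    Returns a frame with columns gene, baseMean, log2fc, se, stat, p, padj.
    """
    factor, level_alt, level_ref = contrast
    design.check_against(counts)
    sub_design = design.subset(**subset) if subset else design
    if factor not in sub_design.frame.columns:
        raise KeyError(f"unknown contrast factor {factor!r}")

    if level_alt == level_ref:
        # identical levels: fold change is identically zero by construction
        sub = sub_design.subset(**{factor: level_alt})
        cm = counts.subset_samples(sub.sample_ids)
        sf = size_factors_median_ratio(cm)
        norm = normalize_counts(cm, sf)
        base_mean = norm.mean(axis=1).to_numpy()
        n = counts.n_genes
        return pd.DataFrame(
            {
                "gene": counts.gene_ids,
                "baseMean": base_mean,
                "log2fc": np.zeros(n),
                "se": np.full(n, np.nan),
                "stat": np.zeros(n),
                "p": np.ones(n),
                "padj": np.ones(n),
            }
        ).set_index("gene")

    sub = sub_design.subset(**{factor: {level_alt, level_ref}})
    for lv in (level_alt, level_ref):
        if (sub.frame[factor] == lv).sum() == 0:
            raise ValueError(f"contrast level {lv!r} has no samples in the subset")
    cm = counts.subset_samples(sub.sample_ids)
    dm = build_oneway_design(sub, factor, level_alt, level_ref)

    sf = size_factors_median_ratio(cm)
    norm = normalize_counts(cm, sf)
    testable = _testable_mask(cm.counts)

    norm_t = norm.loc[testable]
    disp = estimate_dispersions(norm_t, dm.matrix)
    fit = fit_nb_glm_batch(
        norm_t.to_numpy(), dm, disp.shrunken, gene_ids=list(norm_t.index)
    )
    test = wald_test(fit, coef_index=1)
    padj = adjust_bh(test.p)

    out = pd.DataFrame(
        {
            "baseMean": np.full(counts.n_genes, np.nan),
            "log2fc": np.nan,
            "se": np.nan,
            "stat": np.nan,
            "p": np.nan,
            "padj": np.nan,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    out["baseMean"] = norm.mean(axis=1).to_numpy()
    sel = out.index[testable]
    out.loc[sel, "log2fc"] = test.log2fc
    out.loc[sel, "se"] = test.se
    out.loc[sel, "stat"] = test.stat
    out.loc[sel, "p"] = test.p
    out.loc[sel, "padj"] = padj
    return out
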