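"""Differential translational efficiency and gene classification.

TE contrasts fit the full interaction model on all samples of two strains
(both RNA fractions) and Wald-test the strain x fraction interaction. The
plug-in estimate log2((A_poly/A_total)/(B_poly/B_total)) from normalized
group means is reported alongside; for a saturated 2x2 design with joint
size factors the two coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dispersion import estimate_dispersions
from .io_fixtures import CountMatrix, SampleDesign
from .nb_glm import adjust_bh, build_design, fit_nb_glm_batch, wald_test
from .normalization import normalize_counts, size_factors_median_ratio

__all__ = [
    "run_te",
    "plug_in_te_lfc",
    "classify_genes",
    "VENN_LABELS",
]

VENN_LABELS = (
    "poly_only_up",
    "both_up",
    "total_only_up",
    "poly_only_down",
    "both_down",
    "total_only_down",
    "ns",
)


def plug_in_te_lfc(norm_means) -> float:
    """log2 ratio-of-ratios from four positive normalized group means.

    ``norm_means`` is ((A_poly, A_total), (B_poly, B_total)) or a flat
    length-4 sequence in that order. Any non-positive mean yields NaN.
    """
    vals = np.asarray(norm_means, dtype=float).ravel()
    if vals.shape != (4,):
        raise ValueError("expected four group means (A_poly, A_total, B_poly, B_total)")
    a_poly, a_total, b_poly, b_total = vals
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        return float("nan")
    return float(np.log2((a_poly / a_total) / (b_poly / b_total)))


def _per_fraction_size_factors(cm: CountMatrix, design: SampleDesign) -> pd.Series:
    parts = []
    for fraction in ("total", "polysomal"):
        sub = design.subset(fraction=fraction)
        if len(sub.frame) == 0:
            continue
        parts.append(size_factors_median_ratio(cm.subset_samples(sub.sample_ids)))
    return pd.concat(parts).loc[cm.samples]


def run_te(
    counts: CountMatrix,
    design: SampleDesign,
    strain_a: str,
    strain_b: str,
    sf_scope: str = "joint",
) -> pd.DataFrame:
    """Differential TE of strain_a relative to strain_b.

    Returns a frame indexed by gene with columns baseMean, log2fc (the
    interaction coefficient, log2), plug_in_log2fc, se, stat, p, padj.
    Genes with nonzero counts in fewer than 2 samples get missing
    statistics. ``sf_scope='per-fraction'`` estimates size factors within
    each RNA fraction separately (the per-condition normalization variant);
    'joint' uses all samples of the contrast at once.
    """
    if sf_scope not in ("joint", "per-fraction"):
        raise ValueError("sf_scope must be 'joint' or 'per-fraction'")
    design.check_against(counts)
    sub = design.subset(strain={strain_a, strain_b})
    cells = sub.frame.groupby(["strain", "fraction"], observed=True).size()
    for strain in (strain_a, strain_b):
        for fraction in ("total", "polysomal"):
            if (strain, fraction) not in cells.index:
                raise ValueError(
                    f"missing samples for strain={strain!r}, fraction={fraction!r}"
                )
    cm = counts.subset_samples(sub.sample_ids)
    dm = build_design(sub, strain_ref=strain_b, fraction_ref="total")

    if sf_scope == "joint":
        sf = size_factors_median_ratio(cm)
    else:
        sf = _per_fraction_size_factors(cm, sub)
    norm = normalize_counts(cm, sf)

    testable = (cm.counts > 0).sum(axis=1) >= 2
    norm_t = norm.loc[testable]
    disp = estimate_dispersions(norm_t, dm.matrix)
    fit = fit_nb_glm_batch(
        norm_t.to_numpy(), dm, disp.shrunken, gene_ids=list(norm_t.index)
    )
    test = wald_test(fit, coef_index=3)
    padj = adjust_bh(test.p)

    # plug-in ratio-of-ratios from normalized group means
    samples = sub.frame.set_index("sample_id")
    groups = {
        key: [
            s
            for s in cm.samples
            if (samples.loc[s, "strain"], samples.loc[s, "fraction"]) == key
        ]
        for key in [
            (strain_a, "polysomal"),
            (strain_a, "total"),
            (strain_b, "polysomal"),
            (strain_b, "total"),
        ]
    }
    means = np.column_stack([norm[cols].mean(axis=1).to_numpy() for cols in groups.values()])
    with np.errstate(divide="ignore", invalid="ignore"):
        plug_in = np.where(
            (means > 0).all(axis=1),
            np.log2((means[:, 0] / means[:, 1]) / (means[:, 2] / means[:, 3])),
            np.nan,
        )

    out = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1).to_numpy(),
            "log2fc": np.nan,
            "plug_in_log2fc": plug_in,
            "se": np.nan,
            "stat": np.nan,
            "p": np.nan,
            "padj": np.nan,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    sel = out.index[testable]
    out.loc[sel, "log2fc"] = test.log2fc
    out.loc[sel, "se"] = test.se
    out.loc[sel, "stat"] = test.stat
    out.loc[sel, "p"] = test.p
    out.loc[sel, "padj"] = padj
    return out


def classify_genes(
    de_poly: pd.DataFrame, de_total: pd.DataFrame, alpha: float = 0.01
) -> pd.Series:
    """Venn-style labels from separate polysomal and total DE runs.

    Each gene gets one of ``VENN_LABELS``. A gene is significant on an
    axis when padj < alpha there; direction is that axis's own log2fc
    sign. Genes significant in opposite directions on the two axes are
    labeled by the polysomal axis (its exclusive label). Genes untested
    (missing padj) in either table count as not significant there.
    """
    if set(de_poly.index) != set(de_total.index):
        raise ValueError("gene universes of the two DE tables differ")
    dp = de_poly
    dt = de_total.loc[dp.index]

    def sig(df: pd.DataFrame, sign: int) -> pd.Series:
        padj = df["padj"]
        ok = padj.notna() & (padj < alpha)
        return ok & (np.sign(df["log2fc"].fillna(0.0)) == sign)

    up_p, down_p = sig(dp, 1), sig(dp, -1)
    up_t, down_t = sig(dt, 1), sig(dt, -1)

    label = pd.Series("ns", index=dp.index, name="label")
    label[up_t & ~up_p & ~down_p] = "total_only_up"
    label[down_t & ~up_p & ~down_p] = "total_only_down"
    label[up_p & ~up_t] = "poly_only_up"
    label[down_p & ~down_t] = "poly_only_down"
    label[up_p & up_t] = "both_up"
    label[down_p & down_t] = "both_down"
    return label
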