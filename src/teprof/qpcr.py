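"""qPCR relative expression and replicate testing.

Per sample, each gene's abundance proxy E^(-Cq) is normalized by the
geometric mean of the reference genes' proxies; condition fold changes are
ratios of condition means. With efficiency E = 2 this reduces to the
familiar delta-delta-Cq arithmetic: one cycle less = twice the template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .polysome_profiles import holm_sidak

__all__ = ["CqTable", "RelativeExpression", "relative_expression", "test_expression"]

CQ_RANGE = (0.0, 45.0)


@dataclass
class CqTable:
    """Tidy Cq measurements: sample_id, condition, gene, cq[, efficiency, is_reference]."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "gene", "cq")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"Cq table missing columns: {missing}")
        df["cq"] = df["cq"].astype(float)
        if ((df["cq"] <= CQ_RANGE[0]) | (df["cq"] >= CQ_RANGE[1])).any():
            bad = df.loc[
                (df["cq"] <= CQ_RANGE[0]) | (df["cq"] >= CQ_RANGE[1])
            ].iloc[0]
            raise ValueError(
                f"Cq {bad['cq']} out of range {CQ_RANGE} "
                f"(sample {bad['sample_id']!r}, gene {bad['gene']!r})"
            )
        if "efficiency" not in df.columns:
            df["efficiency"] = 2.0
        df["efficiency"] = df["efficiency"].astype(float)
        if (df["efficiency"] <= 1.0).any():
            raise ValueError("amplification efficiency must be > 1")
        if "is_reference" not in df.columns:
            df["is_reference"] = False
        self.frame = df.reset_index(drop=True)


@dataclass
class RelativeExpression:
    """Per-sample relative levels and per-condition fold changes."""

    levels: pd.DataFrame  # sample_id, condition, gene, rel_expr
    fold_changes: pd.DataFrame  # gene, condition, fold_change


def relative_expression(
    cq: CqTable,
    condition_ref: str,
    reference_genes: list[str] | None = None,
) -> RelativeExpression:
    """Reference-gene-normalized expression and fold changes vs a condition.

    ``reference_genes`` overrides the table's ``is_reference`` flags; the
    reference set is always explicit one way or the other. Samples missing
    any reference gene are dropped with a warning.
    """
    df = cq.frame
    if reference_genes is not None:
        refs = list(reference_genes)
    else:
        refs = sorted(set(df.loc[df["is_reference"], "gene"]))
    if not refs:
        raise ValueError("no reference genes given or flagged")
    if condition_ref not in set(df["condition"]):
        raise ValueError(f"unknown reference condition {condition_ref!r}")

    # log2 abundance proxy: -cq * log2(E)
    df = df.assign(log2_level=-df["cq"] * np.log2(df["efficiency"]))
    rows = []
    for sample_id, grp in df.groupby("sample_id", observed=True, sort=False):
        ref_rows = grp[grp["gene"].isin(refs)]
        if sorted(set(ref_rows["gene"])) != sorted(set(refs)):
            warnings.warn(
                f"sample {sample_id!r} dropped: missing reference gene(s)",
                stacklevel=2,
            )
            continue
        norm_log2 = ref_rows["log2_level"].mean()  # geometric mean in log space
        sub = grp.assign(rel_expr=2.0 ** (grp["log2_level"] - norm_log2))
        rows.append(sub[["sample_id", "condition", "gene", "rel_expr"]])
    if not rows:
        raise ValueError("no sample retained: all are missing reference genes")
    levels = pd.concat(rows, ignore_index=True)

    cond_means = (
        levels.groupby(["gene", "condition"], observed=True)["rel_expr"]
        .mean()
        .unstack("condition")
    )
    fc = cond_means.div(cond_means[condition_ref], axis=0)
    fold_changes = (
        fc.stack().rename("fold_change").reset_index().loc[:, ["gene", "condition", "fold_change"]]
    )
    return RelativeExpression(levels=levels, fold_changes=fold_changes)


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-sample t robust to zero-variance degenerate groups."""
    if np.isclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t_stat), float(p_val)


def test_expression(
    levels: pd.DataFrame,
    method: str = "holm_sidak_t",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Replicate testing of relative expression between conditions.

    ``levels`` is tidy with columns gene, condition, rel_expr (the
    :class:`RelativeExpression` ``levels`` frame works directly).

    - ``holm_sidak_t``: per-gene two-sample t between exactly two
      conditions, Holm-Sidak adjusted across genes.
    - ``anova_sidak``: per-gene one-way ANOVA across all conditions plus
      Sidak-adjusted pairwise t contrasts (adjusted within each gene's
      family of pairs).
    """
    required = {"gene", "condition", "rel_expr"}
    missing = required - set(levels.columns)
    if missing:
        raise ValueError(f"levels table missing columns: {sorted(missing)}")
    conditions = sorted(set(levels["condition"]))
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to test")

    def values(gene: str, cond: str) -> np.ndarray:
        v = levels.loc[
            (levels["gene"] == gene) & (levels["condition"] == cond), "rel_expr"
        ].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(
                f"gene {gene!r}, condition {cond!r}: need >= 2 replicates"
            )
        return v

    genes = list(dict.fromkeys(levels["gene"]))

    if method == "holm_sidak_t":
        if len(conditions) != 2:
            raise ValueError("holm_sidak_t requires exactly two conditions")
        rows = []
        for gene in genes:
            a, b = values(gene, conditions[0]), values(gene, conditions[1])
            t_stat, p_val = _ttest(a, b, equal_var)
            rows.append({"gene": gene, "t": float(t_stat), "p": float(p_val)})
        out = pd.DataFrame(rows, columns=["gene", "t", "p"])
        out["padj"] = holm_sidak(out["p"])
        return out

    if method == "anova_sidak":
        rows = []
        pairs = [
            (a, b) for i, a in enumerate(conditions) for b in conditions[i + 1 :]
        ]
        for gene in genes:
            samples = [values(gene, c) for c in conditions]
            if np.isclose(np.var(np.concatenate(samples)), 0.0):
                p_anova = 1.0
            else:
                _, p_anova = stats.f_oneway(*samples)
            for cond_a, cond_b in pairs:
                a, b = values(gene, cond_a), values(gene, cond_b)
                _, p_pair = _ttest(a, b, equal_var)
                padj = min(1.0, 1.0 - (1.0 - float(p_pair)) ** len(pairs))
                rows.append(
                    {
                        "gene": gene,
                        "pair": f"{cond_a} vs {cond_b}",
                        "p_anova": float(p_anova),
                        "p": float(p_pair),
                        "padj": padj,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "pair", "p_anova", "p", "padj"])

    raise ValueError("method must be 'holm_sidak_t' or 'anova_sidak'")
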