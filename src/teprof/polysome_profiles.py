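"""Sucrose-gradient A254 trace quantification.

Peaks are local maxima of a moving-average-smoothed trace above a
prominence threshold, bounded by the adjacent valleys (local minima).
Per-peak abundance is the trapezoidal area between the trace and a
baseline (zero, or the chord between the bounding valleys); fold changes
are expressed against a reference peak's group mean, and per-peak group
comparisons use two-sample t tests with Holm-Sidak adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ProfileTrace",
    "Peak",
    "PeakSet",
    "DEFAULT_PEAK_NAMES",
    "read_trace",
    "write_trace",
    "detect_peaks",
    "quantify_auc",
    "peak_fold_changes",
    "compare_peaks",
    "holm_sidak",
]

DEFAULT_PEAK_NAMES = ("40S", "60S", "monosome", "P1", "P2", "P3", "P4", "P5", "P6")

MIN_TRACE_POINTS = 50


@dataclass
class ProfileTrace:
    """A254 absorbance versus gradient position."""

    position: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.position.ndim != 1 or self.position.shape != self.absorbance.shape:
            raise ValueError("position and absorbance must be 1-D and equally long")
        if self.position.size < MIN_TRACE_POINTS:
            raise ValueError(f"trace needs >= {MIN_TRACE_POINTS} points")
        if not (np.diff(self.position) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.position.size


@dataclass
class Peak:
    """One detected peak: apex and bounding valleys (indices into the trace)."""

    name: str
    apex: int
    left: int
    right: int
    apex_position: float


@dataclass
class PeakSet:
    """Ordered, non-overlapping peaks of one trace."""

    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.peaks, self.peaks[1:]):
            if cur.left < prev.right:
                raise ValueError("peak intervals must be ordered and non-overlapping")
        for pk in self.peaks:
            if not (pk.left <= pk.apex <= pk.right):
                raise ValueError("valleys must bracket the apex")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def names(self) -> list[str]:
        return [p.name for p in self.peaks]


def read_trace(path, label: str = "") -> ProfileTrace:
    """Read a two-column numeric trace; a single header line is auto-skipped."""
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(tok) for tok in first.replace(",", " ").replace("\t", " ").split()]
    except ValueError:
        skip = 1
    data = np.loadtxt(path, skiprows=skip, delimiter=None if "\t" not in first else "\t")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("trace file must have two numeric columns")
    return ProfileTrace(data[:, 0], data[:, 1], label=label)


def write_trace(trace: ProfileTrace, path) -> None:
    np.savetxt(
        path,
        np.column_stack([trace.position, trace.absorbance]),
        delimiter="\t",
        header="position\tabsorbance",
        comments="",
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.repeat(y[0], pad), y, np.repeat(y[-1], pad)])
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(
    trace: ProfileTrace,
    min_prominence: float,
    min_separation: float = 0.0,
    smooth_window: int = 5,
    names: tuple[str, ...] = DEFAULT_PEAK_NAMES,
) -> PeakSet:
    """Find peaks and their valley boundaries on the smoothed trace.

    ``min_separation`` is in position units; peaks closer than this are
    merged, keeping the larger maximum. Names are assigned left-to-right
    from ``names``, then 'unassigned'. An empty result triggers a warning,
    not an error.
    """
    y = _smooth(trace.absorbance, smooth_window)
    step = float(np.median(np.diff(trace.position)))
    distance = max(int(round(min_separation / step)), 1)
    apexes, _ = signal.find_peaks(y, prominence=min_prominence, distance=distance)
    if apexes.size == 0:
        warnings.warn("no peaks found above the prominence threshold", stacklevel=2)
        return PeakSet([])

    # valleys: minimum of the smoothed trace between consecutive apexes,
    # trace ends outside the first/last apex
    bounds = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        bounds.append(a + int(np.argmin(y[a : b + 1])))
    bounds.append(y.size - 1)

    peaks = []
    for i, apex in enumerate(apexes):
        name = names[i] if i < len(names) else "unassigned"
        peaks.append(
            Peak(
                name=name,
                apex=int(apex),
                left=int(bounds[i]),
                right=int(bounds[i + 1]),
                apex_position=float(trace.position[apex]),
            )
        )
    return PeakSet(peaks)


def quantify_auc(
    trace: ProfileTrace, peaks: PeakSet, baseline_mode: str = "zero"
) -> pd.DataFrame:
    """Trapezoidal area of (absorbance - baseline) over each peak interval.

    ``baseline_mode`` is 'zero' (integrate the raw trace) or
    'linear-under-peak' (subtract the chord between the two valleys).
    Negative net areas are clipped to zero and flagged.

    Returns a frame with columns peak, auc, baseline_mode, clipped.
    """
    if baseline_mode not in ("zero", "linear-under-peak"):
        raise ValueError("baseline_mode must be 'zero' or 'linear-under-peak'")
    rows = []
    for pk in peaks:
        x = trace.position[pk.left : pk.right + 1]
        y = trace.absorbance[pk.left : pk.right + 1]
        if baseline_mode == "zero":
            base = np.zeros_like(y)
        else:
            base = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
        area = float(np.trapezoid(y - base, x))
        clipped = area < 0
        rows.append(
            {
                "peak": pk.name,
                "auc": max(area, 0.0),
                "baseline_mode": baseline_mode,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows, columns=["peak", "auc", "baseline_mode", "clipped"])


def peak_fold_changes(
    quants: pd.DataFrame, reference: tuple[str, str]
) -> pd.DataFrame:
    """Mean AUC per (group, peak) divided by the reference group's peak mean.

    ``quants`` is tidy with columns group, replicate, peak, auc;
    ``reference`` is (group, peak).
    """
    required = {"group", "replicate", "peak", "auc"}
    missing = required - set(quants.columns)
    if missing:
        raise ValueError(f"quants table missing columns: {sorted(missing)}")
    ref_group, ref_peak = reference
    ref_rows = quants[(quants["group"] == ref_group) & (quants["peak"] == ref_peak)]
    if ref_rows.empty:
        raise ValueError(f"reference peak {ref_peak!r} not present in group {ref_group!r}")
    ref_mean = float(ref_rows["auc"].mean())
    if ref_mean <= 0:
        raise ValueError("reference peak has non-positive mean AUC")
    out = (
        quants.groupby(["group", "peak"], observed=True)["auc"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_auc", "std": "sd_auc", "count": "n"})
    )
    out["fold_change"] = out["mean_auc"] / ref_mean
    return out


def holm_sidak(p) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sort ascending; adj_(i) = max over j <= i of 1 - (1 - p_(j))^(m-j+1),
    capped at 1. NaNs are excluded from the family size and passed through.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    stepwise = 1.0 - (1.0 - pv[order]) ** (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def compare_peaks(
    quants_a: pd.DataFrame,
    quants_b: pd.DataFrame,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-peak two-sample t tests between groups, Holm-Sidak adjusted.

    Inputs are tidy per-replicate AUC tables with columns peak and auc
    (extra columns ignored). Peaks with fewer than 2 replicates in either
    group are skipped with a flag and excluded from the adjustment family.
    """
    peaks = [p for p in dict.fromkeys(quants_a["peak"]) if p in set(quants_b["peak"])]
    rows = []
    for peak in peaks:
        a = quants_a.loc[quants_a["peak"] == peak, "auc"].to_numpy(dtype=float)
        b = quants_b.loc[quants_b["peak"] == peak, "auc"].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append({"peak": peak, "t": np.nan, "p": np.nan, "skipped": True})
            continue
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t_stat, p_val = 0.0, 1.0  # identical constant groups
        else:
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"peak": peak, "t": float(t_stat), "p": float(p_val), "skipped": False})
    out = pd.DataFrame(rows, columns=["peak", "t", "p", "skipped"])
    out["padj"] = holm_sidak(out["p"])
    return out
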