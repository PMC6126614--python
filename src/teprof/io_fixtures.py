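"""Reading/writing of count matrices, sample sheets, and packaged gene tables.

The canonical on-disk dialect is tab-separated text; a comma fallback is
auto-detected from the header line. Gene identifiers are opaque strings.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "load_table_fixture",
    "FIXTURE_NAMES",
    "FRACTION_LEVELS",
]

FRACTION_LEVELS = ("total", "polysomal")

FIXTURE_NAMES = ("table1_oxphos", "table2_translation")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    gene_ids: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.samples = [str(s) for s in self.samples]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.samples),
        ):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[i]!r}, sample {self.samples[j]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene ID {dup!r}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise ValueError(f"duplicate sample ID {dup!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing}")
        idx = [self.samples.index(s) for s in samples]
        return CountMatrix(list(self.gene_ids), list(samples), self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class SampleDesign:
    """Per-sample experimental factors: strain, RNA fraction, replicate."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "strain", "fraction", "replicate")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["strain"] = df["strain"].astype(str)
        df["fraction"] = df["fraction"].astype(str)
        bad = sorted(set(df["fraction"]) - set(FRACTION_LEVELS))
        if bad:
            raise FormatError(
                f"unknown fraction label(s) {bad}; allowed: {list(FRACTION_LEVELS)}"
            )
        try:
            df["replicate"] = df["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"replicate must be a positive integer: {exc}") from exc
        if (df["replicate"] < 1).any():
            raise FormatError("replicate must be a positive integer")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicated sample_id {dup!r}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.frame["strain"]))

    def subset(self, **factors: str) -> "SampleDesign":
        """Rows matching all given factor=value pairs (value may be a set)."""
        mask = pd.Series(True, index=self.frame.index)
        for key, val in factors.items():
            if key not in self.frame.columns:
                raise KeyError(f"unknown factor {key!r}")
            if isinstance(val, (set, frozenset, list, tuple)):
                mask &= self.frame[key].isin(list(val))
            else:
                mask &= self.frame[key] == val
        return SampleDesign(self.frame.loc[mask])

    def check_against(self, counts: CountMatrix) -> None:
        """Every count-matrix sample must appear exactly once in the sheet."""
        sheet = set(self.sample_ids)
        missing = [s for s in counts.samples if s not in sheet]
        if missing:
            raise FormatError(f"samples in counts but not in sample sheet: {missing}")


def read_count_matrix(path) -> CountMatrix:
    """Read a gene x sample count matrix from TSV (comma fallback).

    The first column holds gene IDs, the header row sample IDs. Every body
    cell must be a non-negative integer; violations are reported with the
    offending gene and sample so the file can be fixed.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = df[col]
        for i, raw in enumerate(vals):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {raw!r} at gene {genes[i]!r}, sample {samples[j]!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"negative count {v} at gene {genes[i]!r}, sample {samples[j]!r}"
                )
            counts[i, j] = v
    if len(set(genes)) != len(genes):
        raise FormatError(f"duplicate gene ID {_first_duplicate(genes)!r}")
    return CountMatrix(genes, samples, counts)


def write_count_matrix(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path) -> SampleDesign:
    """Read a sample sheet with columns sample_id, strain, fraction, replicate."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
    sep = _detect_sep(header)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return SampleDesign(df)


def write_sample_table(design: SampleDesign, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def load_table_fixture(name: str) -> pd.DataFrame:
    """Load a packaged annotated gene table.

    Available fixtures: ``table1_oxphos`` (polysomally enriched OXPHOS
    transcripts, sections Complex I-V) and ``table2_translation``
    (polysomally reduced translation transcripts, sections Translation /
    Ribosome / mRNA processing). Columns: accession, gene_name,
    description, section, log2fc.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")
    ref = importlib.resources.files("teprof.data").joinpath(f"{name}.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"log2fc": float})
    if df["section"].isna().any():
        raise ValueError("fixture has empty section labels")
    if not np.isfinite(df["log2fc"]).all():
        raise ValueError("fixture has non-finite log2fc")
    return df
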