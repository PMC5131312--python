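"""Core data containers and tab-separated readers/writers.

The pipeline's raw input is a gene x sample table of nonnegative integer
counts plus a per-sample design table assigning each sample to a cell of the
factorial layout (substrate rigidity x genotype x drug treatment x replicate).
Sample-to-condition mapping always goes through the design table; sample names
are opaque identifiers and are never parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RIGIDITY_LEVELS = ("soft", "stiff")
GENOTYPE_LEVELS = ("KDEL", "SUN1L")
TREATMENT_LEVELS = ("none", "blebbistatin", "Y27632")


class FormatError(ValueError):
    """Raised when an input file violates the container invariants."""


class ConfigurationError(ValueError):
    """Raised when a requested analysis is inconsistent with the inputs."""


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer gene x sample count table.

    ``counts`` is indexed by gene id with one column per sample id; both id
    sets must be unique and every entry must be a nonnegative integer.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FormatError("count matrix is empty")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if not np.isfinite(values).all():
            raise FormatError("non-finite counts")
        if (values < 0).any():
            raise FormatError("negative counts")
        if not np.array_equal(values, np.floor(values)):
            raise FormatError("fractional counts")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)])


@dataclass(frozen=True)
class DesignTable:
    """Per-sample factor assignments.

    Columns: sample_id, rigidity (soft=1 kPa / stiff=308 kPa), genotype
    (KDEL control / SUN1L LINC-disrupting construct), treatment
    (none / blebbistatin / Y27632), replicate (positive integer).
    """

    table: pd.DataFrame = field()

    REQUIRED = ("sample_id", "rigidity", "genotype", "treatment", "replicate")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in design: {dups}")
        for col, levels in (
            ("rigidity", RIGIDITY_LEVELS),
            ("genotype", GENOTYPE_LEVELS),
            ("treatment", TREATMENT_LEVELS),
        ):
            bad = sorted(set(df[col]) - set(levels))
            if bad:
                raise FormatError(f"unknown {col} level(s): {bad}")
        reps = pd.to_numeric(df["replicate"], errors="coerce")
        if reps.isna().any() or (reps <= 0).any() or (reps != reps.astype(int)).any():
            raise FormatError("replicate must be a positive integer")
        cells = df[["rigidity", "genotype", "treatment", "replicate"]]
        if cells.duplicated().any():
            raise FormatError("duplicate (rigidity, genotype, treatment, replicate) tuple")
        out = df.loc[:, list(self.REQUIRED)].copy()
        out["replicate"] = reps.astype(int)
        object.__setattr__(self, "table", out.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_where(self, **factors) -> list[str]:
        """Sample ids matching all given factor=value (or factor=iterable) pairs."""
        mask = pd.Series(True, index=self.table.index)
        for name, value in factors.items():
            if name not in self.table.columns:
                raise KeyError(f"unknown design factor {name!r}")
            col = self.table[name]
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= col.isin(list(value))
            else:
                mask &= col == value
        return list(self.table.loc[mask, "sample_id"])

    def validate_against(self, counts: CountMatrix) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            raise FormatError("design sample ids do not match count matrix sample ids")


def read_counts(path) -> CountMatrix:
    """Read a TSV count table: first column gene id, one column per sample."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty count table: {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"count table has no sample columns: {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            raise FormatError(f"non-numeric count in column {col!r}")
        df[col] = coerced
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_design(path) -> DesignTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty design table: {path}") from exc
    return DesignTable(df)


def write_design(design: DesignTable, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Byte-stable TSV output used by every pipeline stage."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT annotation sets: name <tab> description <tab> member ids."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: expected name, description, members")
            name = parts[0]
            if name in sets:
                raise FormatError(f"duplicate GMT set name {name!r}")
            sets[name] = set(p for p in parts[2:] if p)
    if not sets:
        raise FormatError(f"empty GMT file: {path}")
    return sets
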