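"""Data model and readers/writers for every format the pipeline touches.

The pipeline operates on four kinds of input:

* a log2-scale gene x sample expression matrix (TSV, genes as rows),
* a per-sample annotation table with a two-level group label and
  optional categorical strata (TSV),
* gene set collections in GMT format (MSigDB-style),
* TF -> target interactions as a two-column edge list (TSV).

Gene identifiers are matched by exact string comparison after
whitespace trimming; no symbol aliasing is attempted.  All tabular
output is TSV with a header line and floats serialized to 6
significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, ParseError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes as rows, samples as columns.

    Invariants: gene and sample identifiers are unique, values contain
    no missing entries, and the matrix dimensions match the identifier
    lists.  ``validate`` enforces these after any manual construction.
    """

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate(self) -> "ExpressionMatrix":
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample identifiers: {dups[:5]}")
        if self.data.isna().any().any():
            raise InputError("expression matrix contains missing values")
        if self.data.shape[1] < 2:
            raise InputError("expression matrix needs at least 2 samples")
        return self


@dataclass
class SampleAnnotation:
    """Per-sample group label plus optional categorical strata.

    ``table`` is indexed by sample id; ``group_col`` names the
    two-level grouping column.  Any other column is treated as a
    stratum.  ``group_levels`` fixes the (A, B) orientation of every
    downstream contrast: statistics are signed A minus B.
    """

    table: pd.DataFrame
    group_col: str = "group"

    def __post_init__(self) -> None:
        if self.group_col not in self.table.columns:
            raise InputError(f"annotation lacks group column {self.group_col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group_levels(self) -> tuple[str, str]:
        levels = sorted(self.table[self.group_col].astype(str).unique())
        if len(levels) != 2:
            raise InputError(
                f"group column {self.group_col!r} must have exactly 2 levels, "
                f"found {levels}"
            )
        return levels[0], levels[1]

    @property
    def strata_cols(self) -> list[str]:
        return [c for c in self.table.columns if c != self.group_col]

    def groups_for(self, sample_ids: list[str]) -> pd.Series:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise InputError(f"samples without annotation: {missing[:5]}")
        return self.table.loc[sample_ids, self.group_col].astype(str)

    def mask_for(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (in_A, in_B) aligned with ``sample_ids``."""
        a, b = self.group_levels
        groups = self.groups_for(sample_ids).to_numpy()
        mask_a, mask_b = groups == a, groups == b
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise InputError("each group needs at least 2 samples")
        return mask_a, mask_b

    def validate(self, expr: ExpressionMatrix | None = None) -> "SampleAnnotation":
        if self.table.index.has_duplicates:
            raise InputError("duplicate sample ids in annotation")
        self.group_levels  # raises unless exactly two levels
        counts = self.table[self.group_col].value_counts()
        if (counts < 2).any():
            raise InputError("each group needs at least 2 samples")
        if expr is not None:
            self.groups_for(expr.sample_ids)
        return self


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def validate(self) -> "GeneSetCollection":
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")
        return self


@dataclass
class TFTargetMap:
    """Regulons: mapping from TF name to its set of target genes.

    Targets may or may not be present in a given expression matrix;
    intersection with the measured universe happens downstream.
    """

    regulons: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, tf: str) -> frozenset[str]:
        return self.regulons[tf]

    @property
    def tf_names(self) -> list[str]:
        return list(self.regulons)


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    sep: str = "\t",
    duplicate_policy: str = "first",
) -> ExpressionMatrix:
    """Read a gene x sample expression table.

    Gene identifiers are expected in the first column, sample
    identifiers in the header.  Duplicate gene rows are collapsed by
    ``duplicate_policy`` ("first" keeps the first occurrence, "mean"
    averages); genes with any missing value are dropped, with a logged
    count, because the permutation statistics assume complete rows.
    """
    if duplicate_policy not in ("first", "mean"):
        raise ConfigError(f"unknown duplicate policy {duplicate_policy!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype_backend="numpy_nullable")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
    if df.shape[1] < 2:
        raise InputError(f"{path}: expression matrix needs at least 2 samples")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene rows collapsed by %r", path, n_dup, duplicate_policy)
        if duplicate_policy == "first":
            df = df[~df.index.duplicated(keep="first")]
        else:
            df = df.groupby(level=0, sort=False).mean()
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d genes with missing values", path, n_missing)
        df = df.dropna(axis=0)
    return ExpressionMatrix(df.astype(float)).validate()


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def read_annotations(
    path: str | Path, group_col: str = "group", sep: str = "\t"
) -> SampleAnnotation:
    """Read a sample annotation TSV with sample_id, group and strata columns."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    ann = SampleAnnotation(df, group_col=group_col)
    return ann.validate()


def write_annotations(ann: SampleAnnotation, path: str | Path, sep: str = "\t") -> None:
    ann.table.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name TAB description TAB member genes.

    Duplicate members within a line are deduplicated; a line with fewer
    than three fields or a repeated set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0].strip(), fields[1].strip()
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions).validate()


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# TF target edge lists
# ---------------------------------------------------------------------------


def read_tf_targets(path: str | Path) -> TFTargetMap:
    """Read a two-column (TF, target) edge list into regulons.

    A header line is tolerated (detected as the literal column names
    "tf"/"target" in any case).  Duplicate edges collapse under set
    semantics; self-edges are retained, since a TF may target itself.
    """
    edges: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            if lineno == 1 and fields[0].lower() in ("tf", "regulator") and fields[1].lower() in ("target", "gene"):
                continue
            edges.setdefault(fields[0], set()).add(fields[1])
    return TFTargetMap({tf: frozenset(ts) for tf, ts in edges.items()})


def write_tf_targets(tf_map: TFTargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\n")
        for tf in sorted(tf_map.regulons):
            for target in sorted(tf_map.regulons[tf]):
                fh.write(f"{tf}\t{target}\n")
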