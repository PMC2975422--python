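"""Two-condition expression matrices: loading, validation, transforms, subsampling.

The expected on-disk dialect is a flat tab-separated table: a header row of
sample identifiers, one row per gene/probe with the gene identifier in the
first column (or a named column), and log-scale intensities everywhere else.
This matches the flat style of GEO series-matrix exports without requiring a
GEO parser. Normalization is out of scope: the loader expects pre-normalized
values and only a log transform is offered for linear-scale input.

Duplicate gene identifiers are permitted (probe sets may repeat a gene
symbol) and treated as independent rows. Missing values are rejected, not
imputed — a silent fill would corrupt the per-gene means everything
downstream is built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "GroupDesign",
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "read_groups",
    "read_truth_ids",
    "log_transform",
    "subsample_columns",
]


class LoadError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of each sample to condition ``A`` or ``B``.

    ``label_names`` optionally remembers the original condition labels
    (e.g. ``{"A": "normal", "B": "disease"}``) for reporting.
    """

    assignment: dict[str, str]
    label_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.assignment.values()} - {"A", "B"}
        if bad:
            raise ValueError(f"condition labels must be 'A' or 'B', got {sorted(bad)}")
        n_a = sum(1 for v in self.assignment.values() if v == "A")
        n_b = len(self.assignment) - n_a
        if n_a == 0 or n_b == 0:
            raise ValueError(
                f"both conditions need at least one sample (A={n_a}, B={n_b})"
            )

    def condition_of(self, sample_id: str) -> str:
        return self.assignment[sample_id]

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == condition]

    @property
    def p1(self) -> int:
        """Number of condition-A samples."""
        return len(self.samples("A"))

    @property
    def p2(self) -> int:
        """Number of condition-B samples."""
        return len(self.samples("B"))


@dataclass
class ExpressionMatrix:
    """N genes x P samples of log-scale expression intensities.

    ``design`` may be ``None`` right after loading; every analysis step
    requires it to be set. ``log_scale`` records whether values are already
    on a log scale (the default assumption for pre-processed input).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    design: GroupDesign | None = None
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 1 or p < 2:
            raise ValueError(f"need at least 1 gene and 2 samples, got {n}x{p}")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match row count")
        if len(self.sample_ids) != p:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.sample_ids)) != p:
            raise ValueError("sample IDs must be unique")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.design is not None:
            missing = [s for s in self.sample_ids if s not in self.design.assignment]
            if missing:
                raise ValueError(f"samples without condition label: {missing}")
            extra = set(self.design.assignment) - set(self.sample_ids)
            if extra:
                raise ValueError(
                    f"design labels samples not in the matrix: {sorted(extra)}"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_columns(self, condition: str) -> np.ndarray:
        """Column indices belonging to ``condition`` ('A' or 'B'), in matrix order."""
        if self.design is None:
            raise ValueError("matrix has no group design attached")
        return np.array(
            [
                j
                for j, s in enumerate(self.sample_ids)
                if self.design.condition_of(s) == condition
            ],
            dtype=int,
        )

    def with_design(self, design: GroupDesign) -> "ExpressionMatrix":
        return replace(self, design=design)


def read_matrix(
    path,
    gene_id_column: str | None = None,
    log_scale: bool = True,
) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    Parameters
    ----------
    path:
        File with a header row of sample IDs and one row per gene. The gene
        identifier sits in ``gene_id_column`` (default: the first column).
    log_scale:
        Whether the stored values are already log-scale (default). Pass
        ``False`` for raw intensities and follow with :func:`log_transform`.

    The returned matrix has no group design attached; see :func:`read_groups`.
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise LoadError(f"{path}: empty file or blank header row")
    header = header_line.rstrip("\n").rstrip("\r").split("\t")
    if gene_id_column is None:
        gene_col = header[0]
    else:
        if gene_id_column not in header:
            raise LoadError(f"{path}: gene ID column {gene_id_column!r} not in header")
        gene_col = gene_id_column
    sample_ids = [c for c in header if c != gene_col]
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise LoadError(f"{path}: duplicate sample ID(s) in header: {sorted(dup)}")

    # field-count scan first: pandas would silently absorb extra fields
    # into an index instead of flagging a ragged row
    n_fields = len(header)
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for rowno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            found = line.rstrip("\n").rstrip("\r").count("\t") + 1
            if found != n_fields:
                raise LoadError(
                    f"{path}: ragged row {rowno}: {found} fields, expected {n_fields}"
                )
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            skiprows=1,
            header=None,
            names=header,
            dtype=str,
            keep_default_na=False,
            na_values=[],
        )
    except pd.errors.ParserError as exc:
        raise LoadError(f"{path}: ragged row — {exc}") from exc
    if df.shape[0] == 0:
        raise LoadError(f"{path}: no gene rows")

    gene_ids = df[gene_col].tolist()
    values = np.empty((df.shape[0], len(sample_ids)), dtype=float)
    for j, col in enumerate(sample_ids):
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            cell = raw.iloc[i]
            kind = "missing value" if cell.strip() == "" else f"non-numeric value {cell!r}"
            raise LoadError(
                f"{path}: {kind} at gene {gene_ids[i]!r} (row {i + 2}), "
                f"sample {col!r}"
            )
        values[:, j] = numeric.to_numpy()
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise LoadError(
            f"{path}: non-finite value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values, log_scale=log_scale)


def write_matrix(matrix: ExpressionMatrix, path, gene_id_column: str = "gene_id") -> None:
    """Write a matrix back to the tab-separated dialect with 6 significant digits."""
    df = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    df.insert(0, gene_id_column, matrix.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_groups(path, sample_ids: list[str], label_a: str | None = None) -> GroupDesign:
    """Read a two-column (sample_id, label) file into a :class:`GroupDesign`.

    Exactly two distinct labels must occur. The first label encountered maps
    to condition A unless ``label_a`` names it explicitly.
    """
    assignment_raw: dict[str, str] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise LoadError(
                    f"{path}: line {lineno}: expected two tab-separated fields"
                )
            sample, label = parts[0].strip(), parts[1].strip()
            if sample in assignment_raw:
                raise LoadError(f"{path}: sample {sample!r} labeled more than once")
            assignment_raw[sample] = label
            if label not in order:
                order.append(label)
    unknown = [s for s in assignment_raw if s not in sample_ids]
    if unknown:
        raise LoadError(f"{path}: sample(s) not present in matrix: {unknown}")
    unlabeled = [s for s in sample_ids if s not in assignment_raw]
    if unlabeled:
        raise LoadError(f"{path}: sample(s) without a condition label: {unlabeled}")
    if len(order) != 2:
        raise LoadError(
            f"{path}: expected exactly two condition labels, got {order or 'none'}"
        )
    if label_a is not None:
        if label_a not in order:
            raise LoadError(f"{path}: requested A-label {label_a!r} not among {order}")
        a_label = label_a
    else:
        a_label = order[0]
    b_label = next(l for l in order if l != a_label)
    assignment = {
        s: ("A" if lab == a_label else "B") for s, lab in assignment_raw.items()
    }
    return GroupDesign(assignment, label_names={"A": a_label, "B": b_label})


def read_truth_ids(path) -> set[str]:
    """Read a truth set: one gene identifier per non-blank line."""
    with open(path, encoding="utf-8") as fh:
        ids = {line.strip() for line in fh if line.strip()}
    return ids


def log_transform(
    matrix: ExpressionMatrix, base: float = 2.0, floor: float = 1.0
) -> ExpressionMatrix:
    """log_base(max(value, floor)) elementwise, for linear-scale input.

    ``floor`` guards zeros/negatives from background subtraction; it must be
    positive. The result is marked log-scale.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if base <= 0 or base == 1:
        raise ValueError(f"log base must be positive and != 1, got {base}")
    if matrix.log_scale:
        raise ValueError("matrix is already marked log-scale")
    vals = np.log(np.maximum(matrix.values, floor)) / math.log(base)
    return replace(matrix, values=vals, log_scale=True)


def subsample_columns(
    matrix: ExpressionMatrix, n_a: int, n_b: int, seed: int
) -> ExpressionMatrix:
    """Draw ``n_a`` condition-A and ``n_b`` condition-B columns without replacement.

    Selection is uniform and deterministic for a fixed ``seed``; gene rows are
    unchanged and the retained columns keep their original order.
    """
    if matrix.design is None:
        raise ValueError("matrix has no group design attached")
    cols_a = matrix.condition_columns("A")
    cols_b = matrix.condition_columns("B")
    if n_a < 1 or n_a > len(cols_a):
        raise ValueError(f"n_a={n_a} out of range 1..{len(cols_a)}")
    if n_b < 1 or n_b > len(cols_b):
        raise ValueError(f"n_b={n_b} out of range 1..{len(cols_b)}")
    rng = np.random.default_rng(seed)
    keep_a = rng.choice(cols_a, size=n_a, replace=False)
    keep_b = rng.choice(cols_b, size=n_b, replace=False)
    keep = np.sort(np.concatenate([keep_a, keep_b]))
    sample_ids = [matrix.sample_ids[j] for j in keep]
    assignment = {s: matrix.design.condition_of(s) for s in sample_ids}
    design = GroupDesign(assignment, label_names=dict(matrix.design.label_names))
    return ExpressionMatrix(
        list(matrix.gene_ids),
        sample_ids,
        matrix.values[:, keep].copy(),
        design=design,
        log_scale=matrix.log_scale,
    )
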