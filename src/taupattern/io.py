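"""Plain tab-delimited I/O for expression matrices, design tables and annotation maps.

All files are UTF-8 TSV; lines starting with ``#`` are ignored. The expression
matrix holds log2 RMA-scale intensities with transcript clusters as rows and
samples as columns. A GEO series-matrix export can be converted to this format
by deleting the ``!``-prefixed header/footer lines and renaming the first
column header to ``cluster``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUP_ORDER, validate_design
from .errors import FormatError

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_annotation",
    "write_annotation",
    "write_table",
]

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix plus its sample design.

    ``values``: DataFrame, rows = transcript clusters (unique ids),
    columns = sample ids. ``design``: DataFrame indexed by sample id with
    columns genotype, treatment (and a derived ``group`` column).
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate transcript-cluster ids in matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression matrix contains non-finite values")
        self.design = validate_design(self.design, require_all_cells=False)
        matrix_samples = set(self.values.columns)
        design_samples = set(self.design.index)
        if matrix_samples != design_samples:
            missing = sorted(matrix_samples - design_samples)
            extra = sorted(design_samples - matrix_samples)
            raise FormatError(
                f"matrix/design sample mismatch: missing from design {missing}, "
                f"not in matrix {extra}"
            )
        # align design row order to the matrix column order
        self.design = self.design.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> pd.Series:
        """Sample -> design-cell label, in matrix column order."""
        return self.design["group"]

    def cell_counts(self) -> dict[str, int]:
        counts = self.design["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_ORDER}

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.design.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.design[
            ["genotype", "treatment"]
        ].equals(other.design[["genotype", "treatment"]])


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    for col in ("sample", "genotype", "treatment"):
        if col not in df.columns:
            raise FormatError(f"design file lacks column {col!r}")
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in design file")
    return df.set_index("sample")[["genotype", "treatment"]]


def write_design(design: pd.DataFrame, path) -> None:
    out = design[["genotype", "treatment"]].copy()
    out.insert(0, "sample", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path, design_path) -> ExpressionMatrix:
    """Read a matrix TSV (first column = cluster id) and its design TSV."""
    raw = pd.read_csv(path, **_READ_KW)
    if raw.shape[1] < 2:
        raise FormatError("expression matrix needs an id column plus sample columns")
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any():
        dupes = raw[id_col][raw[id_col].duplicated()].unique()[:5]
        raise FormatError(f"duplicate transcript-cluster ids: {list(dupes)}")
    raw = raw.set_index(id_col)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    design = read_design(design_path)
    return ExpressionMatrix(values, design)


def write_expression_matrix(matrix: ExpressionMatrix, path, design_path=None) -> None:
    out = matrix.values.copy()
    out.insert(0, "cluster", out.index)
    out.to_csv(path, sep="\t", index=False)
    if design_path is not None:
        write_design(matrix.design, design_path)


def read_annotation(path) -> dict[str, set[str]]:
    """Read transcript-cluster -> gene-symbol map.

    Two tab-separated columns: cluster id, semicolon-separated symbols
    (possibly empty). Returns cluster -> set of symbols.
    """
    annotation: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header_skipped = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            cluster = parts[0]
            if not header_skipped:
                header_skipped = True
                if cluster == "cluster":
                    continue
            symbols_field = parts[1] if len(parts) > 1 else ""
            symbols = {s.strip() for s in symbols_field.split(";") if s.strip()}
            if cluster in annotation:
                raise FormatError(f"duplicate cluster row in annotation: {cluster!r}")
            annotation[cluster] = symbols
    return annotation


def write_annotation(annotation: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster\tsymbols\n")
        for cluster in sorted(annotation):
            fh.write(f"{cluster}\t{';'.join(sorted(annotation[cluster]))}\n")


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a result table as TSV with stable column order."""
    if index_label is not None:
        df = df.copy()
        df.insert(0, index_label, df.index)
    df.to_csv(path, sep="\t", index=False)
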