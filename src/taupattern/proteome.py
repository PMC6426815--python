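"""Nascent-proteome (puromycin-IP LC-MS/MS) set analysis.

Protein hit tables are filtered by post-search criteria (>= 1 unique
peptide, ion score strictly > 30), cleared of non-specific binders seen in
IgG-control runs, merged across the two non-transgenic groups, partitioned
into Venn regions, and summarized as per-category annotation-term ratios
against the non-transgenic reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError, FormatError

__all__ = [
    "ProteinHitTable",
    "DEFAULT_CATEGORIES",
    "filter_hits",
    "subtract_controls",
    "combine_non_groups",
    "venn_partition",
    "annotation_ratio",
    "read_hit_table",
    "write_hit_table",
]

#: heuristic functional categories for annotation-term grouping; users can
#: supply their own list matching their annotation-record table
DEFAULT_CATEGORIES = (
    "translation_ribosome",
    "synaptic",
    "metabolic",
    "cytoskeletal",
    "signaling",
    "other",
)

_HIT_COLUMNS = ["protein", "n_unique_peptides", "ion_score"]


@dataclass
class ProteinHitTable:
    """Protein-level hits for one IP run / group.

    ``records``: DataFrame with columns protein, n_unique_peptides,
    ion_score (best peptide ion score for the protein).
    """

    group: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _HIT_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"hit table {self.group!r} lacks columns {missing}")
        if self.records["protein"].duplicated().any():
            raise FormatError(f"duplicate protein ids in hit table {self.group!r}")
        self.records = self.records.reset_index(drop=True)

    @property
    def proteins(self) -> set[str]:
        return set(self.records["protein"])

    def __len__(self) -> int:
        return len(self.records)


def filter_hits(
    table: ProteinHitTable, min_unique: int = 1, min_ion_score: float = 30.0
) -> ProteinHitTable:
    """Keep records with >= ``min_unique`` unique peptides and ion score > ``min_ion_score``."""
    rec = table.records
    keep = (rec["n_unique_peptides"] >= min_unique) & (rec["ion_score"] > min_ion_score)
    return ProteinHitTable(table.group, rec.loc[keep].copy())


def subtract_controls(
    tables: list[ProteinHitTable], igg_tables: list[ProteinHitTable]
) -> list[ProteinHitTable]:
    """Remove any protein seen in any IgG-control run from every sample table."""
    nonspecific: set[str] = set()
    for igg in igg_tables:
        nonspecific |= igg.proteins
    out = []
    for table in tables:
        keep = ~table.records["protein"].isin(nonspecific)
        out.append(ProteinHitTable(table.group, table.records.loc[keep].copy()))
    return out


def combine_non_groups(
    tables: list[ProteinHitTable],
    non_groups: tuple[str, str] = ("Non_Veh", "Non_Dox"),
    merged_label: str = "Non",
) -> list[ProteinHitTable]:
    """Merge the two non-transgenic tables into a single ``Non`` table (set union).

    For proteins present in both inputs, the union record keeps the larger
    peptide count and the higher ion score.
    """
    by_group = {t.group: t for t in tables}
    missing = [g for g in non_groups if g not in by_group]
    if missing:
        raise AnalysisError(f"missing non-transgenic tables: {missing}")
    merged = pd.concat([by_group[g].records for g in non_groups], ignore_index=True)
    merged = (
        merged.groupby("protein", as_index=False)
        .agg({"n_unique_peptides": "max", "ion_score": "max"})
    )[_HIT_COLUMNS]
    out = [ProteinHitTable(merged_label, merged)]
    out.extend(t for t in tables if t.group not in non_groups)
    return out


def venn_partition(tables: list[ProteinHitTable]) -> dict[str, set[str]]:
    """Partition the union of 2-4 protein sets into disjoint Venn regions.

    Region keys are membership bit strings in table order ("10" = only the
    first table, "11" = both, ...). Regions are pairwise disjoint and their
    union equals the union of the inputs; empty regions are included with
    empty sets.
    """
    k = len(tables)
    if not 2 <= k <= 4:
        raise ConfigError(f"venn partition defined for 2-4 sets, got {k}")
    sets = [t.proteins for t in tables]
    universe = set().union(*sets)
    regions: dict[str, set[str]] = {
        "".join(bits): set()
        for bits in _nonzero_bitmasks(k)
    }
    for protein in universe:
        key = "".join("1" if protein in s else "0" for s in sets)
        regions[key].add(protein)
    return regions


def _nonzero_bitmasks(k: int):
    for mask in range(1, 2**k):
        yield tuple("1" if mask & (1 << (k - 1 - j)) else "0" for j in range(k))


def venn_counts(regions: dict[str, set[str]]) -> pd.Series:
    return pd.Series({key: len(v) for key, v in sorted(regions.items())}, name="count")


def annotation_ratio(
    records: pd.DataFrame,
    reference_group: str = "Non",
    alpha: float = 0.1,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Per-category annotation-term counts as a ratio to the reference group.

    ``records`` needs columns term, group, category, adjusted_p. Terms are
    kept only when adjusted_p < ``alpha`` (strict). The ratio for
    (group, category) is count(group, category) / count(reference, category);
    when the reference category count is zero the ratio is NaN (undefined).
    Returns a DataFrame categories x groups of ratios.
    """
    for col in ("term", "group", "category", "adjusted_p"):
        if col not in records.columns:
            raise FormatError(f"annotation records lack column {col!r}")
    unknown = set(records["category"]) - set(categories)
    if unknown:
        raise ConfigError(f"unknown annotation categories: {sorted(unknown)}")
    if reference_group not in set(records["group"]):
        raise AnalysisError(f"reference group {reference_group!r} absent from records")
    significant = records.loc[records["adjusted_p"] < alpha]
    counts = (
        significant.groupby(["category", "group"], observed=True)["term"]
        .nunique()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(index=list(categories), fill_value=0)
    ref = counts.get(reference_group, pd.Series(0, index=counts.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = counts.div(ref.replace(0, np.nan), axis=0)
    return ratios


def read_hit_table(path, group: str) -> ProteinHitTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["n_unique_peptides"] = df["n_unique_peptides"].astype(int)
    df["ion_score"] = df["ion_score"].astype(float)
    return ProteinHitTable(group, df[_HIT_COLUMNS])


def write_hit_table(table: ProteinHitTable, path) -> None:
    table.records[_HIT_COLUMNS].to_csv(path, sep="\t", index=False)
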