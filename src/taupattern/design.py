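"""The 2x2 study design: genotype (Non / Tg) crossed with treatment (Veh / Dox).

The four design cells are always handled in the fixed order
(Non+Veh, Non+Dox, Tg+Veh, Tg+Dox); every 4-vector in the package
(group means, idealized templates) follows this order.
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError

GENOTYPES = ("Non", "Tg")
TREATMENTS = ("Veh", "Dox")

#: Fixed group order used for group-mean vectors and templates.
GROUP_ORDER = ("Non_Veh", "Non_Dox", "Tg_Veh", "Tg_Dox")


def group_label(genotype: str, treatment: str) -> str:
    return f"{genotype}_{treatment}"


def validate_design(design: pd.DataFrame, require_all_cells: bool = True) -> pd.DataFrame:
    """Check a design table (index: sample id; columns: genotype, treatment).

    Returns the design with an added ``group`` column. Raises
    :class:`FormatError` on unknown levels or duplicate samples and, when
    ``require_all_cells``, on any empty design cell.
    """
    if design.index.has_duplicates:
        raise FormatError("duplicate sample ids in design table")
    for col, levels in (("genotype", GENOTYPES), ("treatment", TREATMENTS)):
        if col not in design.columns:
            raise FormatError(f"design table lacks required column {col!r}")
        bad = set(design[col]) - set(levels)
        if bad:
            raise FormatError(f"unknown {col} levels: {sorted(bad)} (expected {levels})")
    out = design.copy()
    out["group"] = [group_label(g, t) for g, t in zip(out["genotype"], out["treatment"])]
    if require_all_cells:
        present = set(out["group"])
        missing = [g for g in GROUP_ORDER if g not in present]
        if missing:
            raise FormatError(f"empty design cells: {missing}")
    return out
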