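"""Relative qPCR quantification by the 2^-ddCt method.

Per sample, dCt = Ct_target - Ct_reference (the reference being an internal
control such as GAPDH); ddCt subtracts the arithmetic mean dCt of the
control group; fold change = 2^-ddCt. Technical replicates (duplicate rows
for a sample) are averaged on the Ct scale before dCt is formed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError

__all__ = ["ddct_fold_change"]

logger = logging.getLogger(__name__)

_REQUIRED = ("sample", "group", "ct_target", "ct_reference")


def ddct_fold_change(
    table: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample and per-group 2^-ddCt fold changes relative to ``control_group``.

    ``table`` needs columns sample, group, ct_target, ct_reference. Records
    with a missing reference (or target) Ct are skipped and logged. Returns
    ``(per_sample, per_group)``: the per-sample frame carries dct, ddct and
    fold_change columns; the per-group Series is the arithmetic mean of
    per-sample fold changes.
    """
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"Ct table lacks columns {missing}")
    work = table.copy()
    work["ct_target"] = pd.to_numeric(work["ct_target"], errors="coerce")
    work["ct_reference"] = pd.to_numeric(work["ct_reference"], errors="coerce")
    bad = work["ct_target"].isna() | work["ct_reference"].isna()
    if bad.any():
        logger.warning("skipping %d Ct records with missing values", int(bad.sum()))
        work = work.loc[~bad]
    if not (work["group"] == control_group).any():
        raise AnalysisError(f"control group {control_group!r} is empty")

    # technical replicates: average Cts per sample before forming dCt
    work = (
        work.groupby(["sample", "group"], as_index=False)[["ct_target", "ct_reference"]]
        .mean()
    )
    work["dct"] = work["ct_target"] - work["ct_reference"]
    control_mean = work.loc[work["group"] == control_group, "dct"].mean()
    work["ddct"] = work["dct"] - control_mean
    work["fold_change"] = np.exp2(-work["ddct"])
    per_group = work.groupby("group")["fold_change"].mean()
    return work, per_group
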