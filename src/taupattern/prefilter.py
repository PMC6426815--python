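"""Pre-statistical filtering of the expression matrix.

Two filters are applied before any testing: transcript clusters must be
uniquely annotated to a single gene symbol, and must show reliable signal
(log2 RMA intensity strictly above 6.76 on at least one array). Both
filters only drop rows; no intensity is ever modified, and both are
idempotent and commute.
"""

from __future__ import annotations

import logging

from .io import ExpressionMatrix

__all__ = ["filter_unique_annotation", "filter_signal", "SIGNAL_THRESHOLD"]

logger = logging.getLogger(__name__)

SIGNAL_THRESHOLD = 6.76


def filter_unique_annotation(
    matrix: ExpressionMatrix,
    annotation: dict[str, set[str]],
    collapse_symbols: bool = True,
) -> ExpressionMatrix:
    """Keep clusters annotated to exactly one gene symbol.

    Rows missing from the annotation map are treated as non-annotated and
    dropped (logged). With ``collapse_symbols`` (default), when several
    retained clusters map to the same symbol only the cluster with the
    highest mean intensity survives (ties broken by lexicographic cluster
    id), yielding a symbol-unique matrix.
    """
    keep: list[str] = []
    n_missing = n_multi = 0
    for cluster in matrix.genes:
        symbols = annotation.get(cluster)
        if symbols is None:
            n_missing += 1
        elif len(symbols) == 1:
            keep.append(cluster)
        else:
            n_multi += 1
    if n_missing:
        logger.warning("dropped %d clusters absent from the annotation map", n_missing)
    if collapse_symbols:
        mean_intensity = matrix.values.loc[keep].mean(axis=1)
        best: dict[str, str] = {}
        for cluster in keep:
            symbol = next(iter(annotation[cluster]))
            incumbent = best.get(symbol)
            if incumbent is None:
                best[symbol] = cluster
                continue
            a, b = mean_intensity[cluster], mean_intensity[incumbent]
            if a > b or (a == b and cluster < incumbent):
                best[symbol] = cluster
        chosen = set(best.values())
        keep = [c for c in keep if c in chosen]
    logger.info(
        "annotation filter: %d -> %d rows (%d missing, %d multi-symbol)",
        len(matrix.genes), len(keep), n_missing, n_multi,
    )
    return matrix.subset(keep)


def filter_signal(matrix: ExpressionMatrix, threshold: float = SIGNAL_THRESHOLD) -> ExpressionMatrix:
    """Keep rows whose maximum intensity is strictly above ``threshold`` on >= 1 array."""
    keep = matrix.values.max(axis=1) > threshold
    logger.info("signal filter (> %.2f): %d -> %d rows", threshold, len(keep), int(keep.sum()))
    return matrix.subset(matrix.genes[keep])
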