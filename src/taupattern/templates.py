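"""Template-matching pattern classification and binomial pattern enrichment.

DEG group-mean profiles over the four design cells (Non+Veh, Non+Dox,
Tg+Veh, Tg+Dox) are Pearson-correlated against six idealized 0/1 templates;
a gene is assigned to the template of highest absolute correlation when
|r| >= 0.85, with the sign of r recording whether the gene follows the
pattern or its mirror reflection. Template enrichment is tested against a
permutation-estimated chance assignment rate with an upper-tail exact
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import GROUP_ORDER
from .errors import AnalysisError
from .io import ExpressionMatrix

__all__ = [
    "Template",
    "PatternAssignment",
    "TEMPLATE_NAMES",
    "canonical_templates",
    "group_means",
    "template_correlation",
    "assign_pattern",
    "assign_patterns",
    "EnrichmentNull",
    "enrichment_null_rate",
    "test_enrichment",
]


class Template(NamedTuple):
    """A named ideal intensity 4-vector in the fixed design-cell order."""

    name: str
    values: tuple[float, float, float, float]


TEMPLATE_NAMES = (
    "rescued_by_tau_reduction",
    "resistant_to_tau_suppression",
    "dox_altered",
    "dox_and_tg_altered",
    "dox_only_in_non",
    "dox_only_in_tg",
)

_CANONICAL_VALUES = (
    (0, 0, 1, 0),  # high only with unsuppressed transgenic tau; dox rescues
    (0, 0, 1, 1),  # altered by the transgene, unaffected by tau suppression
    (0, 1, 0, 1),  # doxycycline effect in both genotypes
    (0, 1, 1, 2),  # additive doxycycline + transgene effect
    (0, 1, 0, 0),  # doxycycline effect only in non-transgenics
    (0, 0, 0, 1),  # doxycycline effect only in transgenics
)


def canonical_templates() -> list[Template]:
    """The six canonical expression patterns, in fixed order."""
    return [Template(n, v) for n, v in zip(TEMPLATE_NAMES, _CANONICAL_VALUES)]


@dataclass
class PatternAssignment:
    gene: str
    template: str | None
    r: float
    direction: int  # sign of r; 0 when unassigned

    @property
    def assigned(self) -> bool:
        return self.template is not None


def group_means(matrix: ExpressionMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Arithmetic mean intensity per design cell (columns in fixed order)."""
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]
    groups = matrix.groups()
    cols = {}
    for g in GROUP_ORDER:
        samples = groups.index[groups == g]
        if len(samples) == 0:
            raise AnalysisError(f"design cell {g} is empty")
        cols[g] = values[samples].mean(axis=1)
    return pd.DataFrame(cols)[list(GROUP_ORDER)]


def template_correlation(means: Sequence[float], template: Template | Sequence[float]) -> float:
    """Pearson product-moment correlation of a 4-vector with a template.

    Returns NaN when either vector has zero variance.
    """
    t = np.asarray(template.values if isinstance(template, Template) else template, dtype=float)
    m = np.asarray(means, dtype=float)
    mc, tc = m - m.mean(), t - t.mean()
    denom = np.linalg.norm(mc) * np.linalg.norm(tc)
    if denom == 0:
        return float("nan")
    return float(np.dot(mc, tc) / denom)


def _correlation_matrix(means: np.ndarray, templates: list[Template]) -> np.ndarray:
    """Genes x templates Pearson correlations; NaN rows for constant means."""
    t = np.array([tpl.values for tpl in templates], dtype=float)
    tc = t - t.mean(axis=1, keepdims=True)
    tc /= np.linalg.norm(tc, axis=1, keepdims=True)
    mc = means - means.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc / norms) @ tc.T
    r[norms.ravel() == 0] = np.nan
    return r


def assign_pattern(
    means: Sequence[float],
    templates: list[Template] | None = None,
    r_min: float = 0.85,
) -> PatternAssignment:
    """Assign one group-mean vector to the template of highest |r|.

    Ties on |r| go to the earlier template in canonical order. Constant mean
    vectors are unassignable (r = NaN).
    """
    templates = templates or canonical_templates()
    gene = getattr(means, "name", "")
    r = _correlation_matrix(np.asarray(means, dtype=float)[None, :], templates)[0]
    if np.isnan(r).all():
        return PatternAssignment(gene, None, float("nan"), 0)
    best = int(np.nanargmax(np.abs(r)))
    r_best = float(r[best])
    if abs(r_best) >= r_min:
        return PatternAssignment(gene, templates[best].name, r_best, int(np.sign(r_best)))
    return PatternAssignment(gene, None, r_best, 0)


def assign_patterns(
    means: pd.DataFrame,
    templates: list[Template] | None = None,
    r_min: float = 0.85,
) -> pd.DataFrame:
    """Vectorized :func:`assign_pattern` over a genes x 4 group-mean table.

    Returns a DataFrame indexed by gene with columns ``template`` (name or
    ``""``), ``r`` (best correlation, NaN if undefined), ``direction``
    (+1/-1, 0 when unassigned) and ``assigned``.
    """
    templates = templates or canonical_templates()
    r = _correlation_matrix(means.to_numpy(dtype=float), templates)
    absr = np.abs(r)
    undefined = np.isnan(absr).all(axis=1)
    best = np.where(undefined, 0, np.nanargmax(np.where(np.isnan(absr), -1, absr), axis=1))
    r_best = r[np.arange(len(means)), best]
    assigned = ~undefined & (np.abs(r_best) >= r_min)
    out = pd.DataFrame(
        {
            "template": np.where(assigned, np.array(TEMPLATE_NAMES, dtype=object)[best], ""),
            "r": np.where(undefined, np.nan, r_best),
            "direction": np.where(assigned, np.sign(r_best), 0).astype(int),
            "assigned": assigned,
        },
        index=means.index,
    )
    return out


class EnrichmentNull(NamedTuple):
    """Permutation-estimated chance assignment probabilities.

    ``p0`` is indexed by template name; ``n_reference`` is the binomial
    denominator the probabilities refer to (tested genes in ``screen`` mode,
    DEG count in ``fixed_degs`` mode).
    """

    p0: pd.Series
    n_reference: int
    mode: str


def _counts_per_template(assignments: pd.DataFrame, templates: list[Template]) -> np.ndarray:
    hit = assignments.loc[assignments["assigned"], "template"].value_counts()
    return np.array([hit.get(t.name, 0) for t in templates], dtype=float)


def enrichment_null_rate(
    matrix: ExpressionMatrix,
    degs: Sequence[str],
    templates: list[Template] | None = None,
    r_min: float = 0.85,
    n_perm: int = 200,
    seed: int | None = None,
    mode: str = "screen",
    alpha: float = 0.01,
    ss_type: str = "III",
    permutations=None,
) -> EnrichmentNull:
    """Chance per-template assignment probability p0 by design-label permutation.

    Each permutation shuffles the sample -> design-cell assignment globally.
    In ``screen`` mode (default) the whole screen is replayed on the
    permuted labels — DEGs re-selected at ``alpha`` and re-assigned — and p0
    is the chance probability that a *tested* gene ends up selected and
    assigned to the template; this accounts for the design-aligned structure
    that selection at alpha induces in group means, so the downstream
    binomial test is calibrated on null data. In ``fixed_degs`` mode the
    observed DEG set is kept and only its group means are recomputed, giving
    the chance assigned-fraction among those genes.

    p0 is clipped away from 0 and 1 by 1/(n_reference * n_perm). Explicit
    ``permutations`` (sample-index arrays) may replace the random shuffles.
    """
    templates = templates or canonical_templates()
    degs = list(degs)
    if not degs:
        raise AnalysisError("cannot estimate a null assignment rate with zero DEGs")
    if mode not in ("screen", "fixed_degs"):
        raise AnalysisError(f"unknown null-rate mode {mode!r}")
    rng = np.random.default_rng(seed)
    design = matrix.design
    if permutations is None:
        permutations = [rng.permutation(len(design)) for _ in range(n_perm)]
    n_perm = len(permutations)

    counts = np.zeros(len(templates))
    denom = 0
    for perm in permutations:
        shuffled = design.iloc[perm][["genotype", "treatment"]].copy()
        shuffled.index = design.index
        permuted = ExpressionMatrix(matrix.values, shuffled)
        if mode == "screen":
            from .anova import anova_matrix, select_degs

            deg_set = select_degs(anova_matrix(permuted, ss_type=ss_type), alpha=alpha)
            denom += deg_set.n_tested
            chosen = deg_set.selected
        else:
            denom += len(degs)
            chosen = degs
        if chosen:
            means = group_means(permuted, chosen)
            assign = assign_patterns(means, templates, r_min)
            counts += _counts_per_template(assign, templates)

    n_reference = int(round(denom / n_perm))
    p0 = counts / denom
    eps = 1.0 / max(denom, 1)
    p0 = pd.Series(
        np.clip(p0, eps, 1 - eps), index=[t.name for t in templates], name="p0"
    )
    return EnrichmentNull(p0, n_reference, mode)


def test_enrichment(
    assignments: pd.DataFrame,
    p0: pd.Series | EnrichmentNull,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail exact binomial enrichment test per template.

    ``k`` counts genes assigned to the template (either sign); genes with
    undefined correlation count toward the denominator but never toward
    ``k``. The p-value is P(X >= k | N, p0); a template is enriched when
    p <= alpha. When ``p0`` is a plain Series (e.g. the uniform 1/6
    fallback) the denominator N is the number of DEGs in ``assignments``;
    an :class:`EnrichmentNull` carries its own matching denominator.
    """
    if isinstance(p0, EnrichmentNull):
        n_total = p0.n_reference if p0.mode == "screen" else len(assignments)
        rates = p0.p0
    else:
        n_total = len(assignments)
        rates = p0
    observed = assignments.loc[assignments["assigned"], "template"].value_counts()
    rows = []
    for name in rates.index:
        k = int(observed.get(name, 0))
        p = float(stats.binom.sf(k - 1, n_total, rates[name])) if k > 0 else 1.0
        rows.append((name, k, n_total, float(rates[name]), p, p <= alpha))
    return pd.DataFrame(
        rows, columns=["template", "k", "N", "p0", "p_binomial", "enriched"]
    ).set_index("template")


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p) via the regularized survival function."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(stats.binom.sf(k - 1, n, p))
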