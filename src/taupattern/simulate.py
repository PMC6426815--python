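"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators mirror the three kinds of study input:

* :func:`generate_expression` — a log2-intensity matrix over the 2x2
  genotype x treatment design, with a planted fraction of genes following
  each idealized expression template, a fraction of low-signal rows (to
  exercise the signal prefilter) and ambiguously / un-annotated clusters
  (to exercise the annotation prefilter).
* :func:`generate_proteome` — per-group immunoprecipitation protein hit
  tables with shared contaminants that also appear in IgG-control runs.
* :func:`generate_ct_table` — qPCR Ct tables with known per-group fold
  changes relative to a control group.

Every generator takes an explicit integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUP_ORDER
from .errors import ConfigError
from .io import ExpressionMatrix
from .proteome import ProteinHitTable
from .templates import TEMPLATE_NAMES, canonical_templates

__all__ = [
    "SimConfig",
    "ProteomeSimConfig",
    "CtSimConfig",
    "generate_expression",
    "generate_annotation",
    "generate_proteome",
    "generate_ct_table",
]

#: default per-cell sample counts; the Tg_Veh cell has one fewer array,
#: mirroring a quality-control removal, so unbalanced ANOVA paths are exercised.
DEFAULT_N_PER_GROUP = (6, 6, 5, 6)

SIGNAL_THRESHOLD = 6.76


@dataclass
class SimConfig:
    """Parameters of the synthetic expression matrix.

    All intensities are on the log2 RMA scale. ``planted_fraction`` is the
    fraction of genes planted per template (six templates); planted genes get
    group means ``baseline + direction * effect_size * template_value`` with
    direction drawn +1/-1 with equal probability. ``low_signal_fraction``
    rows are drawn entirely below the 6.76 signal threshold;
    ``ambiguous_fraction`` clusters map to two gene symbols and
    ``unannotated_fraction`` to none, so the annotation prefilter has work
    to do. Fractions must sum to at most 1 across the six templates plus the
    special rows.
    """

    n_genes: int = 10_000
    n_per_group: tuple[int, int, int, int] = DEFAULT_N_PER_GROUP
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.25
    effect_size: float = 1.0
    planted_fraction: float = 0.05
    low_signal_fraction: float = 0.10
    ambiguous_fraction: float = 0.02
    unannotated_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if len(self.n_per_group) != 4 or any(n < 2 for n in self.n_per_group):
            raise ConfigError("n_per_group needs 4 entries, each >= 2")
        if self.baseline_sd <= 0 or self.noise_sd < 0:
            raise ConfigError("baseline_sd must be > 0 and noise_sd >= 0")
        fracs = (
            self.planted_fraction,
            self.low_signal_fraction,
            self.ambiguous_fraction,
            self.unannotated_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("fractions must lie in [0, 1]")
        total = (
            6 * self.planted_fraction
            + self.low_signal_fraction
            + self.ambiguous_fraction
            + self.unannotated_fraction
        )
        if total > 1 + 1e-12:
            raise ConfigError(f"planted + special fractions exceed 1 ({total:.3f})")


def _sample_ids(n_per_group: tuple[int, int, int, int]) -> tuple[list[str], list[str]]:
    samples, groups = [], []
    for group, n in zip(GROUP_ORDER, n_per_group):
        for i in range(n):
            samples.append(f"{group}_{i + 1}")
            groups.append(group)
    return samples, groups


def generate_expression(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a seeded expression matrix and its planting record.

    Returns ``(matrix, truth)`` where ``truth`` is indexed by gene with
    columns ``template`` (name or ``""``), ``direction`` (+1/-1, 0 when not
    planted), ``effect`` and ``status`` in
    {planted, null, low_signal, ambiguous, unannotated}.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"TC{i + 1:06d}" for i in range(n)]
    samples, groups = _sample_ids(config.n_per_group)
    group_idx = np.array([GROUP_ORDER.index(g) for g in groups])

    n_planted_each = int(round(config.planted_fraction * n))
    n_low = int(round(config.low_signal_fraction * n))
    n_ambig = int(round(config.ambiguous_fraction * n))
    n_unannot = int(round(config.unannotated_fraction * n))

    status = np.array(["null"] * n, dtype=object)
    template_of = np.array([""] * n, dtype=object)
    pos = 0
    for name in TEMPLATE_NAMES:
        status[pos : pos + n_planted_each] = "planted"
        template_of[pos : pos + n_planted_each] = name
        pos += n_planted_each
    status[pos : pos + n_low] = "low_signal"
    pos += n_low
    status[pos : pos + n_ambig] = "ambiguous"
    pos += n_ambig
    status[pos : pos + n_unannot] = "unannotated"

    direction = np.where(status == "planted", rng.choice([-1, 1], size=n), 0)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    low = status == "low_signal"
    # low-signal rows: baseline well under the threshold; a final clip keeps
    # even extreme noise draws strictly below 6.76
    baseline[low] = rng.uniform(4.0, 5.8, size=int(low.sum()))

    template_values = {t.name: np.asarray(t.values, dtype=float) for t in canonical_templates()}
    offsets = np.zeros((n, 4))
    for i in range(n):
        if status[i] == "planted":
            offsets[i] = direction[i] * config.effect_size * template_values[template_of[i]]

    means = baseline[:, None] + offsets  # n_genes x 4 cell means
    values = means[:, group_idx] + rng.normal(0.0, config.noise_sd, size=(n, len(samples)))
    values[low] = np.minimum(values[low], SIGNAL_THRESHOLD - 0.01)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.DataFrame(
            {
                "genotype": [g.split("_")[0] for g in groups],
                "treatment": [g.split("_")[1] for g in groups],
            },
            index=pd.Index(samples, name="sample"),
        ),
    )
    truth = pd.DataFrame(
        {
            "template": template_of,
            "direction": direction,
            "effect": np.where(status == "planted", config.effect_size, 0.0),
            "status": status,
        },
        index=pd.Index(genes, name="gene"),
    )
    return matrix, truth


def generate_annotation(truth: pd.DataFrame) -> dict[str, set[str]]:
    """Symbol annotation consistent with a planting record.

    Clean clusters map 1:1 to a symbol; ``ambiguous`` clusters carry two
    symbols and ``unannotated`` clusters none, so the uniqueness prefilter
    drops exactly those.
    """
    annotation: dict[str, set[str]] = {}
    for i, (gene, row) in enumerate(truth.iterrows()):
        if row["status"] == "unannotated":
            annotation[gene] = set()
        elif row["status"] == "ambiguous":
            annotation[gene] = {f"G{i + 1:06d}", f"G{i + 1:06d}B"}
        else:
            annotation[gene] = {f"G{i + 1:06d}"}
    return annotation


@dataclass
class ProteomeSimConfig:
    """Parameters of the synthetic IP-proteomics hit tables.

    A fraction of the protein universe are contaminants: they bind
    non-specifically, so they show up in the IgG-control runs (and in the
    sample runs) with probability ``contaminant_presence``. The remaining
    proteins are signal and appear in each group's table independently with
    probability ``signal_presence``. ``low_score_fraction`` of records get
    ion scores <= 30 and ``zero_peptide_fraction`` get zero unique peptides,
    so both post-search filters are exercised.
    """

    n_proteins: int = 300
    contaminant_fraction: float = 0.2
    contaminant_presence: float = 0.9
    signal_presence: float = 0.3
    low_score_fraction: float = 0.1
    zero_peptide_fraction: float = 0.05
    groups: tuple[str, ...] = GROUP_ORDER
    igg_groups: tuple[str, ...] = ("IgG_Non", "IgG_Tg")

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError("protein universe must be non-empty")
        for name in (
            "contaminant_fraction",
            "contaminant_presence",
            "signal_presence",
            "low_score_fraction",
            "zero_peptide_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")


def _hit_records(rng, proteins, config) -> pd.DataFrame:
    n = len(proteins)
    peptides = rng.poisson(2.0, size=n) + 1
    peptides[rng.random(n) < config.zero_peptide_fraction] = 0
    scores = rng.uniform(31.0, 120.0, size=n)
    low = rng.random(n) < config.low_score_fraction
    scores[low] = rng.uniform(10.0, 30.0, size=int(low.sum()))
    return pd.DataFrame(
        {"protein": proteins, "n_unique_peptides": peptides, "ion_score": np.round(scores, 2)}
    )


def generate_proteome(
    config: ProteomeSimConfig, seed: int
) -> tuple[list[ProteinHitTable], pd.DataFrame]:
    """Generate per-group hit tables plus IgG-control tables and the truth.

    ``truth`` is indexed by protein with columns ``contaminant`` (bool) and
    one boolean presence column per sample group.
    """
    rng = np.random.default_rng(seed)
    proteins = np.array([f"P{i + 1:05d}" for i in range(config.n_proteins)])
    n_contam = int(round(config.contaminant_fraction * config.n_proteins))
    contaminant = np.zeros(config.n_proteins, dtype=bool)
    contaminant[:n_contam] = True

    truth = pd.DataFrame({"contaminant": contaminant}, index=pd.Index(proteins, name="protein"))
    tables: list[ProteinHitTable] = []
    for group in config.groups:
        present = np.where(
            contaminant,
            rng.random(config.n_proteins) < config.contaminant_presence,
            rng.random(config.n_proteins) < config.signal_presence,
        )
        truth[group] = present
        tables.append(ProteinHitTable(group, _hit_records(rng, proteins[present], config)))
    for group in config.igg_groups:
        present = contaminant & (rng.random(config.n_proteins) < config.contaminant_presence)
        tables.append(ProteinHitTable(group, _hit_records(rng, proteins[present], config)))
    return tables, truth


@dataclass
class CtSimConfig:
    """Parameters of the synthetic qPCR Ct table.

    ``group_fold_changes`` maps group label -> true expression fold change
    relative to ``control_group`` (whose fold change is 1). Target Ct values
    follow ``Ct_target = Ct_reference + offset - log2(fold) + noise``.
    """

    group_fold_changes: dict[str, float] = field(
        default_factory=lambda: {"Control": 1.0, "Case": 2.0}
    )
    control_group: str = "Control"
    n_per_group: int = 6
    noise_sd: float = 0.1
    reference_ct_mean: float = 18.0
    target_offset: float = 6.0

    def __post_init__(self) -> None:
        if self.control_group not in self.group_fold_changes:
            raise ConfigError("control group missing from group_fold_changes")
        if any(f <= 0 for f in self.group_fold_changes.values()):
            raise ConfigError("fold changes must be positive")
        if self.n_per_group < 1 or self.noise_sd < 0:
            raise ConfigError("need n_per_group >= 1 and noise_sd >= 0")


def generate_ct_table(config: CtSimConfig, seed: int) -> pd.DataFrame:
    """Generate a Ct table with columns sample, group, ct_target, ct_reference."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in config.group_fold_changes.items():
        for i in range(config.n_per_group):
            ct_ref = config.reference_ct_mean + rng.normal(0.0, config.noise_sd)
            ct_target = (
                ct_ref
                + config.target_offset
                - np.log2(fold)
                + rng.normal(0.0, config.noise_sd)
            )
            rows.append((f"{group}_{i + 1}", group, round(ct_target, 4), round(ct_ref, 4)))
    return pd.DataFrame(rows, columns=["sample", "group", "ct_target", "ct_reference"])
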