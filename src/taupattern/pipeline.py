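"""Orchestration of the transcriptome pipeline: (simulate |) load -> prefilter
-> ANOVA DEG screen -> template matching -> binomial enrichment.

Every stage reads and writes plain TSV, so any stage can be rerun on its
own; a JSON manifest records thresholds, seeds, input digests and the
per-stage funnel counts (tested -> DEG -> assigned).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anova import anova_matrix, estimate_fdr, select_degs
from .errors import ConfigError
from .io import ExpressionMatrix, read_annotation, read_expression_matrix, write_table
from .prefilter import filter_signal, filter_unique_annotation
from .simulate import SimConfig, generate_annotation, generate_expression
from .templates import (
    assign_patterns,
    canonical_templates,
    enrichment_null_rate,
    group_means,
    test_enrichment,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the transcriptome pipeline in one place.

    Defaults are the published analysis settings: signal > 6.76, ANOVA
    p <= 0.01, |r| >= 0.85 for template assignment, binomial p <= 0.05 for
    enrichment.
    """

    matrix_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    simulate: SimConfig | None = None

    signal_threshold: float = 6.76
    collapse_symbols: bool = True
    alpha: float = 0.01
    ss_type: str = "III"
    fdr_method: str = "permutation"
    n_perm_fdr: int = 100
    r_min: float = 0.85
    null_method: str = "screen"  # or "fixed_degs" (permute means of the observed DEG set) or "uniform" (p0 = 1/6)
    n_perm_null: int = 200
    enrichment_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and (self.matrix_path is None or self.design_path is None):
            raise ConfigError("either a simulation config or matrix+design paths are required")
        for name, lo, hi in (
            ("alpha", 0, 1),
            ("r_min", 0, 1),
            ("enrichment_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigError(f"{name} must lie in ({lo}, {hi}]")


@dataclass
class PipelineResult:
    filtered: ExpressionMatrix
    anova: pd.DataFrame
    degs: "object"
    assignments: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full transcriptome pipeline and optionally write stage TSVs."""
    manifest: dict = {
        "package_version": __version__,
        "thresholds": {
            "signal_threshold": config.signal_threshold,
            "alpha": config.alpha,
            "r_min": config.r_min,
            "enrichment_alpha": config.enrichment_alpha,
            "ss_type": config.ss_type,
            "fdr_method": config.fdr_method,
            "null_method": config.null_method,
        },
        "seed": config.seed,
        "inputs": {},
    }

    if config.simulate is not None:
        matrix, truth = generate_expression(config.simulate)
        annotation = generate_annotation(truth)
        manifest["inputs"]["simulation"] = asdict(config.simulate)
    else:
        matrix = read_expression_matrix(config.matrix_path, config.design_path)
        manifest["inputs"]["matrix_sha256"] = _digest(config.matrix_path)
        manifest["inputs"]["design_sha256"] = _digest(config.design_path)
        annotation = None
        if config.annotation_path:
            annotation = read_annotation(config.annotation_path)
            manifest["inputs"]["annotation_sha256"] = _digest(config.annotation_path)
        truth = None

    n_input = len(matrix.genes)
    filtered = matrix
    if annotation is not None:
        filtered = filter_unique_annotation(filtered, annotation, config.collapse_symbols)
    filtered = filter_signal(filtered, config.signal_threshold)
    logger.info("prefilter: %d -> %d rows", n_input, len(filtered.genes))

    results = anova_matrix(filtered, ss_type=config.ss_type)
    degs = select_degs(results, alpha=config.alpha)
    degs.fdr_estimate = estimate_fdr(
        filtered,
        alpha=config.alpha,
        n_perm=config.n_perm_fdr,
        seed=config.seed,
        ss_type=config.ss_type,
        method=config.fdr_method,
    )
    degs.fdr_method = config.fdr_method
    logger.info(
        "DEG screen: %d/%d genes at p <= %g (FDR %s %.3g)",
        len(degs.selected), degs.n_tested, config.alpha, config.fdr_method, degs.fdr_estimate,
    )

    templates = canonical_templates()
    means = group_means(filtered, degs.selected) if degs.selected else pd.DataFrame()
    assignments = (
        assign_patterns(means, templates, config.r_min) if degs.selected else pd.DataFrame()
    )
    if degs.selected:
        if config.null_method == "uniform":
            p0 = pd.Series(1.0 / len(templates), index=[t.name for t in templates], name="p0")
        else:
            p0 = enrichment_null_rate(
                filtered,
                degs.selected,
                templates,
                config.r_min,
                n_perm=config.n_perm_null,
                seed=config.seed + 1,
                mode=config.null_method,
                alpha=config.alpha,
                ss_type=config.ss_type,
            )
        enrichment = test_enrichment(assignments, p0, alpha=config.enrichment_alpha)
    else:
        enrichment = pd.DataFrame()

    manifest["counts"] = {
        "input_rows": n_input,
        "filtered_rows": len(filtered.genes),
        "tested": degs.n_tested,
        "degs": len(degs.selected),
        "assigned": int(assignments["assigned"].sum()) if len(assignments) else 0,
        "enriched_templates": int(enrichment["enriched"].sum()) if len(enrichment) else 0,
    }
    manifest["fdr_estimate"] = degs.fdr_estimate

    result = PipelineResult(filtered, results, degs, assignments, enrichment, manifest)
    if outdir is not None:
        _write_outputs(result, Path(outdir), truth)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, truth) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import write_expression_matrix

    write_expression_matrix(
        result.filtered, outdir / "filtered_matrix.tsv", outdir / "design.tsv"
    )
    deg_table = result.anova.copy()
    deg_table["selected"] = deg_table.index.isin(result.degs.selected)
    for effect, genes in result.degs.by_effect.items():
        deg_table[f"selected_{effect}"] = deg_table.index.isin(genes)
    write_table(deg_table, outdir / "degs.tsv", index_label="gene")
    if len(result.assignments):
        write_table(result.assignments, outdir / "patterns.tsv", index_label="gene")
    if len(result.enrichment):
        write_table(result.enrichment, outdir / "enrichment.tsv", index_label="template")
    if truth is not None:
        write_table(truth, outdir / "truth.tsv", index_label="gene")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
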