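"""End-to-end orchestration: expression + ontology in, clusters out.

The pipeline runs filter -> log -> enrich -> SimRel reduction -> repetitive
rate reduction -> per-set KPCA -> agglomerative clustering, persisting every
intermediate so the surviving functional gene sets can be audited, and
evaluates against reference labels when they are provided.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import cluster as cl
from . import enrichment as en
from . import features as ft
from . import ontology as on
from . import repetition as rp
from . import semantic as sm

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    expr: str
    obo: str
    annot: str
    outdir: str
    k: int
    truth: str | None = None
    annot_fmt: str = "tsv"
    transpose: bool = False
    alpha: float = 0.05
    min_genes: int = 2
    simrel_cutoff: float = 0.4
    representative: str = "ancestor_first"
    rep_threshold: float = 0.8
    rounds: int = 2
    until_converged: bool = False
    retain_mode: str = "variance"
    retain_ratio: float | None = None  # None: pick from cell count
    linkage: str = "ward"
    matching: str = "majority"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 <= self.simrel_cutoff <= 1.0:
            raise ValueError("simrel_cutoff must be in [0, 1]")
        if not 0.0 < self.rep_threshold <= 1.0:
            raise ValueError("rep_threshold must be in (0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.linkage not in cl.LINKAGES:
            raise ValueError(f"linkage must be one of {cl.LINKAGES}")
        if self.retain_mode not in ("variance", "count"):
            raise ValueError("retain_mode must be 'variance' or 'count'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML (or key: value) config, rejecting unknown keys."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> cl.MetricReport | None:
    """Execute the full pipeline, persisting intermediates under outdir.

    Returns the metric report when reference labels are configured, else
    None.  Any stage failure is re-raised as :class:`StageError` naming the
    stage; artifacts written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config: {dataclasses.asdict(config)}"]

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:
                _write_log(outdir, log_lines + [f"{name}: FAILED ({exc})"])
                raise StageError(name, exc) from exc
            return result
        return deco

    expr = stage("load_expression")(
        lambda: ft.read_expression(config.expr, transpose=config.transpose))
    graph = stage("parse_obo")(lambda: on.parse_obo(config.obo))
    annot = stage("parse_annotations")(
        lambda: on.propagate(graph, on.parse_annotations(
            config.annot, fmt=config.annot_fmt)))
    log_lines.append(
        f"inputs: {expr.n_cells} cells x {len(expr.gene_ids)} genes, "
        f"{len(graph.terms)} terms, {len(annot.genes)} annotated genes")

    expr = stage("filter_noise_genes")(lambda: ft.filter_noise_genes(expr))
    log_lines.append(f"filter_noise_genes: {len(expr.gene_ids)} genes kept")
    expr = stage("log_transform")(lambda: ft.log_transform(expr))

    terms = stage("enrich")(lambda: en.enrich(
        expr.gene_ids, graph, annot,
        alpha=config.alpha, min_genes=config.min_genes))
    en.write_enrichment_tsv(terms, outdir / "enrichment.tsv")
    log_lines.append(f"enrich: {len(terms)} significant terms")

    report: list[tuple[str, str, float]] = []
    terms = stage("semantic_reduction")(lambda: sm.reduce_terms(
        terms, graph, annot, cutoff=config.simrel_cutoff,
        representative=config.representative, report=report))
    with open(outdir / "semantic_reduction.tsv", "w") as fh:
        fh.write("discarded\trepresentative\tsimrel\n")
        for drop, keep, s in report:
            fh.write(f"{drop}\t{keep}\t{s:.4f}\n")
    log_lines.append(f"semantic_reduction: {len(terms)} terms survive")

    sets = [rp.FunctionalGeneSet.from_enriched(t) for t in terms]
    sets = stage("repetition_reduction")(lambda: rp.reduce_redundancy(
        sets, threshold=config.rep_threshold, rounds=config.rounds,
        until_converged=config.until_converged))
    rp.write_gmt(sets, outdir / "gene_sets.gmt")
    log_lines.append(f"repetition_reduction: {len(sets)} functional gene sets")

    ratio = (config.retain_ratio if config.retain_ratio is not None
             else ft.retention_ratio(expr.n_cells))
    fm = stage("build_feature_matrix")(lambda: ft.build_feature_matrix(
        expr, sets, ratio, mode=config.retain_mode))
    ft.write_feature_matrix(fm, outdir / "features.csv")
    log_lines.append(
        f"build_feature_matrix: ratio {ratio:.2f}, "
        f"{fm.values.shape[1]} components")

    result = stage("cluster")(lambda: cl.agglomerative(
        fm, k=config.k, linkage=config.linkage))
    cl.write_labels(fm.cell_ids, result.labels, outdir / "labels.tsv")
    log_lines.append(f"cluster: k={config.k}, linkage={config.linkage}")

    metrics = None
    if config.truth:
        truth_ids, truth = cl.read_labels(config.truth)
        order = {cid: i for i, cid in enumerate(truth_ids)}
        aligned = truth[[order[cid] for cid in fm.cell_ids]]
        metrics = stage("evaluate")(lambda: cl.evaluate(
            aligned, result.labels, matching=config.matching))
        with open(outdir / "metrics.tsv", "w") as fh:
            fh.write("ARI\tNMI\tHOM\tCOM\n")
            fh.write("\t".join(f"{v:.4f}" for v in (
                metrics.ari, metrics.nmi, metrics.hom, metrics.com)) + "\n")
        log_lines.append(f"evaluate: {metrics.as_dict()}")

    _write_log(outdir, log_lines)
    return metrics


def _write_log(outdir: Path, lines: list[str]) -> None:
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
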