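"""End-to-end orchestration: thickness → ΔCT → PLS → inference → profiling.

A single :class:`PipelineConfig` (YAML-loadable) drives the full analysis:
load or simulate the inputs, compute ΔCT, standardize and align expression,
select the component count by cross-validation, fit, permutation-test the
first component's variance explained, bootstrap the gene weights, derive the
significant up/down gene lists, profile the component scores across
cytoarchitectonic classes, and overlap the significant genes with cell-type
marker sets. All artifacts are written to the output directory along with a
machine-readable :class:`RunReport`.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .genesets import (GeneSetCollection, overlap_frame, overlap_test, read_gmt,
                       write_gene_list)
from .io import (align, compute_delta_ct, load_expression, load_thickness,
                 standardize_genes, write_delta_ct)
from .pls import (bootstrap_gene_weights, fit_pls, permutation_test_variance,
                  select_components_cv, significant_gene_lists)
from .simulate import (SimulationConfig, default_annotation_params,
                       generate_annotations, generate_cohort,
                       generate_expression, write_simulation, GROUP_A, GROUP_B)
from .spatial import (class_enrichment, enrichment_frame, load_class_map,
                      regional_scores)
from .utils import PipelineError, ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: resampling depth per profile: "test" for fast exploratory runs and CI,
#: "paper" for publication-grade permutation and bootstrap counts
PROFILES = {"test": (1000, 200), "paper": (10000, 1000)}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and resampling depth of one pipeline run.

    Exactly one of the file-input block (`thickness`, `expression`, plus the
    optional `class_map` / `gene_sets`) or the `simulation` block must be
    given.
    """

    thickness: str | None = None
    expression: str | None = None
    class_map: str | None = None
    gene_sets: str | None = None
    simulation: SimulationConfig | None = None
    group_a: str = GROUP_A
    group_b: str = GROUP_B
    max_components: int = 35
    folds: int = 10
    profile: str = "test"
    n_perm: int | None = None
    n_boot: int | None = None
    z_threshold: float = 1.96
    q_threshold: float = 0.05
    standardize: bool = True
    min_regions: int = 10
    write_inputs: bool = True   # copy simulated inputs into outdir
    seed: int = 0
    outdir: str = "pipeline_out"

    def __post_init__(self):
        has_files = self.thickness is not None or self.expression is not None
        if has_files == (self.simulation is not None):
            raise ValidationError(
                "config must provide exactly one of input paths or a simulation block")
        if has_files and (self.thickness is None or self.expression is None):
            raise ValidationError("file inputs need both 'thickness' and 'expression'")
        if self.profile not in PROFILES:
            raise ValidationError(f"profile must be one of {sorted(PROFILES)}")
        if self.z_threshold <= 0 or self.q_threshold <= 0:
            raise ValidationError("thresholds must be positive")

    @property
    def resolved_n_perm(self) -> int:
        return int(self.n_perm) if self.n_perm is not None else PROFILES[self.profile][0]

    @property
    def resolved_n_boot(self) -> int:
        return int(self.n_boot) if self.n_boot is not None else PROFILES[self.profile][1]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        inputs = raw.pop("inputs", {})
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **inputs, **raw)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run (JSON-serializable)."""

    schema_version: int
    package_version: str
    seed: int
    profile: str
    n_perm: int
    n_boot: int
    group_a: str
    group_b: str
    n_regions: int
    n_genes: int
    selected_k: int
    y_variance_explained: list[float]
    permutation: dict
    n_up: int
    n_down: int
    up_genes: list[str]
    down_genes: list[str]
    genes: list[str]
    z: list[float]
    ve_classes: list[dict]
    celltype_overlap: list[dict]
    timing_seconds: float = 0.0

    def to_dict(self, include_timing: bool = True) -> dict:
        d = asdict(self)
        if not include_timing:
            d.pop("timing_seconds")
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _stage(name: str, hint: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc} (hint: {hint})") from exc


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis described by `config` and write all artifacts."""
    t0 = time.perf_counter()
    os.makedirs(config.outdir, exist_ok=True)
    seed = int(config.seed)
    logger.info("pipeline start: seed=%d profile=%s outdir=%s",
                seed, config.profile, config.outdir)

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        expr = _stage("simulate", "check the simulation block", generate_expression, sim)
        cohort, truth = _stage("simulate", "check the simulation block",
                               generate_cohort, expr, sim)
        collection, cmap = _stage("simulate", "check the simulation block",
                                  generate_annotations, expr, truth,
                                  seed=sim.seed,
                                  **default_annotation_params(sim))
        if config.write_inputs:
            _stage("simulate", "output directory must be writable", write_simulation,
                   config.outdir, expr, cohort, truth, collection, cmap)
        group_a, group_b = GROUP_A, GROUP_B
    else:
        cohort = _stage("load_thickness", "check the thickness TSV",
                        load_thickness, config.thickness)
        expr = _stage("load_expression", "check the expression TSV",
                      load_expression, config.expression)
        cmap = (_stage("load_class_map", "check the class map TSV",
                       load_class_map, config.class_map)
                if config.class_map else None)
        collection = None
        if config.gene_sets:
            sets = _stage("load_gene_sets", "check the GMT file", read_gmt, config.gene_sets)
            collection = GeneSetCollection.from_sets(sets, universe=set(expr.genes))
        group_a, group_b = config.group_a, config.group_b

    # --- ΔCT, standardization, alignment ---------------------------------
    dct = _stage("delta_ct", "group labels must match the thickness table",
                 compute_delta_ct, cohort, group_a, group_b)
    write_delta_ct(dct, os.path.join(config.outdir, "delta_ct.tsv"))
    if config.standardize:
        expr = _stage("standardize", "expression must have varying gene columns",
                      standardize_genes, expr)
    expr, dct = _stage("align", "expression and thickness must share region ids",
                       align, expr, dct, config.min_regions)
    X, y = expr.values, dct.values
    logger.info("aligned data: %d regions x %d genes", *X.shape)

    # --- component selection and fit --------------------------------------
    selected_k = _stage("select_components", "reduce max_components or folds",
                        select_components_cv, X, y, max_k=config.max_components,
                        folds=config.folds, seed=seed)
    model = _stage("fit", "reduce the component count", fit_pls, X, y, selected_k)
    logger.info("selected %d components; component-1 variance explained %.3f",
                selected_k, model.y_variance_explained[0])

    # --- inference on component 1 -----------------------------------------
    perm = _stage("permutation_test", "increase n_perm or check inputs",
                  permutation_test_variance, X, y, component=1,
                  n_perm=config.resolved_n_perm, seed=seed)
    table = _stage("bootstrap", "increase n_boot or check inputs",
                   bootstrap_gene_weights, X, y, expr.genes, component=1,
                   n_boot=config.resolved_n_boot, seed=seed,
                   z_threshold=config.z_threshold, q_threshold=config.q_threshold)
    up, down = significant_gene_lists(table)
    table.to_frame().to_csv(os.path.join(config.outdir, "gene_weights.tsv"),
                            sep="\t", index=False)
    write_gene_list(up, os.path.join(config.outdir, "genes_up.txt"))
    write_gene_list(down, os.path.join(config.outdir, "genes_down.txt"))
    logger.info("significant genes: %d up, %d down", len(up), len(down))

    # --- spatial class profile --------------------------------------------
    ve_rows: list[dict] = []
    if cmap is not None:
        cmap_aligned = _stage("class_profile", "class map must cover analysed regions",
                              cmap.subset, expr.regions)
        scores = regional_scores(X, model.weights[:, 0])
        ve = _stage("class_profile", "check the class map",
                    class_enrichment, scores, cmap_aligned,
                    n_perm=config.resolved_n_perm, seed=seed)
        enrichment_frame(ve).to_csv(os.path.join(config.outdir, "ve_classes.tsv"),
                                    sep="\t", index=False)
        ve_rows = enrichment_frame(ve).to_dict("records")

    # --- cell-type overlap -------------------------------------------------
    ct_rows: list[dict] = []
    if collection is not None and (up or down):
        results = _stage("celltype_overlap", "check the GMT file",
                         overlap_test, up + down, collection,
                         n_perm=config.resolved_n_perm, seed=seed)
        overlap_frame(results).to_csv(
            os.path.join(config.outdir, "celltype_overlap.tsv"), sep="\t", index=False)
        ct_rows = overlap_frame(results).to_dict("records")
    elif collection is not None:
        logger.info("no significant genes; skipping cell-type overlap test")

    report = RunReport(
        schema_version=SCHEMA_VERSION,
        package_version=__version__,
        seed=seed,
        profile=config.profile,
        n_perm=config.resolved_n_perm,
        n_boot=config.resolved_n_boot,
        group_a=group_a,
        group_b=group_b,
        n_regions=len(expr.regions),
        n_genes=len(expr.genes),
        selected_k=selected_k,
        y_variance_explained=[float(v) for v in model.y_variance_explained],
        permutation={"component": 1, "statistic": perm.statistic_observed,
                     "p": perm.p, "n_perm": perm.n_perm},
        n_up=len(up),
        n_down=len(down),
        up_genes=up,
        down_genes=down,
        genes=list(expr.genes),
        z=[float(v) for v in table.z],
        ve_classes=ve_rows,
        celltype_overlap=ct_rows,
        timing_seconds=time.perf_counter() - t0,
    )
    report.to_json(os.path.join(config.outdir, "report.json"))
    logger.info("pipeline done in %.1f s", report.timing_seconds)
    return report


def validate_run(report_a: RunReport, report_b: RunReport) -> dict:
    """Concordance summary between two runs over the same gene universe.

    Returns the Jaccard overlap of the up-gene lists, the Spearman rank
    correlation of the gene z-scores, and the fraction of cytoarchitectonic
    classes with agreeing over/under direction — the synthetic analogue of a
    discovery-versus-validation comparison.
    """
    from scipy.stats import spearmanr

    if set(report_a.genes) != set(report_b.genes):
        raise ValidationError("reports come from different gene universes")
    order_b = {g: i for i, g in enumerate(report_b.genes)}
    zb = np.array([report_b.z[order_b[g]] for g in report_a.genes])
    za = np.asarray(report_a.z)
    rho = float(spearmanr(za, zb).statistic)

    up_a, up_b = set(report_a.up_genes), set(report_b.up_genes)
    union = up_a | up_b
    jaccard = len(up_a & up_b) / len(union) if union else 1.0

    agree = None
    if report_a.ve_classes and report_b.ve_classes:
        dir_a = {row["class"]: row["direction"] for row in report_a.ve_classes}
        dir_b = {row["class"]: row["direction"] for row in report_b.ve_classes}
        shared = sorted(set(dir_a) & set(dir_b))
        if shared:
            agree = float(np.mean([dir_a[c] == dir_b[c] for c in shared]))

    return {"up_jaccard": float(jaccard), "z_rank_correlation": rho,
            "ve_direction_agreement": agree}
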