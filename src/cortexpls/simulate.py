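"""Synthetic study generator with a planted expression → thickness link.

The generator emulates the data shapes of a two-group imaging-transcriptomics
study: a region x gene expression matrix with spatially autocorrelated gene
maps, two groups of subject thickness vectors whose group-mean difference is
a linear function of expression over a sparse causal gene set plus Gaussian
subject noise, a 7-class cytoarchitectonic region map, and marker gene sets
with controlled overlap with the causal set. Because the causal genes, their
weights and the planted regional pattern are returned as ground truth, every
downstream stage of the analysis can be tested for parameter recovery and
for calibration under the global null (``n_causal = 0`` or ``effect_size = 0``).

The generative model is deliberately the estimand of a one-response PLS
regression: the planted ΔCT pattern is a single linear latent direction of
the expression matrix, ``d = standardize(E[:, causal] @ w)``, and group B
("converter" analogue) subjects lose ``effect_size * delta_scale_mm * d_r``
millimetres of thickness in region ``r``. ΔCT taken as group A minus group B
therefore tracks ``+effect_size * delta_scale_mm * d``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import ExpressionMatrix, ThicknessCohort
from .utils import ValidationError, substream

GROUP_A = "stable"
GROUP_B = "converter"

#: marker-set names used by :func:`generate_annotations` (canonical cortical
#: cell classes; purely cosmetic labels for the synthetic sets)
CELL_TYPE_NAMES = (
    "astrocytes",
    "excitatory_neurons",
    "inhibitory_neurons",
    "endothelial_cells",
    "oligodendrocytes",
    "oligodendrocyte_precursors",
    "microglia",
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard test surface: a 308-region parcellation,
    2000 genes of which 50 are causal, a 100 + 40 subject two-group design,
    an effect of 1.5 standard units of planted signal at 0.1 mm per unit,
    and 0.1 mm of subject-level thickness noise.
    """

    n_regions: int = 308
    n_genes: int = 2000
    n_subjects_a: int = 100
    n_subjects_b: int = 40
    n_causal: int = 50
    effect_size: float = 1.5          # std units of the planted ΔCT pattern
    subject_noise_sd: float = 0.1     # mm, per subject per region
    expr_spatial_rho: float = 0.3     # AR(1) region-neighbour autocorrelation
    baseline_thickness: float = 2.5   # mm
    delta_scale_mm: float = 0.1       # mm of thickness per std unit of pattern
    seed: int = 0

    def __post_init__(self):
        for name in ("n_regions", "n_genes", "n_subjects_a", "n_subjects_b"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")
            setattr(self, name, int(getattr(self, name)))
        self.n_causal = int(self.n_causal)
        if self.n_causal < 0:
            raise ValidationError("n_causal must be >= 0")
        if self.n_causal > self.n_genes:
            raise ValidationError("n_causal must not exceed n_genes")
        if not (0.0 <= self.expr_spatial_rho < 1.0):
            raise ValidationError("expr_spatial_rho must lie in [0, 1)")
        if self.subject_noise_sd < 0:
            raise ValidationError("subject_noise_sd must be >= 0")
        if self.baseline_thickness <= 0:
            raise ValidationError("baseline_thickness must be positive")
        if int(self.seed) < 0:
            raise ValidationError("seed must be a non-negative integer")
        self.seed = int(self.seed)


@dataclass
class GroundTruth:
    """Planted signal of one synthetic cohort."""

    causal_genes: list[str]
    causal_weights: dict[str, float]      # nonzero exactly on causal_genes
    planted_delta: np.ndarray             # standardized noiseless pattern, length R
    regions: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        d = {
            "causal_genes": self.causal_genes,
            "causal_weights": self.causal_weights,
            "planted_delta": dict(zip(self.regions, map(float, self.planted_delta))),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        regions = sorted(d["planted_delta"])
        return cls(
            causal_genes=list(d["causal_genes"]),
            causal_weights={k: float(v) for k, v in d["causal_weights"].items()},
            planted_delta=np.array([d["planted_delta"][r] for r in regions]),
            regions=regions,
        )


def region_ids(n: int) -> list[str]:
    return [f"R{i + 1:04d}" for i in range(n)]


def gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """Draw a region x gene matrix of spatially autocorrelated expression maps.

    Each gene is an independent AR(1) Gaussian process over the fixed region
    ordering with parameter ``expr_spatial_rho`` and unit marginal variance;
    genes are mutually independent. Deterministic for a fixed seed.
    """
    rng = substream(config.seed, "expression")
    rho = config.expr_spatial_rho
    eps = rng.standard_normal((config.n_regions, config.n_genes))
    values = np.empty_like(eps)
    values[0] = eps[0]
    innov = np.sqrt(1.0 - rho * rho)
    for r in range(1, config.n_regions):
        values[r] = rho * values[r - 1] + innov * eps[r]
    return ExpressionMatrix(regions=region_ids(config.n_regions),
                            genes=gene_ids(config.n_genes), values=values)


def generate_cohort(expr: ExpressionMatrix, config: SimulationConfig,
                    truth: GroundTruth | None = None):
    """Draw a two-group thickness cohort whose ΔCT tracks a planted pattern.

    Causal genes are drawn uniformly without replacement with N(0,1) weights;
    the planted pattern is the standardized projection of expression onto
    those weights. Group A subjects are baseline plus noise; group B subjects
    additionally lose ``effect_size * delta_scale_mm`` mm of thickness per
    standard unit of the pattern. Pass a previous run's ``truth`` to redraw
    only the subject noise while keeping the causal gene set and weights
    (the synthetic analogue of an independent validation cohort).

    Returns ``(ThicknessCohort, GroundTruth)``.
    """
    R, G = expr.values.shape
    if R != config.n_regions:
        raise ValidationError("expression region count must equal config.n_regions")
    rng = substream(config.seed, "cohort")

    if truth is None:
        if config.n_causal > G:
            raise ValidationError("n_causal must not exceed the gene count")
        causal_idx = np.sort(rng.choice(G, size=config.n_causal, replace=False))
        w = rng.standard_normal(config.n_causal)
        if config.n_causal > 0:
            d_raw = expr.values[:, causal_idx] @ w
            d = (d_raw - d_raw.mean()) / d_raw.std(ddof=1)
        else:
            d = np.zeros(R)
        causal_genes = [expr.genes[i] for i in causal_idx]
        truth = GroundTruth(
            causal_genes=causal_genes,
            causal_weights=dict(zip(causal_genes, map(float, w))),
            planted_delta=d,
            regions=list(expr.regions),
        )
    else:
        # keep the planted signal, spend this stream's draws on fresh noise only
        if list(truth.regions) != list(expr.regions):
            raise ValidationError("ground truth regions do not match the expression matrix")
        d = np.asarray(truth.planted_delta, dtype=float)

    na, nb = config.n_subjects_a, config.n_subjects_b
    noise = config.subject_noise_sd * rng.standard_normal((na + nb, R))
    values = np.empty((na + nb, R))
    values[:na] = config.baseline_thickness + noise[:na]
    decrement = config.effect_size * config.delta_scale_mm * d
    values[na:] = config.baseline_thickness - decrement + noise[na:]

    cohort = ThicknessCohort(
        subject_ids=[f"S{i + 1:04d}" for i in range(na + nb)],
        group_labels=[GROUP_A] * na + [GROUP_B] * nb,
        regions=list(expr.regions),
        values=values,
    )
    return cohort, truth


def generate_annotations(expr: ExpressionMatrix, truth: GroundTruth,
                         n_sets: int = 7, set_size: int = 100,
                         causal_overlap_frac: float = 0.5, seed: int = 0):
    """Draw marker gene sets and a 7-class region map for enrichment testing.

    The first set contains ``round(causal_overlap_frac * set_size)`` causal
    genes (its planted enrichment); all other members and all other sets are
    drawn uniformly from non-causal genes. The region map partitions the
    region ordering into 7 contiguous classes of near-equal size.

    Returns ``(GeneSetCollection, ClassMap)``.
    """
    from .genesets import GeneSetCollection
    from .spatial import ClassMap

    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    if set_size < 1 or set_size > len(expr.genes):
        raise ValidationError("set_size must lie in [1, n_genes]")
    if not (0.0 <= causal_overlap_frac <= 1.0):
        raise ValidationError("causal_overlap_frac must lie in [0, 1]")

    rng = substream(seed, "annotations")
    causal = np.array(sorted(truth.causal_genes))
    noncausal = np.array(sorted(set(expr.genes) - set(truth.causal_genes)))
    n_overlap = int(np.rint(causal_overlap_frac * set_size))
    if n_overlap > causal.size:
        raise ValidationError(
            f"requested overlap ({n_overlap}) exceeds available causal genes ({causal.size})")
    if set_size - n_overlap > noncausal.size or (n_sets > 1 and set_size > noncausal.size):
        raise ValidationError("not enough non-causal genes for the requested sets")

    sets: dict[str, set[str]] = {}
    names = [CELL_TYPE_NAMES[i] if i < len(CELL_TYPE_NAMES) else f"set_{i + 1:02d}"
             for i in range(n_sets)]
    first = set(rng.choice(causal, size=n_overlap, replace=False)) if n_overlap else set()
    first |= set(rng.choice(noncausal, size=set_size - n_overlap, replace=False))
    sets[names[0]] = first
    for name in names[1:]:
        sets[name] = set(rng.choice(noncausal, size=set_size, replace=False))

    collection = GeneSetCollection.from_sets(sets, universe=set(expr.genes))

    n_classes = 7
    labels = np.empty(len(expr.regions), dtype=int)
    for c, chunk in enumerate(np.array_split(np.arange(len(expr.regions)), n_classes)):
        labels[chunk] = c + 1
    class_map = ClassMap(regions=list(expr.regions), labels=labels)
    return collection, class_map


def default_annotation_params(config: SimulationConfig) -> dict:
    """Feasible marker-set sizing for a given simulation scale.

    Sets hold ~5% of the gene pool (capped at 100 genes) and the first set's
    causal overlap targets half its size, capped by the causal genes available.
    """
    set_size = max(1, min(100, config.n_genes // 10))
    n_overlap = min(set_size // 2, config.n_causal)
    return {"set_size": set_size, "causal_overlap_frac": n_overlap / set_size}


def write_simulation(outdir, expr: ExpressionMatrix, cohort: ThicknessCohort,
                     truth: GroundTruth, collection=None, class_map=None) -> None:
    """Write all generated artifacts to `outdir` in their interchange formats."""
    import os

    from .genesets import write_gmt
    from .io import write_expression, write_thickness
    from .spatial import write_class_map

    os.makedirs(outdir, exist_ok=True)
    write_expression(expr, os.path.join(outdir, "expression.tsv"))
    write_thickness(cohort, os.path.join(outdir, "thickness.tsv"))
    truth.to_json(os.path.join(outdir, "ground_truth.json"))
    if collection is not None:
        write_gmt(collection.sets, os.path.join(outdir, "gene_sets.gmt"))
    if class_map is not None:
        write_class_map(class_map, os.path.join(outdir, "class_map.tsv"))
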