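"""Readers, validators and core transforms for thickness and expression tables.

The two imaging-side inputs are plain TSV tables:

* a thickness cohort — one row per subject with a group label and one column
  of mean cortical thickness (mm) per parcellation region, and
* a region x gene expression matrix — one row per region, one column per gene.

This module turns them into validated in-memory containers, computes the
per-region group difference in mean cortical thickness (ΔCT), z-scores gene
columns for regression, and aligns the two data sources on shared region ids.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ThicknessCohort:
    """Subject x region cortical-thickness matrix with a two-level group label."""

    subject_ids: list[str]
    group_labels: list[str]
    regions: list[str]
    values: np.ndarray  # subjects x regions, millimetres

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("thickness values must be a 2-D subjects x regions array")
        n, r = self.values.shape
        if len(self.subject_ids) != n or len(self.group_labels) != n:
            raise ValidationError("subject ids and group labels must match value rows")
        if len(self.regions) != r:
            raise ValidationError("region ids must match value columns")
        if len(set(self.regions)) != r:
            raise ValidationError("region ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("thickness values must be finite (no missing cells)")
        if np.any(self.values <= 0):
            raise ValidationError("thickness values must be positive")
        if len(set(self.group_labels)) != 2:
            raise ValidationError("exactly two groups required")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_labels))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class DeltaCT:
    """Per-region difference of group-mean cortical thickness (group_a - group_b)."""

    regions: list[str]
    values: np.ndarray  # length R, millimetres
    group_a: str
    group_b: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.regions) != self.values.size:
            raise ValidationError("ΔCT length must match region ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ΔCT values must be finite")


@dataclass
class ExpressionMatrix:
    """Region x gene expression matrix (raw units, or z-units after standardization)."""

    regions: list[str]
    genes: list[str]
    values: np.ndarray  # R x G

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D region x gene array")
        r, g = self.values.shape
        if len(self.regions) != r:
            raise ValidationError("region ids must match value rows")
        if len(self.genes) != g:
            raise ValidationError("gene ids must match value columns")
        if len(set(self.regions)) != r:
            raise ValidationError("region ids must be unique")
        if len(set(self.genes)) != g:
            raise ValidationError("gene ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite (no missing cells)")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_thickness(path) -> ThicknessCohort:
    """Read a thickness cohort TSV (columns: subject_id, group, one per region)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("subject_id", "group"):
        if col not in raw.columns:
            raise ValidationError(f"thickness table must have a '{col}' column")
    region_cols = [c for c in raw.columns if c not in ("subject_id", "group")]
    if not region_cols:
        raise ValidationError("thickness table has no region columns")
    block = raw[region_cols]
    numeric = block.apply(pd.to_numeric, errors="coerce")

    missing = block.isna()
    if missing.to_numpy().any():
        cells = _offending_cells(raw, missing)
        raise ValidationError(f"missing thickness values at: {cells}")
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        cells = _offending_cells(raw, bad)
        raise ValidationError(f"non-numeric thickness values at: {cells}")

    return ThicknessCohort(
        subject_ids=raw["subject_id"].tolist(),
        group_labels=raw["group"].tolist(),
        regions=region_cols,
        values=numeric.to_numpy(dtype=float),
    )


def _offending_cells(raw: pd.DataFrame, mask: pd.DataFrame, limit: int = 10) -> str:
    cells = []
    rows, cols = np.nonzero(mask.to_numpy())
    for i, j in zip(rows[:limit], cols[:limit]):
        cells.append(f"(subject {raw['subject_id'].iloc[i]}, region {mask.columns[j]})")
    suffix = "" if len(rows) <= limit else f" and {len(rows) - limit} more"
    return ", ".join(cells) + suffix


def write_thickness(cohort: ThicknessCohort, path) -> None:
    df = pd.DataFrame(cohort.values, columns=cohort.regions)
    df.insert(0, "group", cohort.group_labels)
    df.insert(0, "subject_id", cohort.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def load_expression(path) -> ExpressionMatrix:
    """Read a region x gene expression TSV (first column region_id)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "region_id":
        raise ValidationError("expression table must start with a 'region_id' column")
    genes = df.columns[1:].tolist()
    values = df[genes].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return ExpressionMatrix(regions=df["region_id"].astype(str).tolist(), genes=genes, values=values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.genes)
    df.insert(0, "region_id", expr.regions)
    df.to_csv(path, sep="\t", index=False)


def load_delta_ct(path) -> DeltaCT:
    """Read a ΔCT TSV written by :func:`write_delta_ct` ('#'-comment header)."""
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return DeltaCT(
        regions=df["region_id"].astype(str).tolist(),
        values=df["delta_ct"].to_numpy(dtype=float),
        group_a=meta.get("group_a", "group_a"),
        group_b=meta.get("group_b", "group_b"),
    )


def write_delta_ct(dct: DeltaCT, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# group_a={dct.group_a}\n# group_b={dct.group_b}\n")
        fh.write("region_id\tdelta_ct\n")
        for r, v in zip(dct.regions, dct.values):
            fh.write(f"{r}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def compute_delta_ct(cohort: ThicknessCohort, group_a: str, group_b: str) -> DeltaCT:
    """Per-region mean thickness of `group_a` minus mean thickness of `group_b`.

    Orientation follows the stable-minus-converter convention: with the
    stable group as `group_a`, positive ΔCT means the region is thinner in
    converters.
    """
    labels = np.asarray(cohort.group_labels)
    for g in (group_a, group_b):
        if g not in labels:
            raise ValidationError(f"unknown group label: {g!r}")
    if group_a == group_b:
        raise ValidationError("group_a and group_b must differ")
    mean_a = cohort.values[labels == group_a].mean(axis=0)
    mean_b = cohort.values[labels == group_b].mean(axis=0)
    return DeltaCT(regions=list(cohort.regions), values=mean_a - mean_b,
                   group_a=group_a, group_b=group_b)


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene column across regions (sample, n-1, variance).

    Zero-variance genes cannot carry regional signal and are dropped with a
    logged warning. Raises if no gene survives.
    """
    v = expr.values
    if v.shape[0] < 2:
        raise ValidationError("standardization needs at least two regions")
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    keep = sd > 1e-12
    n_dropped = int((~keep).sum())
    if n_dropped == v.shape[1]:
        raise ValidationError("all gene columns have zero variance")
    if n_dropped:
        logger.warning("dropping %d zero-variance gene column(s)", n_dropped)
    z = (v[:, keep] - mean[keep]) / sd[keep]
    genes = [g for g, k in zip(expr.genes, keep) if k]
    return ExpressionMatrix(regions=list(expr.regions), genes=genes, values=z)


def align(expr: ExpressionMatrix, dct: DeltaCT, min_regions: int = 10):
    """Reorder both inputs to the sorted intersection of their region ids.

    Alignment is by id, never by position, so a misordered imaging table can
    not silently be regressed against the wrong expression rows. Inputs that
    already share an identical ordered region list are returned unchanged.
    """
    if expr.regions == dct.regions:
        return expr, dct
    common = sorted(set(expr.regions) & set(dct.regions))
    if not common:
        raise ValidationError("expression and ΔCT share no region ids")
    if len(common) < min_regions:
        raise ValidationError(
            f"only {len(common)} shared region(s); at least {min_regions} required")
    e_idx = {r: i for i, r in enumerate(expr.regions)}
    d_idx = {r: i for i, r in enumerate(dct.regions)}
    e_rows = [e_idx[r] for r in common]
    d_rows = [d_idx[r] for r in common]
    expr_out = ExpressionMatrix(regions=common, genes=list(expr.genes),
                                values=expr.values[e_rows])
    dct_out = DeltaCT(regions=common, values=dct.values[d_rows],
                      group_a=dct.group_a, group_b=dct.group_b)
    return expr_out, dct_out
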