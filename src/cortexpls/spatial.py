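"""Cytoarchitectonic class profiling of component region scores.

Regions are grouped into Von Economo-style classes (five cytoarchitectonic
types plus limbic and insular subtypes by default, seven in total, but the
class count follows the map file so other atlases work). For a component's
regional score map, each class's mean score is tested against a null built
by permuting the region-to-class assignment: classes whose member regions
score higher than chance are "over"-expressed for that component, lower
scoring classes "under"-expressed. p-values are two-sided with add-one
smoothing and Benjamini-Hochberg corrected across classes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import fdr_bh
from .utils import ValidationError, substream

logger = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = {
    1: "primary motor",
    2: "association",
    3: "association 2",
    4: "secondary sensory",
    5: "primary sensory",
    6: "limbic",
    7: "insular",
}


@dataclass
class ClassMap:
    """Region-to-class assignment (integer labels, optional display names)."""

    regions: list[str]
    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.regions) != self.labels.size:
            raise ValidationError("class labels must match region ids")
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("region ids must be unique")
        present = np.unique(self.labels)
        if present.size < 2:
            raise ValidationError("class map must contain at least two classes")
        for lab in present:
            self.names.setdefault(int(lab), DEFAULT_CLASS_NAMES.get(int(lab), f"class {lab}"))

    def subset(self, regions: list[str]) -> "ClassMap":
        """Restrict the map to `regions` (in that order); all must be present."""
        idx = {r: i for i, r in enumerate(self.regions)}
        missing = [r for r in regions if r not in idx]
        if missing:
            raise ValidationError(
                f"{len(missing)} region(s) missing from class map, e.g. {missing[:3]}")
        rows = [idx[r] for r in regions]
        return ClassMap(regions=list(regions), labels=self.labels[rows], names=dict(self.names))


@dataclass
class ClassEnrichment:
    """Permutation-test outcome for one class."""

    class_label: int
    class_name: str
    n_regions_in_class: int
    mean_score: float
    direction: str      # "over" | "under"
    p_perm: float
    q: float


def load_class_map(path) -> ClassMap:
    df = pd.read_csv(path, sep="\t")
    if not {"region_id", "class_label"}.issubset(df.columns):
        raise ValidationError("class map needs 'region_id' and 'class_label' columns")
    names = {}
    if "class_name" in df.columns:
        names = {int(l): str(n) for l, n in zip(df["class_label"], df["class_name"])}
    return ClassMap(regions=df["region_id"].astype(str).tolist(),
                    labels=df["class_label"].to_numpy(dtype=int), names=names)


def write_class_map(class_map: ClassMap, path) -> None:
    df = pd.DataFrame({
        "region_id": class_map.regions,
        "class_label": class_map.labels,
        "class_name": [class_map.names[int(l)] for l in class_map.labels],
    })
    df.to_csv(path, sep="\t", index=False)


def regional_scores(X, weights) -> np.ndarray:
    """Project standardized expression onto a gene weight vector, mean-centered.

    ``score_r = sum_g X[r, g] * w[g]``, then centered across regions; this is
    the regional score map of the component defined by `weights`.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ValidationError("weight length must match the gene dimension of X")
    s = X @ w
    return s - s.mean()


def class_enrichment(scores, class_map: ClassMap, n_perm: int = 10000,
                     seed: int = 0) -> list[ClassEnrichment]:
    """Test each class's mean component score against a region-permutation null.

    `scores` must be aligned with ``class_map.regions``. The statistic per
    class is the mean score of its member regions; the null permutes the
    region-to-class assignment `n_perm` times (all classes share each
    permutation). p-values are two-sided around zero — scores are centered,
    so the permutation expectation of every class mean is exactly zero — with
    add-one smoothing; direction is "over" when the observed mean exceeds the
    null median. q-values are BH-adjusted across classes.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if s.size != len(class_map.regions):
        raise ValidationError("scores and class map must cover identical regions")
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    s = s - s.mean()
    R = s.size
    labels = class_map.labels
    classes = np.unique(labels)
    members = {int(c): np.flatnonzero(labels == c) for c in classes}
    for c, m in members.items():
        if m.size < 2:
            logger.warning("class %d has fewer than 2 regions; testing anyway", c)

    rng = substream(seed, "class_perm")
    null = np.empty((n_perm, classes.size))
    block = 512
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm_scores = np.stack([s[rng.permutation(R)] for _ in range(b)])
        for j, c in enumerate(classes):
            null[done:done + b, j] = perm_scores[:, members[int(c)]].mean(axis=1)
        done += b

    observed = np.array([s[members[int(c)]].mean() for c in classes])
    p = np.empty(classes.size)
    direction = []
    for j, c in enumerate(classes):
        p[j] = (1.0 + np.count_nonzero(np.abs(null[:, j]) >= abs(observed[j]))) / (n_perm + 1.0)
        direction.append("over" if observed[j] > np.median(null[:, j]) else "under")
    q = fdr_bh(p)

    return [
        ClassEnrichment(class_label=int(c), class_name=class_map.names[int(c)],
                        n_regions_in_class=int(members[int(c)].size),
                        mean_score=float(observed[j]), direction=direction[j],
                        p_perm=float(p[j]), q=float(q[j]))
        for j, c in enumerate(classes)
    ]


def enrichment_frame(results: list[ClassEnrichment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "class": r.class_label,
        "name": r.class_name,
        "n_regions": r.n_regions_in_class,
        "mean_score": r.mean_score,
        "direction": r.direction,
        "p": r.p_perm,
        "q": r.q,
    } for r in results])
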