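"""Shared helpers: validation errors, seeded RNG substreams, permutation p-values."""
from __future__ import annotations

import numpy as np


class ValidationError(ValueError):
    """Raised when an input table, argument or configuration violates its contract."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message carries the stage name."""


# Fixed per-stage tags so one user-facing integer seed expands into
# independent streams for each stochastic stage of the analysis.
_STAGE_IDS = {
    "expression": 11,
    "cohort": 23,
    "annotations": 37,
    "cv": 41,
    "permutation": 53,
    "bootstrap": 67,
    "class_perm": 71,
    "overlap": 83,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return an RNG for a named analysis stage derived from a single integer seed.

    Streams for different stages are statistically independent, so the same
    seed can safely be passed to every stage of a run.
    """
    if seed is None:
        seed = 0
    seed = int(seed)
    if seed < 0:
        raise ValidationError("seed must be a non-negative integer")
    try:
        tag = _STAGE_IDS[stage]
    except KeyError:  # pragma: no cover - internal misuse
        raise ValidationError(f"unknown RNG stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def permutation_pvalue(observed: float, null_values) -> float:
    """Add-one smoothed permutation p-value, (1 + #{null >= observed}) / (n + 1).

    Ties count as at-least-as-extreme, so the p-value is never zero and a
    statistic equal to every null value yields exactly 1.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    return float(1.0 + np.count_nonzero(null >= observed)) / (null.size + 1.0)


def rank_auc(scores, positive_mask) -> float:
    """Area under the ROC curve of `scores` for retrieving `positive_mask` items.

    Computed from the Mann-Whitney rank statistic; ties share midranks.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
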