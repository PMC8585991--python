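"""One-response partial least squares regression with resampling inference.

This is the statistical core of the package. Given a column-standardized
region x gene expression matrix ``X`` (R x G, typically G >> R) and a length-R
response ``y`` of per-region cortical-thickness differences, it provides:

* :func:`fit_pls` — PLS1 (single response, NIPALS with X-deflation only).
  The first component has a closed form: its weight vector is proportional
  to ``X.T @ (y - mean(y))``, the gene-wise covariance with ΔCT. Subsequent
  components repeat the same step on the deflated predictor block.
* :func:`select_components_cv` — k-fold cross-validation over regions with
  the minimum-mean-squared-error rule for choosing the component count.
* :func:`permutation_test_variance` — significance of the fraction of
  response variance a component explains, against refits on y with region
  labels permuted.
* :func:`bootstrap_gene_weights` — per-gene z-scores (weight over bootstrap
  standard error across region resamples), two-sided normal p-values,
  Benjamini-Hochberg q-values and up/down significance calls.

Sign convention: every component's score column is oriented to correlate
non-negatively with y, so "positive weight" consistently means "higher
expression where ΔCT is larger".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .utils import ValidationError, permutation_pvalue, substream

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    ``weights`` columns are unit-norm gene weight vectors, one per component;
    ``scores`` are the corresponding orthogonal region-score columns;
    ``y_variance_explained[k]`` is the incremental R² of y gained by adding
    score k to the regression on the earlier scores (entries sum to at most 1).
    """

    weights: np.ndarray             # G x K, unit-norm columns
    scores: np.ndarray              # R x K, mutually orthogonal
    x_loadings: np.ndarray          # G x K
    y_loadings: np.ndarray          # K
    y_variance_explained: np.ndarray  # K, fractions in [0, 1]
    n_components: int
    y_mean: float
    sign_convention: bool = True    # scores oriented to corr(score, y) >= 0

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Regression coefficient vector of the first `k` components."""
        k = self.n_components if k is None else int(k)
        W, P, q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients(k) + self.y_mean


@dataclass
class GeneWeightTable:
    """Bootstrap-standardized gene weights for one component."""

    genes: list[str]
    raw_weight: np.ndarray
    boot_se: np.ndarray
    z: np.ndarray                 # raw_weight / boot_se
    p: np.ndarray                 # two-sided normal tail
    q: np.ndarray                 # Benjamini-Hochberg across all genes
    significant_up: np.ndarray    # z > +z_threshold and q < q_threshold
    significant_down: np.ndarray
    component: int = 1
    n_boot: int = 0
    z_threshold: float = 1.96
    q_threshold: float = 0.05

    def to_frame(self):
        import pandas as pd

        direction = np.where(self.significant_up, "up",
                             np.where(self.significant_down, "down", "ns"))
        return pd.DataFrame({
            "gene": self.genes,
            "weight": self.raw_weight,
            "se": self.boot_se,
            "z": self.z,
            "p": self.p,
            "q": self.q,
            "direction": direction,
        })


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and add-one smoothed p-value."""

    statistic_observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    seed: int
    component: int = 1


# ---------------------------------------------------------------------------
# core fit
# ---------------------------------------------------------------------------

def _pls1_core(X: np.ndarray, y: np.ndarray, k: int):
    """NIPALS PLS1 with X-deflation. Returns (W, T, P, q, var_exp, achieved).

    `achieved` may be less than `k` if the deflated predictor block runs out
    of rank; callers decide whether that is an error. y is centered here;
    X is used as passed (callers standardize or at least center columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    R, G = X.shape
    if y.size != R:
        raise ValidationError("X rows and y length must agree")
    y_c = y - y.mean()
    yy = float(y_c @ y_c)
    if yy <= _RANK_TOL:
        raise ValidationError("y is constant; PLS response must vary")

    Xd = X.copy()
    scale0 = max(np.abs(Xd).max(), 1.0)
    W = np.zeros((G, k))
    T = np.zeros((R, k))
    P = np.zeros((G, k))
    q = np.zeros(k)
    var_exp = np.zeros(k)
    achieved = 0
    for j in range(k):
        w = Xd.T @ y_c
        nw = float(np.linalg.norm(w))
        if nw <= _RANK_TOL * scale0:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * scale0) ** 2:
            break
        # with w ∝ Xd.T y and X-only deflation, t·y = ||Xd.T y|| >= 0, so the
        # positive-correlation orientation holds by construction
        p = (Xd.T @ t) / tt
        qj = float(y_c @ t) / tt
        Xd -= np.outer(t, p)
        W[:, j], T[:, j], P[:, j], q[j] = w, t, p, qj
        var_exp[j] = qj * qj * tt / yy  # scores orthogonal => R² increments add
        achieved = j + 1
    return W[:, :achieved], T[:, :achieved], P[:, :achieved], q[:achieved], \
        var_exp[:achieved], achieved


def fit_pls(X, y, k: int) -> PLSModel:
    """Fit a `k`-component PLS1 model of y on column-standardized X.

    Raises if y is constant, if fewer than ``k + 1`` regions are available,
    or if `k` exceeds the effective rank of X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    k = int(k)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if X.shape[0] < k + 1:
        raise ValidationError("need at least k + 1 regions to fit k components")
    W, T, P, q, var_exp, achieved = _pls1_core(X, y, k)
    if achieved < k:
        raise ValidationError(
            f"k={k} exceeds the effective rank of X (got {achieved} components)")
    return PLSModel(weights=W, scores=T, x_loadings=P, y_loadings=q,
                    y_variance_explained=var_exp, n_components=k,
                    y_mean=float(y.mean()))


# ---------------------------------------------------------------------------
# component selection
# ---------------------------------------------------------------------------

def select_components_cv(X, y, max_k: int = 35, folds: int = 10, seed: int = 0) -> int:
    """Choose the component count by k-fold cross-validation over regions.

    Regions are partitioned into `folds` folds fixed by `seed`; for each fold
    a ``max_k``-component model is fitted on the remaining regions and the
    held-out squared prediction error is accumulated for every truncation
    ``1..max_k``. Returns the argmin of the mean out-of-fold error, with ties
    broken toward the smaller component count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    R = X.shape[0]
    if folds < 2 or folds > R:
        raise ValidationError("folds must lie in [2, n_regions]")
    max_k = int(max_k)
    largest_fold = int(np.ceil(R / folds))
    if max_k >= R - largest_fold:
        raise ValidationError(
            f"max_k={max_k} is unfittable with {R} regions in {folds} folds")
    rng = substream(seed, "cv")
    order = rng.permutation(R)
    sse = np.zeros(max_k)
    for test_idx in np.array_split(order, folds):
        mask = np.ones(R, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        xm = Xtr.mean(axis=0)
        ym = float(ytr.mean())
        W, T, P, q, _, achieved = _pls1_core(Xtr - xm, ytr, max_k)
        Xte = X[test_idx] - xm
        for k in range(1, max_k + 1):
            kk = min(k, achieved)
            B = W[:, :kk] @ np.linalg.solve(P[:, :kk].T @ W[:, :kk], q[:kk])
            resid = y[test_idx] - (Xte @ B + ym)
            sse[k - 1] += float(resid @ resid)
    mean_err = sse / R
    return int(np.argmin(mean_err)) + 1


# ---------------------------------------------------------------------------
# permutation test of variance explained
# ---------------------------------------------------------------------------

def permutation_test_variance(X, y, component: int = 1, n_perm: int = 10000,
                              seed: int = 0, _force_loop: bool = False) -> PermutationResult:
    """Permutation significance of the y-variance a component explains.

    The statistic is ``y_variance_explained[component]`` of the fitted model;
    the null refits the model after permuting y across regions, destroying
    the region-to-region correspondence between thickness differences and
    expression while preserving the marginal distribution of both blocks.
    p-values use add-one smoothing and are never zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    component = int(component)
    if component < 1:
        raise ValidationError("component must be >= 1")
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-value resolution is %.3f",
                       n_perm, 1.0 / (n_perm + 1))

    model = fit_pls(X, y, component)
    observed = float(model.y_variance_explained[component - 1])
    rng = substream(seed, "permutation")
    R = y.size
    null = np.empty(n_perm)

    if component == 1 and not _force_loop:
        # closed form for the first component: with w ∝ X.T y_c and t = X w,
        # R² = (t·y_c)² / (||t||²·||y_c||²) = ||g||⁴ / (||Xg||²·||y_c||²)
        # where g = X.T y_c — vectorizable across permutations.
        y_c = y - y.mean()
        yy = float(y_c @ y_c)
        block = 256
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            Yp = np.stack([y_c[rng.permutation(R)] for _ in range(b)], axis=1)
            Gm = X.T @ Yp
            gn2 = np.einsum("ij,ij->j", Gm, Gm)
            H = X @ Gm
            hn2 = np.einsum("ij,ij->j", H, H)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(hn2 > 0, gn2 * gn2 / (hn2 * yy), 0.0)
            null[done:done + b] = r2
            done += b
    else:
        for i in range(n_perm):
            yp = y[rng.permutation(R)]
            *_, var_exp, achieved = _pls1_core(X, yp, component)
            null[i] = var_exp[component - 1] if achieved >= component else 0.0

    p = permutation_pvalue(observed, null)
    return PermutationResult(statistic_observed=observed, null_values=null,
                             p=p, n_perm=n_perm, seed=int(seed), component=component)


# ---------------------------------------------------------------------------
# bootstrap gene weights
# ---------------------------------------------------------------------------

def bootstrap_gene_weights(X, y, genes, component: int = 1, n_boot: int = 1000,
                           seed: int = 0, z_threshold: float = 1.96,
                           q_threshold: float = 0.05) -> GeneWeightTable:
    """Bootstrap-standardize the gene weights of one component.

    Regions are resampled with replacement `n_boot` times and the model is
    refitted on each resample (resampled gene columns re-centered, response
    re-centered). Each bootstrap weight vector is aligned to the original
    component by its scalar projection, i.e. divided by ``w_b . w_orig``.
    This corrects reflection (the sign flip a naive resample can undergo)
    and, crucially, the systematic attenuation that unit-norm weight vectors
    suffer when genes far outnumber regions: the bootstrap norm absorbs
    roughly twice the noise mass of the original fit, which uniformly shrinks
    every bootstrap coordinate by the cosine between the two directions and
    would otherwise understate the standard errors and inflate every z-score.
    After alignment, ``z = weight / bootstrap SE`` with two-sided normal
    tails and BH q-values across all genes. A gene is called up (down) when
    its z exceeds ``+z_threshold`` (falls below -z_threshold) *and*
    q < `q_threshold`. Degenerate resamples (constant response, or a weight
    vector essentially orthogonal to the original component) are redrawn and
    logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    component = int(component)
    n_boot = int(n_boot)
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if len(genes) != X.shape[1]:
        raise ValidationError("gene ids must match X columns")

    model = fit_pls(X, y, component)
    w0 = model.weights[:, component - 1]
    rng = substream(seed, "bootstrap")
    R, G = X.shape
    boot = np.empty((n_boot, G))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, R, size=R)
        yb = y[idx]
        if float(np.ptp(yb)) <= _RANK_TOL:
            redraws += 1
            continue
        Xb = X[idx]
        Xb = Xb - Xb.mean(axis=0)
        W, *_rest, achieved = _pls1_core(Xb, yb, component)
        if achieved < component:
            redraws += 1
            continue
        wb = W[:, component - 1]
        c = float(wb @ w0)
        if abs(c) < 1e-3:  # no meaningful alignment possible; redraw
            redraws += 1
            continue
        boot[b] = wb / c
        b += 1
    if redraws:
        logger.warning("redrew %d degenerate bootstrap resample(s)", redraws)

    boot_se = boot.std(axis=0, ddof=1)
    safe_se = np.where(boot_se > 0, boot_se, np.finfo(float).tiny)
    z = w0 / safe_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = fdr_bh(p)
    sig_up = (z > z_threshold) & (q < q_threshold)
    sig_down = (z < -z_threshold) & (q < q_threshold)
    return GeneWeightTable(genes=list(genes), raw_weight=w0.copy(), boot_se=boot_se,
                           z=z, p=p, q=q, significant_up=sig_up,
                           significant_down=sig_down, component=component,
                           n_boot=n_boot, z_threshold=z_threshold,
                           q_threshold=q_threshold)


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def significant_gene_lists(table: GeneWeightTable):
    """Split a gene weight table into (up, down) significant lists, |z|-sorted."""
    order = np.argsort(-np.abs(table.z), kind="stable")
    up = [table.genes[i] for i in order if table.significant_up[i]]
    down = [table.genes[i] for i in order if table.significant_down[i]]
    return up, down
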