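"""Gene-set overlap testing: permutation and exact hypergeometric variants.

Used for two purposes downstream of the regression:

* cell-type assignment — the significant component-1 gene list is overlapped
  with marker sets of the seven canonical cortical cell classes (astrocytes,
  excitatory/inhibitory neurons, endothelial cells, oligodendrocytes and
  their precursors, microglia), with a permutation p-value on the overlap
  count per set; and
* over-representation analysis (ORA) against arbitrary GMT annotation sets
  with the exact upper-tail hypergeometric test.

The permutation null draws lists of the same size uniformly without
replacement from the gene universe, which is exactly the hypergeometric
sampling model, so the two p-values agree up to Monte-Carlo error; both are
reported. The universe defaults to the genes of the analyzed expression
matrix — the frame the regression actually searched — not the whole genome.
Tests are one-sided for enrichment; depletion is not assessed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pls import fdr_bh
from .utils import ValidationError, permutation_pvalue, substream

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a common universe."""

    sets: dict[str, set]
    universe: set

    @classmethod
    def from_sets(cls, sets: dict, universe) -> "GeneSetCollection":
        universe = set(universe)
        restricted = {}
        for name, genes in sets.items():
            genes = set(genes)
            inside = genes & universe
            dropped = len(genes) - len(inside)
            if dropped:
                logger.warning("set %r: dropped %d gene(s) outside the universe",
                               name, dropped)
            if not inside:
                logger.warning("set %r is empty after universe restriction; skipped", name)
                continue
            restricted[name] = inside
        if not restricted:
            raise ValidationError("no gene set survives universe restriction")
        return cls(sets=restricted, universe=universe)


@dataclass
class OverlapResult:
    """Overlap of a gene list with one set, with permutation and exact p-values."""

    set_name: str
    n_overlap: int
    n_list: int
    n_set: int
    n_universe: int
    p_perm: float | None
    p_hypergeom: float
    q: float
    n_perm: int = 0


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file (set name, description, tab-separated gene ids)."""
    sets: dict[str, set] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if not sets:
        raise ValidationError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def _prepare_list(gene_list, universe: set) -> list:
    genes = list(dict.fromkeys(gene_list))  # dedupe, keep order
    inside = [g for g in genes if g in universe]
    dropped = len(genes) - len(inside)
    if dropped:
        logger.warning("gene list: dropped %d gene(s) outside the universe", dropped)
    if not inside:
        raise ValidationError("gene list is empty after universe restriction")
    return inside


def overlap_test(gene_list, collection: GeneSetCollection, n_perm: int = 10000,
                 seed: int = 0) -> list[OverlapResult]:
    """Permutation test of the overlap count between a gene list and each set.

    The null redraws a list of the same size uniformly without replacement
    from the universe `n_perm` times; ``p_perm`` is add-one smoothed on the
    upper tail of the overlap count. The exact hypergeometric upper-tail
    probability is reported alongside. q-values are BH across sets on the
    permutation p-values.
    """
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    genes = _prepare_list(gene_list, collection.universe)
    universe = np.array(sorted(collection.universe))
    M = universe.size
    n_list = len(genes)
    names = list(collection.sets)

    masks = np.zeros((len(names), M), dtype=bool)
    pos = {g: i for i, g in enumerate(universe)}
    for s, name in enumerate(names):
        masks[s, [pos[g] for g in collection.sets[name]]] = True
    list_idx = np.array([pos[g] for g in genes])
    observed = masks[:, list_idx].sum(axis=1)

    rng = substream(seed, "overlap")
    null = np.empty((n_perm, len(names)), dtype=np.int64)
    for i in range(n_perm):
        draw = rng.permutation(M)[:n_list]
        null[i] = masks[:, draw].sum(axis=1)

    p_perm = np.array([permutation_pvalue(observed[s], null[:, s])
                       for s in range(len(names))])
    q = fdr_bh(p_perm)
    results = []
    for s, name in enumerate(names):
        n_set = len(collection.sets[name])
        results.append(OverlapResult(
            set_name=name, n_overlap=int(observed[s]), n_list=n_list,
            n_set=n_set, n_universe=M, p_perm=float(p_perm[s]),
            p_hypergeom=float(hypergeom.sf(observed[s] - 1, M, n_set, n_list)),
            q=float(q[s]), n_perm=n_perm))
    return results


def ora(gene_list, annotations: GeneSetCollection) -> list[OverlapResult]:
    """Exact hypergeometric over-representation analysis against GMT sets.

    Returns one result per annotation set, BH-corrected across sets and
    sorted by ascending p (name as tie-break).
    """
    genes = _prepare_list(gene_list, annotations.universe)
    gene_set = set(genes)
    M = len(annotations.universe)
    n_list = len(genes)
    names = list(annotations.sets)
    p = np.empty(len(names))
    overlaps = np.empty(len(names), dtype=int)
    for s, name in enumerate(names):
        members = annotations.sets[name]
        overlaps[s] = len(gene_set & members)
        p[s] = hypergeom.sf(overlaps[s] - 1, M, len(members), n_list)
    q = fdr_bh(p)
    results = [OverlapResult(set_name=name, n_overlap=int(overlaps[s]),
                             n_list=n_list, n_set=len(annotations.sets[name]),
                             n_universe=M, p_perm=None,
                             p_hypergeom=float(p[s]), q=float(q[s]))
               for s, name in enumerate(names)]
    return sorted(results, key=lambda r: (r.p_hypergeom, r.set_name))


def overlap_frame(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set": r.set_name,
        "n_overlap": r.n_overlap,
        "n_list": r.n_list,
        "n_set": r.n_set,
        "n_universe": r.n_universe,
        "p_perm": r.p_perm,
        "p_hypergeom": r.p_hypergeom,
        "q": r.q,
    } for r in results])
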