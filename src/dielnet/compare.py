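"""Correspondence between the two condition networks.

Overlap counting with one-sided Fisher/hypergeometric significance,
resolution of one network's module into the other network's modules, and
consensus-module detection from the element-wise minimum of two TOMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .network import ModuleAssignment, TOMatrix, detect_modules, merge_close_modules

DISPLAY_CAP = 50.0  # -log10(p) display ceiling


@dataclass
class OverlapResult:
    """Module x module overlap between two assignments on a shared universe.

    ``counts``: genes in common per (A-module, B-module) cell;
    ``p``: one-sided hypergeometric over-representation p per cell;
    ``display``: -log10(p) capped at 50, the conventional heat-map scale.
    """

    counts: pd.DataFrame
    p: pd.DataFrame
    display: pd.DataFrame
    universe_size: int
    sizes_a: pd.Series = field(repr=False)
    sizes_b: pd.Series = field(repr=False)


def hypergeom_sf(k: int, n_universe: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the one-sided Fisher p."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, n_marked, n_drawn))


def overlap_matrix(mod_a: ModuleAssignment, mod_b: ModuleAssignment) -> OverlapResult:
    """Overlap counts and Fisher significance between two module sets.

    The gene universe is the intersection of the genes present in both
    assignments; unassigned genes (label 0) are excluded from cells but kept
    in the universe size N.
    """
    universe = mod_a.labels.index.intersection(mod_b.labels.index)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    la = mod_a.labels.loc[universe]
    lb = mod_b.labels.loc[universe]
    mods_a = sorted(int(m) for m in la.unique() if m != 0)
    mods_b = sorted(int(m) for m in lb.unique() if m != 0)
    n = len(universe)
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b)
    p = pd.DataFrame(1.0, index=mods_a, columns=mods_b)
    ct = pd.crosstab(la, lb)
    for a in mods_a:
        for b in mods_b:
            k = int(ct.at[a, b]) if (a in ct.index and b in ct.columns) else 0
            counts.at[a, b] = k
            p.at[a, b] = hypergeom_sf(k, n, int((la == a).sum()), int((lb == b).sum()))
    with np.errstate(divide="ignore"):
        display = np.minimum(-np.log10(p), DISPLAY_CAP)
    sizes_a = la[la != 0].value_counts().sort_index()
    sizes_b = lb[lb != 0].value_counts().sort_index()
    return OverlapResult(counts, p, display, n, sizes_a, sizes_b)


def resolve_module(
    mod_a: ModuleAssignment,
    module_id: int,
    mod_b: ModuleAssignment,
    em: ExpressionMatrix | None = None,
) -> dict:
    """How one A-module's genes distribute over the B-modules.

    Returns ``fractions`` (B-module -> fraction of the A-module's genes,
    descending; unassigned genes contribute to the remainder so the
    fractions sum to <= 1) and, when an expression matrix is supplied,
    ``profiles``: the mean expression profile of each sub-group.
    """
    if module_id not in mod_a.module_ids:
        raise KeyError(f"module {module_id} not in assignment A")
    genes = mod_a.genes_in(module_id)
    shared = genes.intersection(mod_b.labels.index)
    lb = mod_b.labels.loc[shared]
    frac = {}
    for b in sorted(int(m) for m in lb.unique() if m != 0):
        frac[b] = float((lb == b).sum()) / len(genes)
    fractions = pd.Series(frac).sort_values(ascending=False)
    out: dict = {
        "module": module_id,
        "n_genes": len(genes),
        "fractions": fractions,
        "unassigned_fraction": 1.0 - float(fractions.sum()),
    }
    if em is not None:
        profiles = {}
        for b in fractions.index:
            grp = [g for g in shared[lb == b] if g in em.gene_ids]
            if grp:
                profiles[b] = em.values.loc[grp].mean(axis=0)
        out["profiles"] = pd.DataFrame(profiles).T
    return out


def consensus_modules(
    tom_a: TOMatrix,
    tom_b: TOMatrix,
    min_size: int = 30,
    merge_cut: float = 0.25,
    scale_quantile: float | None = 0.95,
    em_a: ExpressionMatrix | None = None,
    em_b: ExpressionMatrix | None = None,
) -> ModuleAssignment:
    """Modules of the element-wise-minimum consensus TOM.

    ``scale_quantile`` rescales the second TOM so its off-diagonal quantile
    matches the first's before taking the minimum (prevents a globally
    weaker network from dominating); pass None to disable.  When both
    expression matrices are given, close consensus modules are merged using
    the worst-case (max over conditions) eigengene dissimilarity.
    """
    genes = tom_a.gene_ids.intersection(tom_b.gene_ids)
    if len(genes) == 0:
        raise ValueError("disjoint gene universes")
    ia = tom_a.gene_ids.get_indexer(genes)
    ib = tom_b.gene_ids.get_indexer(genes)
    a = tom_a.values[np.ix_(ia, ia)].copy()
    b = tom_b.values[np.ix_(ib, ib)].copy()
    if scale_quantile is not None:
        iu = np.triu_indices(len(genes), k=1)
        qa = np.quantile(a[iu], scale_quantile)
        qb = np.quantile(b[iu], scale_quantile)
        if qb > 0:
            b = np.minimum(b * (qa / qb), 1.0)
            np.fill_diagonal(b, 1.0)
    cons = TOMatrix(genes, np.minimum(a, b))
    assignment, _ = detect_modules(cons, min_size=min_size)
    if em_a is not None and em_b is not None and len(assignment.module_ids) > 1:
        assignment = _merge_consensus(
            assignment, em_a, em_b, merge_cut=merge_cut
        )
    return assignment


def _merge_consensus(
    modules: ModuleAssignment,
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    merge_cut: float,
) -> ModuleAssignment:
    """Iteratively merge modules using max-over-conditions ME dissimilarity."""
    import scipy.cluster.hierarchy as sch
    from scipy.spatial.distance import squareform

    from .network import module_eigengenes

    current = modules
    for _ in range(100):
        ids = current.module_ids
        if len(ids) <= 1:
            return current
        diss = np.zeros((len(ids), len(ids)))
        for em in (em_a, em_b):
            eig = module_eigengenes(em, current)
            me = eig.me.loc[ids].to_numpy(dtype=float)
            d = 1.0 - np.corrcoef(me)
            np.fill_diagonal(d, 0.0)
            diss = np.maximum(diss, np.clip((d + d.T) / 2.0, 0.0, None))
        z = sch.linkage(squareform(diss, checks=False), method="average")
        flat = sch.fcluster(z, t=merge_cut, criterion="distance")
        if len(np.unique(flat)) == len(ids):
            return current
        mapping = {m: int(c) for m, c in zip(ids, flat)}
        mapping[0] = 0
        current = ModuleAssignment.from_raw(
            current.labels.map(mapping), dict(current.params, merge_cut=merge_cut)
        )
    return current
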