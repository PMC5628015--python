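"""Signed weighted co-expression network construction and module detection.

The pipeline follows the standard weighted co-expression recipe: Pearson
correlation between log2 expression profiles, signed soft-thresholded
adjacency a_ij = ((1 + cor)/2)^beta, signed topological overlap, average-
linkage clustering of 1 - TOM, adaptive branch cutting into modules of a
minimum size, eigengene computation, and merging of modules whose
eigengenes are nearly collinear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform

from .expression import DendrogramResult, ExpressionMatrix, SCALE_LOG2

_SYM_TOL = 1e-12


@dataclass
class AdjacencyMatrix:
    """Signed soft-thresholded adjacency: symmetric, values in [0, 1]."""

    gene_ids: pd.Index
    values: np.ndarray = field(repr=False)
    beta: float = 16.0

    def __post_init__(self) -> None:
        a = self.values
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency shape inconsistent with gene ids")
        if np.abs(a - a.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("adjacency is not symmetric")
        if a.min(initial=1.0) < -_SYM_TOL or a.max(initial=0.0) > 1 + _SYM_TOL:
            raise ValueError("adjacency values outside [0, 1]")


@dataclass
class TOMatrix:
    """Topological overlap matrix: symmetric, unit diagonal, values >= 0."""

    gene_ids: pd.Index
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = self.values
        if t.shape[0] != t.shape[1] or t.shape[0] != len(self.gene_ids):
            raise ValueError("TOM shape inconsistent with gene ids")
        if np.abs(t - t.T).max(initial=0.0) > 1e-10:
            raise ValueError("TOM is not symmetric")


@dataclass
class ModuleAssignment:
    """Gene -> module labels; label 0 is reserved for unassigned genes.

    Labels are dense positive integers ordered by decreasing module size.
    """

    labels: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.labels[self.labels != 0].value_counts()
        return counts.sort_index()

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    @staticmethod
    def from_raw(labels: pd.Series, params: dict | None = None) -> "ModuleAssignment":
        """Relabel arbitrary positive labels densely by decreasing size."""
        labels = labels.astype(int)
        sizes = labels[labels != 0].value_counts()
        order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[0] = 0
        return ModuleAssignment(labels.map(mapping), params or {})


@dataclass
class EigengeneSet:
    """Module eigengenes: unit-norm first principal components over samples.

    ``me`` is a modules x samples DataFrame; each row has unit Euclidean
    norm and is oriented so it correlates non-negatively with the module's
    mean standardized expression profile.
    """

    me: pd.DataFrame
    variance_explained: pd.Series
    samples: pd.DataFrame = field(repr=False)

    @property
    def module_ids(self) -> list[int]:
        return list(self.me.index)


def signed_adjacency(em: ExpressionMatrix, beta: float = 16.0) -> AdjacencyMatrix:
    """a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta with Pearson correlation.

    Zero-variance genes are dropped with a warning before the correlation
    (their Pearson correlation is undefined).
    """
    if em.scale != SCALE_LOG2:
        raise ValueError("signed_adjacency expects log2-scale expression")
    if em.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = em.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    genes = em.gene_ids
    if (sd == 0).any():
        dropped = list(genes[sd == 0])
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)", stacklevel=2)
        keep = sd > 0
        x, genes = x[keep], genes[keep]
    corr = np.corrcoef(x)
    np.clip(corr, -1.0, 1.0, out=corr)
    adj = ((1.0 + corr) / 2.0) ** beta
    adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(genes, adj, beta)


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """Signed topological overlap.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    L_ij = sum_u a_iu a_uj over u != i, j and k_i is the connectivity of i
    excluding the diagonal; TOM_ii = 1.
    """
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # includes no diagonal terms because a_ii = 0
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return TOMatrix(adj.gene_ids, tom)


def _linkage(dist: np.ndarray) -> np.ndarray:
    return sch.linkage(squareform(dist, checks=False), method="average")


def _cut_recursive(
    dist: np.ndarray,
    idx: np.ndarray,
    min_size: int,
    height_quantile: float,
    split_ratio: float,
    static_height: float | None,
    depth: int,
) -> list[np.ndarray]:
    """Return a list of index arrays, one per accepted branch (module)."""
    if len(idx) < 2 * min_size or depth > 12:
        return [idx]
    sub = dist[np.ix_(idx, idx)]
    z = _linkage(sub)
    cut = (
        static_height
        if static_height is not None
        else float(np.quantile(z[:, 2], height_quantile))
    )
    flat = sch.fcluster(z, t=cut, criterion="distance")
    groups = [idx[flat == c] for c in np.unique(flat)]
    if len(groups) == 1:
        return [idx]
    out: list[np.ndarray] = []
    for g in groups:
        if len(g) < min_size:
            out.append(g)  # too small; caller discards
            continue
        # split a branch further only if it still contains a join nearly as
        # high as the cut itself (i.e. it plausibly holds >1 module)
        if len(g) >= 2 * min_size:
            gz = _linkage(dist[np.ix_(g, g)])
            if gz[:, 2].max() > split_ratio * cut:
                out.extend(
                    _cut_recursive(
                        dist, g, min_size, height_quantile, split_ratio, None, depth + 1
                    )
                )
                continue
        out.append(g)
    return out


def _prune_loose_members(
    tom_values: np.ndarray, idx: np.ndarray, prune_ratio: float
) -> np.ndarray:
    """Drop branch members weakly overlapping the branch core.

    A member's attachment is its mean TOM to the other members; members
    below ``prune_ratio`` x the branch median attachment are released
    (they are genes swept up by average linkage, not co-expressed with the
    core).  Iterates to a fixed point.
    """
    keep = idx
    for _ in range(20):
        if len(keep) < 2:
            return keep
        sub = tom_values[np.ix_(keep, keep)].copy()
        np.fill_diagonal(sub, 0.0)
        attach = sub.sum(axis=1) / (len(keep) - 1)
        cut = prune_ratio * np.median(attach)
        ok = attach >= cut
        if ok.all():
            return keep
        keep = keep[ok]
    return keep


def _branch_contrast(tom_values: np.ndarray, idx: np.ndarray) -> float:
    """Median internal TOM of a branch over its median TOM to the rest.

    Genuine modules overlap among themselves far more than with the
    remaining network; a structureless branch has contrast near 1.
    """
    n = tom_values.shape[0]
    outside = np.setdiff1d(np.arange(n), idx, assume_unique=False)
    if len(outside) == 0:
        return 1.0
    sub = tom_values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    internal = float(np.median(sub[iu]))
    external = float(np.median(tom_values[np.ix_(idx, outside)]))
    if external <= 0:
        return np.inf if internal > 0 else 1.0
    return internal / external


def detect_modules(
    tom: TOMatrix,
    min_size: int = 30,
    height_quantile: float = 0.99,
    split_ratio: float = 0.5,
    prune_ratio: float = 0.5,
    contrast_ratio: float = 2.0,
    static_height: float | None = None,
) -> tuple[ModuleAssignment, DendrogramResult]:
    """Cluster 1 - TOM (average linkage) and cut the tree into modules.

    A top-down adaptive branch decomposition: the dendrogram is first cut at
    the ``height_quantile`` of its merge heights (or at ``static_height`` if
    given); branches that still contain an internal join above
    ``split_ratio`` x cut are recursively re-clustered and re-cut; branch
    members only loosely attached to the branch core (mean TOM below
    ``prune_ratio`` x the branch median) are released; finally a branch is
    accepted as a module only if its internal topological overlap exceeds
    ``contrast_ratio`` x its overlap with the rest of the network (this
    rejects chance branches on structureless data).  Branches smaller than
    ``min_size`` are left unassigned (label 0).  Final labels are dense
    positive integers ordered by decreasing module size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = len(tom.gene_ids)
    if n < 2 * min_size:
        raise ValueError("need at least 2 * min_size genes")
    dist = np.clip(1.0 - tom.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = _linkage(dist)
    branches = _cut_recursive(
        dist,
        np.arange(n),
        min_size,
        height_quantile,
        split_ratio,
        static_height,
        depth=0,
    )
    labels = np.zeros(n, dtype=int)
    nxt = 1
    for g in branches:
        if len(g) >= min_size and prune_ratio > 0:
            g = _prune_loose_members(tom.values, g, prune_ratio)
        if len(g) >= min_size and contrast_ratio > 0:
            if _branch_contrast(tom.values, g) < contrast_ratio:
                continue
        if len(g) >= min_size:
            labels[g] = nxt
            nxt += 1
    assignment = ModuleAssignment.from_raw(
        pd.Series(labels, index=tom.gene_ids),
        {
            "min_size": min_size,
            "height_quantile": height_quantile,
            "split_ratio": split_ratio,
            "prune_ratio": prune_ratio,
            "static_height": static_height,
        },
    )
    ids = [str(g) for g in tom.gene_ids]
    dendro = DendrogramResult(ids, z, pd.DataFrame(dist, index=ids, columns=ids))
    return assignment, dendro


def module_eigengenes(
    em: ExpressionMatrix, modules: ModuleAssignment
) -> EigengeneSet:
    """First principal component (over samples) per module.

    Member genes are standardized across samples; the eigengene is the
    leading right-singular vector, unit norm, oriented so its correlation
    with the module's mean standardized profile is non-negative (ties broken
    by forcing a non-negative loading on the lexicographically first gene).
    """
    if not modules.module_ids:
        raise ValueError("no modules to summarize")
    if em.n_samples < 3:
        raise ValueError("need at least 3 samples")
    me_rows, varex = {}, {}
    for m in modules.module_ids:
        genes = modules.genes_in(m)
        genes = [g for g in genes if g in em.gene_ids]
        x = em.values.loc[genes].to_numpy(dtype=float)
        if x.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene; eigengene degenerate")
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        xz = (x - x.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(xz, full_matrices=False)
        me = vt[0]
        mean_profile = xz.mean(axis=0)
        c = float(np.dot(me, mean_profile))
        if abs(c) < 1e-10:
            first = min(range(len(genes)), key=lambda i: str(genes[i]))
            c = float(np.dot(me, xz[first]))
        if c < 0:
            me = -me
        me_rows[m] = me
        varex[m] = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0
    me_df = pd.DataFrame(me_rows, index=em.sample_ids).T
    return EigengeneSet(me_df, pd.Series(varex), em.samples.copy())


def merge_close_modules(
    em: ExpressionMatrix, modules: ModuleAssignment, merge_cut: float = 0.25
) -> ModuleAssignment:
    """Merge modules whose eigengene dissimilarity 1 - cor is below the cut.

    Eigengenes are re-computed after each merge round until stable.
    """
    if not (0.0 < merge_cut < 1.0):
        raise ValueError("merge_cut must lie in (0, 1)")
    current = modules
    for _ in range(100):
        ids = current.module_ids
        if len(ids) <= 1:
            return current
        eig = module_eigengenes(em, current)
        me = eig.me.loc[ids].to_numpy(dtype=float)
        diss = 1.0 - np.corrcoef(me)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        z = _linkage(diss)
        flat = sch.fcluster(z, t=merge_cut, criterion="distance")
        if len(np.unique(flat)) == len(ids):
            return current
        mapping = {m: int(c) for m, c in zip(ids, flat)}
        mapping[0] = 0
        current = ModuleAssignment.from_raw(
            current.labels.map(mapping), dict(current.params, merge_cut=merge_cut)
        )
    return current


def module_membership(
    em: ExpressionMatrix, eigengenes: EigengeneSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every gene with every module eigengene.

    Returns (MM, P): genes x modules correlation table and its two-sided
    Student-t p-values, t = r sqrt(n-2) / sqrt(1 - r^2).  High |MM| within
    a gene's own module marks hub genes.
    """
    if not eigengenes.me.columns.equals(em.sample_ids):
        me = eigengenes.me[em.sample_ids]
    else:
        me = eigengenes.me
    x = em.values.to_numpy(dtype=float)
    n = x.shape[1]
    xz = x - x.mean(axis=1, keepdims=True)
    xs = x.std(axis=1)
    xs[xs == 0] = np.nan
    e = me.to_numpy(dtype=float)
    ez = e - e.mean(axis=1, keepdims=True)
    es = e.std(axis=1)
    r = (xz @ ez.T) / n / np.outer(xs, es)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t) & ~np.isnan(r), 0.0, p)  # |r| == 1
    mm = pd.DataFrame(r, index=em.gene_ids, columns=me.index)
    pv = pd.DataFrame(p, index=em.gene_ids, columns=me.index)
    return mm, pv


def own_module_membership(
    mm: pd.DataFrame, p: pd.DataFrame, modules: ModuleAssignment
) -> pd.DataFrame:
    """Per-gene MM and p against the gene's own module (label > 0 only)."""
    rows = []
    for g, m in modules.labels.items():
        if m == 0 or g not in mm.index or m not in mm.columns:
            continue
        rows.append({"gene": g, "module": m, "mm": mm.at[g, m], "p": p.at[g, m]})
    return pd.DataFrame(rows).set_index("gene")


def export_network_edges(
    tom: TOMatrix,
    modules: ModuleAssignment,
    edge_path: str | Path,
    node_path: str | Path | None = None,
    threshold: float = 0.1,
    mm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write an undirected weighted edge list with TOM weight >= threshold.

    Columns: source, target, weight, source_module, target_module.  An
    optional node table records module labels and |MM| hubness.  Returns the
    edge DataFrame.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    genes = list(tom.gene_ids)
    t = tom.values
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = t[iu, ju] >= threshold
    labels = modules.labels.reindex(tom.gene_ids).fillna(0).astype(int)
    edges = pd.DataFrame(
        {
            "source": [genes[i] for i in iu[keep]],
            "target": [genes[j] for j in ju[keep]],
            "weight": t[iu[keep], ju[keep]],
            "source_module": labels.to_numpy()[iu[keep]],
            "target_module": labels.to_numpy()[ju[keep]],
        }
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    if node_path is not None:
        nodes = pd.DataFrame({"gene": genes, "module": labels.to_numpy()})
        if mm is not None:
            hub = []
            for g, m in zip(genes, labels.to_numpy()):
                hub.append(
                    abs(mm.at[g, m]) if m != 0 and g in mm.index and m in mm.columns else np.nan
                )
            nodes["hubness"] = hub
        nodes.to_csv(node_path, sep="\t", index=False)
    return edges
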