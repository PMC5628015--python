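"""Expression containers, abundance filtering, log transform, and sample clustering.

The central object is :class:`ExpressionMatrix`: a genes x samples table of
FPKM (or log2 FPKM) values together with per-sample metadata (condition,
Zeitgeber time, day, replicate).  Columns are kept in a deterministic
(condition, zt, replicate) order so that downstream correlation-based steps
are invariant to the order samples arrive in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

SCALE_FPKM = "fpkm"
SCALE_LOG2 = "log2"

_META_COLUMNS = ("condition", "zt", "day", "replicate")


@dataclass(frozen=True)
class FilterLog:
    """Record of an abundance filter: how many genes survived and why."""

    n_input: int
    n_kept: int
    n_dropped: int
    min_fpkm: float


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``condition`` (``"WW"``
        or ``"D"``), ``zt`` (hours), ``day`` and ``replicate``.
    scale
        ``"fpkm"`` (non-negative linear scale) or ``"log2"``.
    note
        Free-text provenance note.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = SCALE_FPKM
    note: str = ""

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_FPKM, SCALE_LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        missing_meta = [c for c in self.values.columns if c not in self.samples.index]
        if missing_meta:
            raise ValueError(
                f"expression columns absent from sample metadata: {missing_meta}"
            )
        for col in _META_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.scale == SCALE_FPKM and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                "negative FPKM at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        # align metadata to the expression columns and order deterministically
        meta = self.samples.loc[list(self.values.columns)]
        order = meta.sort_values(["condition", "zt", "replicate"]).index
        values = self.values[order]
        meta = meta.loc[order]
        values.index.name = values.columns.name = None
        meta.index.name = None
        object.__setattr__(self, "samples", meta)
        object.__setattr__(self, "values", values)

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(
            self.values[ids], self.samples.loc[ids], self.scale, self.note
        )

    def write(self, expr_path: str | Path, meta_path: str | Path) -> None:
        """Write expression and metadata as tab-delimited UTF-8 tables."""
        v = self.values.copy()
        v.index.name = "gene_id"
        v.to_csv(expr_path, sep="\t")
        m = self.samples.copy()
        m.index.name = "sample_id"
        m.to_csv(meta_path, sep="\t")


def read_expression_table(
    path: str | Path, metadata_path: str | Path, scale: str = SCALE_FPKM
) -> ExpressionMatrix:
    """Read an expression TSV (rows = genes) and its sample-metadata TSV.

    Raises with row/column coordinates on non-numeric cells, duplicate gene
    ids, or expression columns missing from the metadata.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    raw.index.name = None
    meta.index.name = None
    try:
        values = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            conv = pd.to_numeric(raw[col], errors="coerce")
            if conv.isna().any() and not raw[col].isna().all():
                i = int(np.argmax(conv.isna().to_numpy()))
                raise ValueError(
                    f"non-numeric value {raw[col].iloc[i]!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                ) from None
        raise
    return ExpressionMatrix(values, meta, scale=scale)


def filter_low_expression(
    em: ExpressionMatrix, min_fpkm: float = 10.0
) -> tuple[ExpressionMatrix, FilterLog]:
    """Keep genes whose maximum FPKM over all samples reaches ``min_fpkm``.

    The threshold is inclusive: a single value exactly at ``min_fpkm`` keeps
    the gene.  Defined on the FPKM scale only.
    """
    if em.scale != SCALE_FPKM:
        raise ValueError("abundance filter is defined on FPKM-scale values")
    keep = em.values.max(axis=1) >= min_fpkm
    log = FilterLog(em.n_genes, int(keep.sum()), int((~keep).sum()), min_fpkm)
    out = ExpressionMatrix(em.values.loc[keep], em.samples, em.scale, em.note)
    return out, log


def log_transform(em: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + offset); rejects already-transformed input."""
    if em.scale == SCALE_LOG2:
        raise ValueError("expression is already on log2 scale")
    if offset <= 0:
        raise ValueError("offset must be positive")
    return ExpressionMatrix(
        np.log2(em.values + offset), em.samples, SCALE_LOG2, em.note
    )


def concat_expression(mats: Iterable[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices sharing a gene universe (e.g. WW + D)."""
    mats = list(mats)
    if not mats:
        raise ValueError("no matrices given")
    genes = mats[0].gene_ids
    scale = mats[0].scale
    for m in mats[1:]:
        if m.scale != scale:
            raise ValueError("mixed scales")
        if not genes.equals(m.gene_ids):
            genes = genes.intersection(m.gene_ids)
    values = pd.concat([m.values.loc[genes] for m in mats], axis=1)
    samples = pd.concat([m.samples for m in mats], axis=0)
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids across matrices")
    return ExpressionMatrix(values, samples, scale)


def average_replicates(em: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns into one profile per (condition, ZT).

    Mirrors pooled-sample profiles; used e.g. for the time-vs-treatment
    sample-clustering check where each leaf is one condition x time point.
    """
    groups = em.samples.groupby(["condition", "zt"], sort=True)
    cols, rows = {}, []
    for (cond, zt), sub in groups:
        sid = f"{cond}_ZT{int(zt):02d}"
        cols[sid] = em.values[sub.index].mean(axis=1)
        rows.append(
            {
                "sample_id": sid,
                "condition": cond,
                "zt": zt,
                "day": sub["day"].iloc[0],
                "replicate": "mean",
            }
        )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return ExpressionMatrix(pd.DataFrame(cols), meta, em.scale, em.note)


@dataclass
class DendrogramResult:
    """Average-linkage dendrogram over samples (or genes).

    Attributes
    ----------
    ids
        Leaf labels in the (sorted) order used to build the linkage.
    linkage
        scipy linkage matrix; ``linkage[:, 2]`` are merge heights.
    distance
        Square distance DataFrame (1 - Pearson correlation).
    """

    ids: list[str]
    linkage: np.ndarray
    distance: pd.DataFrame = field(repr=False)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in sch.leaves_list(self.linkage)]

    def nearest_neighbors(self) -> pd.Series:
        """Closest other leaf per leaf, by the underlying distance."""
        d = self.distance.to_numpy().copy()
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        return pd.Series([self.ids[j] for j in nn], index=self.ids)


def cluster_samples(
    em: ExpressionMatrix, sample_subset: Sequence[str] | None = None
) -> DendrogramResult:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Operates on log2-scale values (matching how expression heatmap/cluster
    figures are drawn for RNA-seq time courses).  Samples are ordered
    lexicographically before computing the linkage so ties break
    deterministically regardless of input order.
    """
    if em.scale != SCALE_LOG2:
        raise ValueError("cluster_samples expects log2-scale values")
    sub = em if sample_subset is None else em.subset_samples(sample_subset)
    if sub.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    ids = sorted(sub.sample_ids)
    x = sub.values[ids].to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance sample column(s): {bad}")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = sch.linkage(squareform(dist, checks=False), method="average")
    return DendrogramResult(ids, z, pd.DataFrame(dist, index=ids, columns=ids))
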