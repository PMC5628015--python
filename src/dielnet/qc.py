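"""Probe-count normalization, robust outlier masking, and enrichment tests.

Implements the two-step normalization used for multiplexed count panels —
a CodeSet step that aligns sample sets through a shared pooled-RNA
reference row, then a Content step that removes per-sample factors via the
geometric mean of designated housekeeping probes — followed by a modified
Z-score filter for spurious single-cell counts, technical-replicate
selection, per-timepoint replicate statistics, and a generic hypergeometric
over-representation test for candidate gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAD_CONSTANT = 0.6745
MEAN_AD_CONSTANT = 0.7979


@dataclass
class ProbeCountTable:
    """Probes x samples counts plus panel metadata.

    ``samples`` is indexed by sample id with at least columns ``set``
    (cartridge/plate set id) and ``is_reference`` (pooled-RNA reference
    columns used by the CodeSet step).  ``housekeeping`` lists >= 3 probes
    with flat profiles; ``technical_pairs`` lists (a, b) duplicate
    measurements of the same biological sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    housekeeping: list[str]
    technical_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.housekeeping) < 3:
            raise ValueError("need at least 3 housekeeping probes")
        missing = [h for h in self.housekeeping if h not in self.counts.index]
        if missing:
            raise ValueError(f"housekeeping probes absent from table: {missing}")
        if not self.counts.columns.isin(self.samples.index).all():
            bad = [c for c in self.counts.columns if c not in self.samples.index]
            raise ValueError(f"count columns without metadata: {bad}")
        arr = self.counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) and not np.isnan(arr).any():
            raise ValueError("counts must be finite")
        if np.nanmin(arr) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def endogenous(self) -> list[str]:
        return [p for p in self.counts.index if p not in self.housekeeping]

    def biological_columns(self) -> list[str]:
        ref = self.samples["is_reference"].astype(bool)
        return [c for c in self.counts.columns if not ref.get(c, False)]


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def normalize_probe_counts(table: ProbeCountTable) -> ProbeCountTable:
    """CodeSet then Content normalization, both multiplicative.

    CodeSet step: each sample set is scaled so its pooled-RNA reference
    column matches the geometric mean of the reference columns across sets.
    Content step: each sample is scaled by (mean across samples of the
    housekeeping geometric means) / (its own housekeeping geometric mean).
    Samples with any zero housekeeping count are rejected with a report.
    """
    counts = table.counts.astype(float).copy()
    meta = table.samples
    hk = counts.loc[table.housekeeping]
    zero_cols = [c for c in counts.columns if (hk[c] <= 0).any()]
    if zero_cols:
        raise ValueError(
            f"zero housekeeping count in sample(s) {zero_cols}; "
            "cannot content-normalize"
        )
    ref_mask = meta["is_reference"].astype(bool)
    ref_cols = [c for c in counts.columns if ref_mask.get(c, False)]
    if ref_cols:
        per_set = {}
        for c in ref_cols:
            s = meta.at[c, "set"]
            per_set.setdefault(s, []).append(_geomean(counts[c].to_numpy() + 0.0))
        set_gm = {s: _geomean(np.array(v)) for s, v in per_set.items()}
        overall = _geomean(np.array(list(set_gm.values())))
        for c in counts.columns:
            s = meta.at[c, "set"]
            if s in set_gm:
                counts[c] = counts[c] * (overall / set_gm[s])
    hk_gm = {c: _geomean(counts.loc[table.housekeeping, c].to_numpy()) for c in counts.columns}
    target = float(np.mean(list(hk_gm.values())))
    for c in counts.columns:
        counts[c] = counts[c] * (target / hk_gm[c])
    return replace(table, counts=counts)


def modified_zscore(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-probe modified Z-scores across samples.

    M = 0.6745 (x - median) / MAD; when MAD = 0 the mean-absolute-deviation
    variant 0.7979 (x - median) / meanAD is used and the probe is flagged.
    A probe with all values identical gets M = 0 everywhere.
    """
    z = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    flagged = []
    for probe in counts.index:
        x = counts.loc[probe].to_numpy(dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > 0:
            z.loc[probe] = MAD_CONSTANT * (x - med) / mad
        else:
            mean_ad = np.mean(np.abs(x - med))
            flagged.append(probe)
            if mean_ad > 0:
                z.loc[probe] = MEAN_AD_CONSTANT * (x - med) / mean_ad
    return z, flagged


def modified_zscore_filter(
    table: ProbeCountTable, cut: float = 3.0
) -> tuple[ProbeCountTable, pd.DataFrame]:
    """Mask probe x sample cells whose |modified Z| exceeds the cut.

    Targets occasional spurious single-sample spikes: cells are masked
    (set to NaN) individually; whole probes are never removed.  Returns the
    filtered table and the boolean mask of removed cells.
    """
    if table.counts.shape[1] < 4:
        raise ValueError("need at least 4 samples per probe")
    z, _ = modified_zscore(table.counts)
    mask = z.abs() > cut
    filtered = table.counts.mask(mask)
    return replace(table, counts=filtered), mask


def choose_technical_replicate(
    table: ProbeCountTable, pairing: list[tuple[str, str]] | None = None
) -> ProbeCountTable:
    """Per technical pair, keep the member with the lower max |modified Z|.

    Ties break deterministically toward the lexicographically smaller
    sample id.  The discarded columns are dropped from the table.
    """
    pairs = pairing if pairing is not None else table.technical_pairs
    for a, b in pairs:
        for s in (a, b):
            if s not in table.counts.columns:
                raise ValueError(f"pairing names unknown sample {s!r}")
    z, _ = modified_zscore(table.counts)
    max_abs = z.abs().max(axis=0)
    drop = []
    for a, b in pairs:
        if max_abs[a] < max_abs[b]:
            drop.append(b)
        elif max_abs[b] < max_abs[a]:
            drop.append(a)
        else:
            drop.append(max(a, b))
    counts = table.counts.drop(columns=drop)
    samples = table.samples.drop(index=drop)
    return ProbeCountTable(counts, samples, table.housekeeping, [])


def replicate_summary_and_tests(
    table: ProbeCountTable, alternative: str = "less"
) -> pd.DataFrame:
    """Per probe and ZT: condition means, SEs, and a one-tailed t-test.

    Biological replicates are averaged with standard errors per time point;
    the droughted and well-watered groups are compared at every ZT by an
    unpaired equal-variance Student t-test, one-tailed in the configured
    direction (``"less"`` tests D < WW).  Flags significance at p < 0.05.
    """
    meta = table.samples
    bio = [
        c
        for c in table.counts.columns
        if not meta.at[c, "is_reference"] and meta.at[c, "condition"] in ("WW", "D")
    ]
    rows = []
    for probe in table.counts.index:
        for zt in sorted(meta.loc[bio, "zt"].dropna().unique()):
            groups = {}
            for cond in ("WW", "D"):
                cols = [
                    c
                    for c in bio
                    if meta.at[c, "condition"] == cond and meta.at[c, "zt"] == zt
                ]
                vals = table.counts.loc[probe, cols].dropna().to_numpy(dtype=float)
                groups[cond] = vals
            ww, d = groups["WW"], groups["D"]
            if len(ww) < 2 or len(d) < 2:
                continue
            if ww.std(ddof=1) == 0 and d.std(ddof=1) == 0 and ww.mean() == d.mean():
                p = 0.5
            else:
                p = float(
                    stats.ttest_ind(d, ww, equal_var=True, alternative=alternative).pvalue
                )
            rows.append(
                {
                    "probe": probe,
                    "zt": zt,
                    "mean_ww": ww.mean(),
                    "se_ww": ww.std(ddof=1) / np.sqrt(len(ww)),
                    "n_ww": len(ww),
                    "mean_d": d.mean(),
                    "se_d": d.std(ddof=1) / np.sqrt(len(d)),
                    "n_d": len(d),
                    "p": p,
                    "sig_p05": p < 0.05,
                }
            )
    return pd.DataFrame(rows)


def enrichment_test(
    gene_set: list[str] | set[str],
    annotation_map: dict[str, list[str]] | pd.DataFrame,
    universe: list[str] | set[str],
    min_term_size: int = 5,
    top_k: int | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per annotation term.

    ``annotation_map`` maps term -> member genes (or a two-column DataFrame
    gene/term).  Terms with fewer than ``min_term_size`` members in the
    universe are skipped.  p-values are Benjamini-Hochberg adjusted across
    the tested terms.
    """
    universe = set(universe)
    genes = set(gene_set)
    if not universe or not genes:
        raise ValueError("empty universe or gene set")
    if not genes <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if isinstance(annotation_map, pd.DataFrame):
        gcol, tcol = annotation_map.columns[:2]
        annotation_map = {
            t: list(sub[gcol]) for t, sub in annotation_map.groupby(tcol)
        }
    rows = []
    n, k_set = len(universe), len(genes)
    for term in sorted(annotation_map):
        members = set(annotation_map[term]) & universe
        if len(members) < min_term_size:
            continue
        overlap = len(members & genes)
        p = float(stats.hypergeom.sf(overlap - 1, n, len(members), k_set)) if overlap else 1.0
        rows.append(
            {"term": term, "term_size": len(members), "overlap": overlap, "p": p}
        )
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        out["q"] = []
    if top_k is not None:
        out = out.head(top_k)
    return out
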