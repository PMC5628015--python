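"""Physiology-side statistics and module-trait association.

Houses the diel trait series (net CO2 assimilation A, stomatal conductance
g_s, light-adapted PSII efficiency Fv'/Fm', non-structural carbohydrates
NSC, and derived intrinsic water-use efficiency WUE = A/g_s), per-timepoint
one-tailed t-tests between conditions, eigengene-trait correlation, gene
significance, and the GS-vs-MM coupling check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .network import EigengeneSet


@dataclass
class TraitSeries:
    """Per-replicate diel measurements of one physiological trait.

    ``data`` holds long-format records with columns ``zt``, ``replicate``,
    ``value``.  Units are carried as free text (e.g. umol CO2 m-2 s-1).
    """

    trait: str
    condition: str
    data: pd.DataFrame
    units: str = ""

    def __post_init__(self) -> None:
        need = {"zt", "replicate", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"trait data must have columns {sorted(need)}")
        self.data = self.data.reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        """Per-ZT mean, standard error (sd/sqrt(n)) and n."""
        g = self.data.groupby("zt")["value"]
        out = pd.DataFrame(
            {"mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.count()), "n": g.count()}
        )
        return out

    def zts(self) -> np.ndarray:
        return np.sort(self.data["zt"].unique())


def compute_wue(a_series: TraitSeries, gs_series: TraitSeries) -> TraitSeries:
    """Intrinsic water-use efficiency WUE = A / g_s per (ZT, replicate).

    Records where g_s = 0 are dropped with a warning (WUE undefined).
    Requires exactly aligned (ZT, replicate) records.
    """
    if a_series.condition != gs_series.condition:
        raise ValueError("conditions differ between A and g_s series")
    a = a_series.data.set_index(["zt", "replicate"])["value"]
    g = gs_series.data.set_index(["zt", "replicate"])["value"]
    if not a.index.sort_values().equals(g.index.sort_values()):
        raise ValueError("A and g_s records are misaligned on (zt, replicate)")
    g = g.loc[a.index]
    zero = g == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} record(s) with g_s = 0")
    wue = (a[~zero] / g[~zero]).rename("value").reset_index()
    return TraitSeries("WUE", a_series.condition, wue, units="umol CO2 / mmol H2O")


def timepoint_ttests(
    trait_ww: TraitSeries, trait_d: TraitSeries, alternative: str
) -> pd.DataFrame:
    """One-tailed unpaired equal-variance Student t-test at every ZT.

    ``alternative`` refers to the droughted group: ``"less"`` tests
    H1: mean(D) < mean(WW), ``"greater"`` the reverse.  Returns per-ZT t, p
    and significance flags at p<0.01 and p<0.05.  Zero pooled variance with
    equal means yields t = 0, p = 0.5 with a warning.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    zts = np.intersect1d(trait_ww.zts(), trait_d.zts())
    rows = []
    for zt in zts:
        ww = trait_ww.data.loc[trait_ww.data["zt"] == zt, "value"].to_numpy()
        d = trait_d.data.loc[trait_d.data["zt"] == zt, "value"].to_numpy()
        if len(ww) < 2 or len(d) < 2:
            raise ValueError(f"need >=2 replicates per group at ZT{zt}")
        if ww.std(ddof=1) == 0 and d.std(ddof=1) == 0:
            if ww.mean() == d.mean():
                warnings.warn(f"zero pooled variance with equal means at ZT{zt}")
                t, p = 0.0, 0.5
            else:
                diff = d.mean() - ww.mean()
                t = np.inf * np.sign(diff)
                want = -1 if alternative == "less" else 1
                p = 0.0 if np.sign(diff) == want else 1.0
        else:
            res = stats.ttest_ind(d, ww, equal_var=True, alternative=alternative)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"zt": zt, "t": t, "p": p, "sig_p01": p < 0.01, "sig_p05": p < 0.05}
        )
    return pd.DataFrame(rows).set_index("zt")


def expand_trait_to_samples(
    trait: TraitSeries,
    samples: pd.DataFrame,
    interpolate_missing: bool = False,
) -> pd.Series:
    """Per-ZT trait means broadcast onto an expression sample axis.

    Every replicate column of a ZT receives that ZT's trait mean,
    preserving the full sample alignment.  A ZT sampled in the expression
    design but absent from the trait series raises (naming the ZT) unless
    ``interpolate_missing`` enables linear interpolation over ZT.
    """
    means = trait.summary()["mean"]
    zts_needed = np.sort(samples["zt"].unique())
    missing = [z for z in zts_needed if z not in means.index]
    if missing and not interpolate_missing:
        raise ValueError(
            f"trait {trait.trait!r} lacks ZT(s) {missing}; "
            "pass interpolate_missing=True to interpolate"
        )
    if missing:
        vals = np.interp(zts_needed, means.index.to_numpy(), means.to_numpy())
        means = pd.Series(vals, index=zts_needed)
    return samples["zt"].map(means).astype(float)


def module_trait_correlation(
    eigengenes: EigengeneSet,
    traits: list[TraitSeries],
    interpolate_missing: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and Student p) between each eigengene and each trait.

    Trait per-ZT means are expanded to the eigengene's sample axis (both
    replicates of a ZT get the ZT mean).  Returns (r, p) DataFrames indexed
    by module with one column per trait.
    """
    n = eigengenes.me.shape[1]
    r = pd.DataFrame(index=eigengenes.me.index, dtype=float)
    p = pd.DataFrame(index=eigengenes.me.index, dtype=float)
    for trait in traits:
        y = expand_trait_to_samples(
            trait, eigengenes.samples, interpolate_missing
        ).to_numpy()
        for m in eigengenes.me.index:
            x = eigengenes.me.loc[m].to_numpy(dtype=float)
            rr, pp = _pearson_with_p(x, y)
            r.at[m, trait.trait] = rr
            p.at[m, trait.trait] = pp
    return r, p


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    n = len(x)
    rr = float(np.corrcoef(x, y)[0, 1])
    rr = max(-1.0, min(1.0, rr))
    if abs(rr) == 1.0:
        return rr, 0.0
    t = rr * np.sqrt(n - 2) / np.sqrt(1.0 - rr**2)
    return rr, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def gene_significance(
    em: ExpressionMatrix, trait: TraitSeries, interpolate_missing: bool = False
) -> pd.Series:
    """GS_g = |cor(x_g, expanded trait means)|, in [0, 1].

    Zero-variance genes are reported as missing (NaN).
    """
    y = expand_trait_to_samples(trait, em.samples, interpolate_missing).to_numpy()
    x = em.values.to_numpy(dtype=float)
    xs = x.std(axis=1)
    ys = y.std()
    if ys == 0:
        raise ValueError("trait has zero variance over the sample axis")
    xz = x - x.mean(axis=1, keepdims=True)
    yz = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xz @ yz) / (len(y) * xs * ys)
    gs = np.abs(np.clip(r, -1.0, 1.0))
    gs[xs == 0] = np.nan
    return pd.Series(gs, index=em.gene_ids, name=f"GS_{trait.trait}")


def gs_mm_correlation(
    gs: pd.Series, mm: pd.DataFrame, module: int, modules
) -> tuple[float, float]:
    """Pearson r (with p) between GS and |MM| over one module's genes.

    A significant positive r means the module's hub genes are also the
    genes most correlated with the physiology measure.
    """
    genes = [g for g in modules.genes_in(module) if g in gs.index and g in mm.index]
    if len(genes) < 3:
        raise ValueError("module needs at least 3 genes with GS and MM")
    x = gs.loc[genes].to_numpy(dtype=float)
    y = np.abs(mm.loc[genes, module].to_numpy(dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    return _pearson_with_p(x, y)
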