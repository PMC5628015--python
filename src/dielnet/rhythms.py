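"""Nonparametric rhythm detection and drought-responsive gene selection.

The detector compares each gene's time course against a family of
phase-shifted cosine reference waveforms using Kendall's S (concordant
minus discordant pairs).  Because the references take tied values — the
same cosine value recurs across days, at symmetric phases, and across
replicates — the null distribution of S under random permutation of the
data is that of a Jonckheere-Terpstra-type statistic with a tied grouping;
it is computed exactly by dynamic programming over Gaussian binomial
coefficients (the generating polynomial of cross-group inversion counts).

Per reference the two-sided exact p is Bonferroni-adjusted for the number
of distinct reference shapes (antiphase pairs are a single shape up to
sign); per gene the minimum over references is kept, phase (LAG) is the
phase of the best-matching reference, and amplitude (AMP) comes from a
fixed-period least-squares cosinor fit on the FPKM scale.  Benjamini-
Hochberg q-values are computed across genes within each condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, SCALE_FPKM
from .network import ModuleAssignment

EXACT_LIMIT_DEFAULT = 26


# ---------------------------------------------------------------------------
# reference waveforms
# ---------------------------------------------------------------------------

@dataclass
class ReferenceWaveformSet:
    """Cosine references evaluated on the sampling design.

    ``values`` is (n_references x n_samples): reference r at sample j is
    cos(2 pi (t_j - phase_r) / period).  Replicate columns of a ZT share the
    reference value, producing tied reference ranks.
    """

    period: float
    phases: np.ndarray
    times: np.ndarray
    values: np.ndarray = field(repr=False)

    @property
    def n_references(self) -> int:
        return len(self.phases)

    @property
    def n_families(self) -> int:
        """Distinct shapes up to sign: antiphase pairs count once."""
        paired = set()
        fams = 0
        for i, ph in enumerate(self.phases):
            if i in paired:
                continue
            anti = (ph + self.period / 2.0) % self.period
            j = np.flatnonzero(np.isclose(self.phases, anti))
            if len(j) and j[0] != i:
                paired.add(int(j[0]))
            fams += 1
        return fams

    def tie_pattern(self, ref_index: int) -> tuple[int, ...]:
        """Sizes of the tied groups of one reference's values, in rank order."""
        v = np.round(self.values[ref_index], 9)
        uniq, counts = np.unique(v, return_counts=True)
        return tuple(int(c) for c in counts)


def build_references(
    times: np.ndarray | list[float],
    period: float = 24.0,
    phase_step: float | None = None,
) -> ReferenceWaveformSet:
    """Cosine references at every phase offset on the sampling grid.

    ``times`` are the ZT hours of every sample column (replicates repeat
    their ZT).  ``phase_step`` defaults to the sampling interval and must
    divide the period.  Phases are anchored at the first time point modulo
    the period, so a noise-free cosine peaking at a sampled ZT matches one
    reference exactly.
    """
    t = np.asarray(times, dtype=float)
    uniq = np.unique(t)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct time points")
    if phase_step is None:
        phase_step = float(np.min(np.diff(uniq)))
    n_steps = period / phase_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"phase_step {phase_step} does not divide period {period}")
    n_steps = int(round(n_steps))
    anchor = float(uniq[0]) % period
    phases = np.sort((anchor + phase_step * np.arange(n_steps)) % period)
    values = np.cos(2.0 * np.pi * (t[None, :] - phases[:, None]) / period)
    return ReferenceWaveformSet(period, phases, t, values)


# ---------------------------------------------------------------------------
# exact null distribution of Kendall S against a tied reference
# ---------------------------------------------------------------------------

def _gaussian_binomial(a: int, b: int) -> list[int]:
    """Coefficients of the Gaussian binomial [a+b choose b]_q.

    Coefficient w counts interleavings of a old and b new (mutually tied)
    elements with exactly w (old, new) inversions.
    """
    @lru_cache(maxsize=None)
    def gb(a_: int, b_: int) -> tuple[int, ...]:
        if a_ == 0 or b_ == 0:
            return (1,)
        # [a+b, b]_q = [a-1+b, b]_q + q^a [a+b-1, b-1]_q
        p1 = gb(a_ - 1, b_)
        p2 = gb(a_, b_ - 1)
        out = [0] * (a_ * b_ + 1)
        for i, c in enumerate(p1):
            out[i] += c
        for i, c in enumerate(p2):
            out[i + a_] += c
        return tuple(out)

    return list(gb(a, b))


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a:
            for j, b in enumerate(q):
                if b:
                    out[i + j] += a * b
    return out


def exact_null_distribution(
    n_points: int,
    tie_pattern: tuple[int, ...] | list[int],
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Exact pmf of Kendall S between untied data and a tied reference.

    ``tie_pattern`` gives the sizes of the reference's tied groups; pairs
    within a tied group contribute nothing to S, so S = 2K - M where K is
    the number of concordant cross-group pairs and M the total number of
    cross-group pairs.  K is distributed as the cross-group inversion count
    of a uniformly random arrangement, whose generating polynomial is a
    product of Gaussian binomials.

    Returns (support, probabilities, is_exact).  Above ``exact_limit``
    points a normal approximation with continuity correction is used and
    flagged via ``is_exact = False``.
    """
    pattern = tuple(int(g) for g in tie_pattern)
    if sum(pattern) != n_points:
        raise ValueError("tie_pattern sizes must sum to n_points")
    m_pairs = (n_points**2 - sum(g**2 for g in pattern)) // 2
    if n_points > exact_limit:
        # Jonckheere-Terpstra normal approximation
        var_jt = (
            n_points**2 * (2 * n_points + 3)
            - sum(g**2 * (2 * g + 3) for g in pattern)
        ) / 72.0
        support = np.arange(-m_pairs, m_pairs + 1, 2, dtype=float)
        sd = 2.0 * math.sqrt(var_jt)
        upper = stats.norm.cdf((support + 1) / sd)
        lower = stats.norm.cdf((support - 1) / sd)
        probs = upper - lower
        probs /= probs.sum()
        return support, probs, False
    poly = [1]
    placed = 0
    for g in pattern:
        poly = _poly_mul(poly, _gaussian_binomial(placed, g))
        placed += g
    total = sum(poly)
    probs = np.array([c / total for c in poly], dtype=float)
    support = 2 * np.arange(len(poly), dtype=float) - m_pairs
    return support, probs, True


@lru_cache(maxsize=64)
def _null_tail(tie_pattern: tuple[int, ...], exact_limit: int) -> tuple:
    n = sum(tie_pattern)
    support, probs, is_exact = exact_null_distribution(n, tie_pattern, exact_limit)
    # tail[i] = P(S >= support[i])
    tail = np.cumsum(probs[::-1])[::-1]
    return support, tail, is_exact


def two_sided_p(s: float, tie_pattern: tuple[int, ...], exact_limit: int = EXACT_LIMIT_DEFAULT) -> float:
    """P(|S| >= |s|) under the exact permutation null (symmetric)."""
    support, tail, _ = _null_tail(tuple(tie_pattern), exact_limit)
    a = abs(float(s))
    if a == 0:
        return 1.0
    idx = np.searchsorted(support, a - 1e-9)
    if idx >= len(support):
        return 0.0
    return float(min(1.0, 2.0 * tail[idx]))


# ---------------------------------------------------------------------------
# the cycling test
# ---------------------------------------------------------------------------

def _pair_signs(values: np.ndarray) -> np.ndarray:
    """Upper-triangle sign(v_i - v_j) flattened, for each row of ``values``."""
    n = values.shape[-1]
    iu, ju = np.triu_indices(n, k=1)
    return np.sign(values[..., iu] - values[..., ju])


def kendall_s(x: np.ndarray, ref: np.ndarray) -> float:
    """Concordant-minus-discordant pair count between one series and a reference."""
    return float(np.sum(_pair_signs(x[None, :]) * _pair_signs(ref[None, :])))


@dataclass
class CosinorFit:
    amplitude: float
    phase: float
    mesor: float


def estimate_amplitude(
    times: np.ndarray | list[float],
    values: np.ndarray | list[float],
    period: float = 24.0,
) -> CosinorFit:
    """Fixed-period least-squares cosinor fit.

    Fits y = m + a cos(2 pi t / period) + b sin(2 pi t / period); the
    amplitude is sqrt(a^2 + b^2) (half the peak-to-trough swing) and the
    phase is the hour of the fitted peak in [0, period).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("cosinor needs at least 4 distinct time points")
    w = 2.0 * np.pi * t / period
    design = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    m, a, b = coef
    amp = float(np.hypot(a, b))
    phase = float((math.atan2(b, a) * period / (2.0 * np.pi)) % period)
    return CosinorFit(amp, phase, float(m))


def jtk_cycle(
    em: ExpressionMatrix,
    refs: ReferenceWaveformSet | None = None,
    q_cut: float = 0.01,
    period: float = 24.0,
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> pd.DataFrame:
    """Rank-based cycling test of every gene against cosine references.

    Runs on FPKM-scale values (ranks are invariant to monotone transforms,
    so the p-values would be identical on log2 data; the amplitude — and the
    amplitude-difference selection threshold — are interpreted in FPKM
    units).  Returns one row per gene: ``tau`` (S / max S at the best
    reference), ``p`` (Bonferroni over reference shapes, min over
    references), ``q`` (Benjamini-Hochberg over genes), ``period``, ``lag``
    (phase of the best reference, hours), ``amp`` (cosinor amplitude),
    ``rhythmic`` (q < ``q_cut``).
    """
    if em.scale != SCALE_FPKM:
        raise ValueError("jtk_cycle expects FPKM-scale values")
    times = em.samples["zt"].to_numpy(dtype=float)
    span = times.max() - times.min()
    if span < 2 * period - (period / 2):
        warnings.warn("less than two full cycles of data; power will be poor")
    if refs is None:
        refs = build_references(times, period=period)
    x = em.values.to_numpy(dtype=float)
    xs = _pair_signs(x)  # genes x pairs
    # round the references so cosine values that are analytically equal
    # (symmetric phases, repeated days, replicates) tie exactly
    rs = _pair_signs(np.round(refs.values, 9))  # refs x pairs
    s = xs @ rs.T  # genes x refs
    patterns = [refs.tie_pattern(r) for r in range(refs.n_references)]
    max_s = np.array(
        [
            (len(times) ** 2 - sum(g**2 for g in pat)) // 2
            for pat in patterns
        ],
        dtype=float,
    )
    n_fam = refs.n_families
    p_ref = np.empty_like(s, dtype=float)
    for r, pat in enumerate(patterns):
        for gi in range(s.shape[0]):
            p_ref[gi, r] = two_sided_p(s[gi, r], pat, exact_limit)
    p_adj = np.minimum(1.0, p_ref * n_fam)
    best = np.argmax(s, axis=1)
    gene_p = p_adj.min(axis=1)
    tau = s[np.arange(len(s)), best] / max_s[best]
    lag = refs.phases[best] % period
    amps = np.empty(len(s))
    for gi in range(len(s)):
        if np.ptp(x[gi]) == 0:
            amps[gi] = 0.0
            gene_p[gi] = 1.0
            tau[gi] = 0.0
        else:
            amps[gi] = estimate_amplitude(times, x[gi], period).amplitude
    q = multipletests(gene_p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "tau": tau,
            "p": gene_p,
            "q": q,
            "period": period,
            "lag": lag,
            "amp": amps,
            "rhythmic": q < q_cut,
        },
        index=em.gene_ids,
    )
    return out


# ---------------------------------------------------------------------------
# drought-responsive selection
# ---------------------------------------------------------------------------

def select_drought_responsive(
    rhythm_ww: pd.DataFrame,
    rhythm_d: pd.DataFrame,
    modules: ModuleAssignment,
    modules_of_interest: list[int] | None,
    amp_cut: float = 10.0,
    q_cut: float = 0.01,
) -> pd.DataFrame:
    """Two-criterion candidate selection within trait-correlated modules.

    gained_rhythm: not rhythmic well-watered (q >= q_cut) but rhythmic under
    drought (q < q_cut).  amplitude_change: rhythmic under both conditions
    with |AMP_D - AMP_WW| > ``amp_cut`` (the signed difference is recorded).
    ``modules_of_interest`` is the caller-supplied list of drought-network
    modules correlated with the physiology (an empty/None list warns and
    uses all modules).
    """
    universe = rhythm_ww.index.intersection(rhythm_d.index)
    labels = modules.labels.reindex(universe).fillna(0).astype(int)
    if not modules_of_interest:
        warnings.warn("empty module filter; using all modules")
        modules_of_interest = modules.module_ids
    keep = labels.isin(modules_of_interest)
    rows = []
    for g in universe[keep]:
        q_ww, q_d = rhythm_ww.at[g, "q"], rhythm_d.at[g, "q"]
        amp_ww, amp_d = rhythm_ww.at[g, "amp"], rhythm_d.at[g, "amp"]
        delta = amp_d - amp_ww
        if q_ww >= q_cut and q_d < q_cut:
            crit = "gained_rhythm"
        elif q_ww < q_cut and q_d < q_cut and abs(delta) > amp_cut:
            crit = "amplitude_change"
        else:
            continue
        rows.append(
            {
                "gene": g,
                "module": int(labels[g]),
                "criterion": crit,
                "amp_ww": amp_ww,
                "amp_d": amp_d,
                "delta": delta,
            }
        )
    cols = ["gene", "module", "criterion", "amp_ww", "amp_d", "delta"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def rank_candidates_by_mm(
    candidates: pd.DataFrame, mm: pd.DataFrame, top_n: int = 3
) -> pd.DataFrame:
    """Top-n candidates per module by |module membership|.

    Ties in |MM| break lexicographically by gene id.
    """
    rows = []
    for module, grp in candidates.groupby("module"):
        scored = []
        for g in grp.index:
            val = abs(mm.at[g, module]) if (g in mm.index and module in mm.columns) else np.nan
            scored.append((g, val))
        scored.sort(key=lambda t: (-(t[1] if np.isfinite(t[1]) else -np.inf), str(t[0])))
        for rank, (g, val) in enumerate(scored[:top_n], start=1):
            rows.append(
                {
                    "gene": g,
                    "module": module,
                    "rank": rank,
                    "abs_mm": val,
                    "criterion": grp.at[g, "criterion"],
                }
            )
    cols = ["gene", "module", "rank", "abs_mm", "criterion"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")
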