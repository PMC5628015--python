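"""Seeded synthetic diel drought-experiment generator with ground truth.

Emulates the study design the analysis assumes: leaf transcriptomes sampled
every 4 h over 48 h (ZT1-ZT45) under well-watered (WW) and droughted (D)
conditions with two biological replicates per time point, module-structured
cosine rhythms with shared phases, drought-induced amplitude scaling,
phase shifts and gained/lost rhythmicity, physiology trait waveforms
coupled to specific modules, and NanoString-style probe-count tables with
occasional spurious single-cell spikes.

Every generated gene carries a truth record (module, per-condition
rhythmicity, amplitude in FPKM units, phase) so downstream recovery tests
can score themselves without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .qc import ProbeCountTable
from .traits import TraitSeries


@dataclass(frozen=True)
class DroughtEffect:
    """Per-module drought response applied to the D condition."""

    amp_scale: float = 1.0
    phase_shift_h: float = 0.0
    gain_rhythm_fraction: float = 0.0
    lose_rhythm_fraction: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.gain_rhythm_fraction, self.lose_rhythm_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("gain/lose fractions must lie in [0, 1]")
        if self.amp_scale < 0:
            raise ValueError("amp_scale must be non-negative")


def _default_drought_effects() -> dict[int, DroughtEffect]:
    return {
        1: DroughtEffect(amp_scale=1.6),
        2: DroughtEffect(phase_shift_h=4.0),
        3: DroughtEffect(gain_rhythm_fraction=0.3),
        4: DroughtEffect(lose_rhythm_fraction=0.3),
    }


def _default_trait_coupling() -> dict[str, tuple[int, int]]:
    return {"A": (1, 1), "gs": (2, 1), "FvFm_prime": (3, -1), "NSC": (5, 1)}


_TRAIT_BASELINE = {"A": 10.0, "gs": 300.0, "FvFm_prime": 0.7, "NSC": 0.10}
_TRAIT_UNITS = {
    "A": "umol CO2 m-2 s-1",
    "gs": "mmol H2O m-2 s-1",
    "FvFm_prime": "dimensionless",
    "NSC": "dry-weight fraction",
}
# mild-drought direction of each trait's mean level in the D condition
_TRAIT_DROUGHT_SCALE = {"A": 0.9, "gs": 0.6, "FvFm_prime": 1.1, "NSC": 1.3}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults reproduce the two-day, 4-hour-resolution design: 12 time
    points (ZT1..ZT45) x 2 conditions x 2 replicates, 24-h cosine rhythms
    with module phases spread uniformly over the day, lognormal FPKM
    baselines centred near 100, relative amplitude 0.5 and 10% relative
    residual noise.
    """

    n_modules: int = 5
    genes_per_module: int = 100
    n_noise_genes: int = 250
    timepoints: tuple[float, ...] = tuple(range(1, 46, 4))
    n_replicates: int = 2
    period: float = 24.0
    module_phases: tuple[float, ...] | None = None
    baseline_fpkm_log_mean: float = math.log(100.0)
    baseline_fpkm_log_sd: float = 0.25
    amplitude_rel: float = 0.5
    noise_sd_rel: float = 0.1
    drought_effects: dict[int, DroughtEffect] = field(
        default_factory=_default_drought_effects
    )
    trait_coupling: dict[str, tuple[int, int]] = field(
        default_factory=_default_trait_coupling
    )
    trait_amp_rel: float = 0.3
    trait_noise_rel: float = 0.1
    trait_n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules <= 0 or self.genes_per_module <= 0:
            raise ValueError("module dimensions must be positive")
        if self.n_noise_genes < 0 or self.n_replicates <= 0:
            raise ValueError("non-positive dimensions")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.amplitude_rel < 0:
            raise ValueError("amplitude_rel must be >= 0")
        if self.module_phases is None:
            self.module_phases = tuple(
                (self.period * i / self.n_modules) % self.period
                for i in range(self.n_modules)
            )
        if len(self.module_phases) != self.n_modules:
            raise ValueError("need one phase per module")
        for ph in self.module_phases:
            if not (0.0 <= ph < self.period):
                raise ValueError(f"phase {ph} outside [0, period)")
        for m in self.drought_effects:
            if not (1 <= m <= self.n_modules):
                raise ValueError(f"drought effect for unknown module {m}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: one record per gene plus trait couplings.

    ``genes`` columns: module (0 = unstructured noise gene), rhythmic_ww,
    rhythmic_d, amp_ww, amp_d (FPKM units; 0 iff not rhythmic), phase_ww,
    phase_d (hours), baseline (FPKM), drought_response in
    {none, gained_rhythm, lost_rhythm, amplitude_change, phase_shift}.
    """

    genes: pd.DataFrame
    trait_coupling: dict[str, tuple[int, int]]

    def labels_for_condition(self, condition: str) -> pd.Series:
        """Module labels as observable in one condition's network.

        A gene planted in a module but non-rhythmic in this condition has a
        flat (noise-like) profile there and is reported as unassigned (0).
        """
        flag = "rhythmic_ww" if condition == "WW" else "rhythmic_d"
        labels = self.genes["module"].where(self.genes[flag], 0)
        return labels.astype(int)

    def write(self, path: str | Path) -> None:
        df = self.genes.copy()
        df.index.name = "gene_id"
        df.to_csv(Path(path), sep="\t")


def _sample_ids(condition: str, timepoints, n_replicates) -> list[tuple]:
    out = []
    for zt in timepoints:
        for rep in range(1, n_replicates + 1):
            day = 3 if zt <= 21 else 4
            out.append((f"{condition}_ZT{int(zt):02d}_r{rep}", condition, zt, day, f"r{rep}"))
    return out


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[TraitSeries], SyntheticTruth]:
    """Generate (WW expression, D expression, trait series, truth).

    The FPKM value of rhythmic gene g at time t is
    max(0, B_g (1 + A_rel cos(2 pi (t - phi_m) / period)) + eps) with
    eps ~ Normal(0, noise_sd_rel * B_g); the D matrix applies the module's
    amp_scale / phase_shift and converts designated fractions of genes to
    gained/lost rhythm.  Traits are cosine waveforms sharing the coupled
    module's phase (sign-flipped for negative coupling) with per-replicate
    noise.  Identical config + seed gives bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_mod_genes = config.n_modules * config.genes_per_module
    n_genes = n_mod_genes + config.n_noise_genes
    gene_ids = [f"G{idx:05d}" for idx in range(n_genes)]
    modules = np.zeros(n_genes, dtype=int)
    for m in range(config.n_modules):
        modules[m * config.genes_per_module : (m + 1) * config.genes_per_module] = m + 1

    baselines = rng.lognormal(
        config.baseline_fpkm_log_mean, config.baseline_fpkm_log_sd, size=n_genes
    )
    rhythmic_ww = modules > 0
    rhythmic_d = modules > 0
    amp_rel_ww = np.where(rhythmic_ww, config.amplitude_rel, 0.0)
    amp_rel_d = amp_rel_ww.copy()
    phase_ww = np.zeros(n_genes)
    phase_d = np.zeros(n_genes)
    response = np.array(["none"] * n_genes, dtype=object)
    for m in range(1, config.n_modules + 1):
        sel = modules == m
        phase_ww[sel] = config.module_phases[m - 1]
        phase_d[sel] = config.module_phases[m - 1]
        eff = config.drought_effects.get(m)
        if eff is None:
            continue
        idx = np.flatnonzero(sel)
        if eff.amp_scale != 1.0:
            amp_rel_d[idx] = amp_rel_ww[idx] * eff.amp_scale
            response[idx] = "amplitude_change"
        if eff.phase_shift_h != 0.0:
            phase_d[idx] = (phase_ww[idx] + eff.phase_shift_h) % config.period
            response[idx] = "phase_shift"
        n_gain = int(round(eff.gain_rhythm_fraction * len(idx)))
        if n_gain:
            gained = rng.choice(idx, size=n_gain, replace=False)
            rhythmic_ww[gained] = False
            amp_rel_ww[gained] = 0.0
            response[gained] = "gained_rhythm"
        n_lose = int(round(eff.lose_rhythm_fraction * len(idx)))
        if n_lose:
            pool = np.setdiff1d(idx, np.flatnonzero(~rhythmic_ww))
            lost = rng.choice(pool, size=min(n_lose, len(pool)), replace=False)
            rhythmic_d[lost] = False
            amp_rel_d[lost] = 0.0
            response[lost] = "lost_rhythm"

    def _matrix(condition, amp_rel, phase, rhythmic):
        ids = _sample_ids(condition, config.timepoints, config.n_replicates)
        t = np.array([rec[2] for rec in ids], dtype=float)
        cosine = np.cos(
            2.0 * np.pi * (t[None, :] - phase[:, None]) / config.period
        )
        mean = baselines[:, None] * (
            1.0 + np.where(rhythmic[:, None], amp_rel[:, None], 0.0) * cosine
        )
        noise = rng.normal(0.0, 1.0, size=mean.shape) * (
            config.noise_sd_rel * baselines[:, None]
        )
        values = np.clip(mean + noise, 0.0, None)
        meta = pd.DataFrame(
            ids, columns=["sample_id", "condition", "zt", "day", "replicate"]
        ).set_index("sample_id")
        vdf = pd.DataFrame(values, index=gene_ids, columns=meta.index)
        return ExpressionMatrix(vdf, meta, scale="fpkm", note=f"synthetic {condition}")

    em_ww = _matrix("WW", amp_rel_ww, phase_ww, rhythmic_ww)
    em_d = _matrix("D", amp_rel_d, phase_d, rhythmic_d)

    traits: list[TraitSeries] = []
    for trait, (mod, sign) in config.trait_coupling.items():
        base = _TRAIT_BASELINE.get(trait, 1.0)
        for condition in ("WW", "D"):
            level = base * (
                _TRAIT_DROUGHT_SCALE.get(trait, 1.0) if condition == "D" else 1.0
            )
            ph = config.module_phases[mod - 1]
            eff = config.drought_effects.get(mod)
            if condition == "D" and eff is not None:
                ph = (ph + eff.phase_shift_h) % config.period
            rows = []
            for zt in config.timepoints:
                wave = level * (
                    1.0
                    + sign
                    * config.trait_amp_rel
                    * math.cos(2.0 * math.pi * (zt - ph) / config.period)
                )
                noise = rng.normal(
                    0.0, config.trait_noise_rel * level, size=config.trait_n_replicates
                )
                for rep in range(config.trait_n_replicates):
                    val = wave + noise[rep]
                    if trait == "FvFm_prime":
                        val = min(max(val, 0.0), 1.0)
                    rows.append({"zt": zt, "replicate": f"r{rep + 1}", "value": val})
            traits.append(
                TraitSeries(
                    trait,
                    condition,
                    pd.DataFrame(rows),
                    units=_TRAIT_UNITS.get(trait, ""),
                )
            )

    truth_df = pd.DataFrame(
        {
            "module": modules,
            "rhythmic_ww": rhythmic_ww,
            "rhythmic_d": rhythmic_d,
            "amp_ww": baselines * amp_rel_ww,
            "amp_d": baselines * amp_rel_d,
            "phase_ww": np.where(rhythmic_ww, phase_ww, 0.0),
            "phase_d": np.where(rhythmic_d, phase_d, 0.0),
            "baseline": baselines,
            "drought_response": response,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SyntheticTruth(truth_df, dict(config.trait_coupling))
    return em_ww, em_d, traits, truth


# ---------------------------------------------------------------------------
# probe-count (NanoString-style) simulation
# ---------------------------------------------------------------------------

@dataclass
class ProbeSimConfig:
    """Probe-count table generator settings.

    Defaults emulate a validation panel: 33 endogenous probes + 3 flat
    housekeeping probes x (2 conditions x 12 time points x 5 biological
    replicates) samples arranged in sets of 12 with one pooled-RNA
    reference sample per set, a handful of technical-replicate pairs, and a
    small fraction of probe x sample cells corrupted by a 10x spike.
    """

    n_probes: int = 33
    n_housekeeping: int = 3
    n_bio_replicates: int = 5
    count_scale: float = 5.0
    set_size: int = 12
    set_factor_log_sd: float = 0.15
    sample_factor_log_sd: float = 0.1
    spike_fraction: float = 0.01
    spike_factor: float = 10.0
    n_technical_pairs: int = 4
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_fraction <= 1.0):
            raise ValueError("spike_fraction must lie in [0, 1]")
        if self.n_housekeeping < 3:
            raise ValueError("need at least 3 housekeeping probes")


def simulate_probe_counts(
    truth: SyntheticTruth,
    config: SimulationConfig,
    probe_config: ProbeSimConfig | None = None,
) -> tuple[ProbeCountTable, pd.DataFrame]:
    """Probe x sample counts with planted spikes; returns (table, spike mask).

    Counts are Poisson draws around scaled noise-free expression profiles,
    multiplied by per-set (cartridge) and per-sample factors that the
    normalization steps are meant to remove.  A ``spike_fraction`` of
    endogenous probe x sample cells is multiplied by ``spike_factor`` and
    recorded in the returned boolean mask.  Housekeeping probes are flat
    and never spiked.
    """
    pc = probe_config or ProbeSimConfig()
    rng = np.random.default_rng(pc.seed)
    g = truth.genes
    # Panel probes must keep relative diel amplitude moderate: a spike of
    # ``spike_factor`` on a trough cell of a probe with relative amplitude A
    # is only separable from the probe's own across-sample spread when
    # spike_factor * (1 - A) clears the peak (1 + A); A <= 0.6 keeps every
    # 10x spike identifiable by the across-sample modified Z.
    amp_rel = np.maximum(g["amp_ww"], g["amp_d"]) / g["baseline"]
    eligible = g[(g["rhythmic_ww"] & g["rhythmic_d"]) & (amp_rel <= 0.6)]
    if len(eligible) < pc.n_probes:
        raise ValueError("not enough moderate-amplitude rhythmic genes for the panel")
    probe_genes = list(eligible.index[: pc.n_probes])
    hk_ids = [f"HK{i + 1}" for i in range(pc.n_housekeeping)]
    # low / medium / high flat expression levels for the housekeeping set
    hk_levels = np.exp(
        np.linspace(
            config.baseline_fpkm_log_mean - 1.0,
            config.baseline_fpkm_log_mean + 1.0,
            pc.n_housekeeping,
        )
    )

    samples = []
    for condition in ("WW", "D"):
        for zt in config.timepoints:
            for rep in range(1, pc.n_bio_replicates + 1):
                samples.append((f"N_{condition}_ZT{int(zt):02d}_b{rep}", condition, zt, rep))
    sample_ids = [s[0] for s in samples]

    def _mean_profile(gene: str, condition: str, zt: float) -> float:
        rec = truth.genes.loc[gene]
        amp = rec["amp_ww"] if condition == "WW" else rec["amp_d"]
        ph = rec["phase_ww"] if condition == "WW" else rec["phase_d"]
        return float(
            rec["baseline"]
            + amp * math.cos(2.0 * math.pi * (zt - ph) / config.period)
        )

    mean = np.zeros((pc.n_probes + pc.n_housekeeping, len(samples)))
    for j, (_, condition, zt, _) in enumerate(samples):
        for i, g in enumerate(probe_genes):
            mean[i, j] = max(_mean_profile(g, condition, zt), 0.1)
        for h in range(pc.n_housekeeping):
            mean[pc.n_probes + h, j] = hk_levels[h]

    n_sets = math.ceil(len(samples) / pc.set_size)
    set_of = np.repeat(np.arange(n_sets), pc.set_size)[: len(samples)]
    set_factor = rng.lognormal(0.0, pc.set_factor_log_sd, size=n_sets)
    sample_factor = rng.lognormal(0.0, pc.sample_factor_log_sd, size=len(samples))
    lam = mean * pc.count_scale * set_factor[set_of] * sample_factor[None, :]

    spikes = np.zeros_like(lam, dtype=bool)
    endo = rng.random((pc.n_probes, len(samples))) < pc.spike_fraction
    spikes[: pc.n_probes] = endo
    lam = np.where(spikes, lam * pc.spike_factor, lam)
    counts = rng.poisson(lam).astype(float)

    probe_index = pd.Index(probe_genes + hk_ids, name="probe")
    counts_df = pd.DataFrame(counts, index=probe_index, columns=sample_ids)
    spikes_df = pd.DataFrame(spikes, index=probe_index, columns=sample_ids)

    meta = pd.DataFrame(
        {
            "condition": [s[1] for s in samples],
            "zt": [s[2] for s in samples],
            "replicate": [s[3] for s in samples],
            "set": set_of,
            "is_reference": False,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # one pooled-RNA reference column per set (CodeSet normalization row)
    pooled = mean.mean(axis=1)
    ref_rows, ref_counts = [], []
    for s in range(n_sets):
        sid = f"REF_set{s}"
        lam_ref = pooled * pc.count_scale * set_factor[s]
        ref_counts.append(rng.poisson(lam_ref).astype(float))
        ref_rows.append(
            {"sample_id": sid, "condition": "POOL", "zt": np.nan,
             "replicate": 0, "set": s, "is_reference": True}
        )
    ref_df = pd.DataFrame(
        np.column_stack(ref_counts),
        index=probe_index,
        columns=[r["sample_id"] for r in ref_rows],
    )
    counts_df = pd.concat([counts_df, ref_df], axis=1)
    spikes_df = pd.concat(
        [spikes_df, pd.DataFrame(False, index=probe_index, columns=ref_df.columns)],
        axis=1,
    )
    meta = pd.concat([meta, pd.DataFrame(ref_rows).set_index("sample_id")])

    # technical replicates: duplicate measurements of a few bio samples
    pairing = []
    chosen = rng.choice(len(samples), size=min(pc.n_technical_pairs, len(samples)), replace=False)
    for j in sorted(chosen):
        sid = sample_ids[j]
        tid = f"{sid}_tr"
        lam_t = mean[:, j] * pc.count_scale * set_factor[set_of[j]] * sample_factor[j]
        spike_t = np.zeros(len(probe_index), dtype=bool)
        endo_t = rng.random(pc.n_probes) < pc.spike_fraction
        spike_t[: pc.n_probes] = endo_t
        lam_t = np.where(spike_t, lam_t * pc.spike_factor, lam_t)
        counts_df[tid] = rng.poisson(lam_t).astype(float)
        spikes_df[tid] = spike_t
        meta.loc[tid] = meta.loc[sid]
        pairing.append((sid, tid))

    table = ProbeCountTable(
        counts=counts_df,
        samples=meta,
        housekeeping=hk_ids,
        technical_pairs=pairing,
    )
    return table, spikes_df


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_experiment(
    outdir: str | Path,
    em_ww: ExpressionMatrix,
    em_d: ExpressionMatrix,
    traits: list[TraitSeries],
    truth: SyntheticTruth,
) -> None:
    """Write the simulated experiment as tab-delimited UTF-8 tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    em_ww.write(out / "expression_ww.tsv", out / "samples_ww.tsv")
    em_d.write(out / "expression_d.tsv", out / "samples_d.tsv")
    rows = []
    for ts in traits:
        for _, rec in ts.data.iterrows():
            rows.append(
                {
                    "trait": ts.trait,
                    "condition": ts.condition,
                    "zt": rec["zt"],
                    "replicate": rec["replicate"],
                    "value": rec["value"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "traits.tsv", sep="\t", index=False)
    truth.write(out / "truth.tsv")
    with open(out / "trait_coupling.json", "w", encoding="utf-8") as fh:
        json.dump(truth.trait_coupling, fh, indent=1)
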