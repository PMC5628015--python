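"""Shared fixtures: one default synthetic experiment and its WW network."""

import numpy as np
import pandas as pd
import pytest

import dielnet as dn


@pytest.fixture(scope="session")
def default_experiment():
    cfg = dn.SimulationConfig(seed=11)
    return cfg, *dn.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def ww_pipeline(default_experiment):
    """Filtered/log WW matrix and its network products."""
    cfg, ww, d, traits, truth = default_experiment
    filtered, _ = dn.filter_low_expression(ww)
    logged = dn.log_transform(filtered)
    tom = dn.topological_overlap(dn.signed_adjacency(logged))
    modules, _ = dn.detect_modules(tom)
    merged = dn.merge_close_modules(logged, modules)
    eigengenes = dn.module_eigengenes(logged, merged)
    return {
        "config": cfg,
        "fpkm": filtered,
        "log": logged,
        "tom": tom,
        "modules": merged,
        "eigengenes": eigengenes,
        "traits": traits,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def probe_table(default_experiment):
    cfg, ww, d, traits, truth = default_experiment
    return dn.simulate_probe_counts(truth, cfg)


def make_expression(values, zts, condition="WW", scale="fpkm", reps_per_zt=1):
    """Small helper: ExpressionMatrix from a 2-D array and ZT list."""
    values = np.asarray(values, dtype=float)
    ids, meta = [], []
    rep_counter = {}
    for zt in zts:
        rep_counter[zt] = rep_counter.get(zt, 0) + 1
        r = rep_counter[zt]
        sid = f"{condition}_ZT{int(zt):02d}_r{r}"
        ids.append(sid)
        meta.append(
            {
                "sample_id": sid,
                "condition": condition,
                "zt": zt,
                "day": 3 if zt <= 21 else 4,
                "replicate": f"r{r}",
            }
        )
    genes = [f"g{i}" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=genes, columns=ids)
    mdf = pd.DataFrame(meta).set_index("sample_id")
    return dn.ExpressionMatrix(vdf, mdf, scale=scale)


def match_modules(detected_labels, truth_labels):
    """Map each planted module to the detected module with maximal overlap."""
    mapping = {}
    for planted in sorted(set(truth_labels) - {0}):
        genes = truth_labels.index[truth_labels == planted]
        hits = detected_labels.reindex(genes).value_counts()
        hits = hits[hits.index != 0]
        mapping[planted] = int(hits.idxmax()) if len(hits) else 0
    return mapping
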