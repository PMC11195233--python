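"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chirpsa as c
from chirpsa.features import BandWindow

GAMMA1_WINDOWS = (
    BandWindow("gamma1_itpc", "ITPC", (30, 57), (600, 1140)),
    BandWindow("gamma1_stp", "STP", (30, 57), (0, 2000)),
)

#: temporal exemplars plus occipital reference nodes (the SA normalisation
#: pools all nodes of the analysis set)
SA_NODE_SET = (
    "lh-superiortemporal", "lh-transversetemporal",
    "rh-superiortemporal", "rh-transversetemporal",
    "lh-lateraloccipital", "rh-lateraloccipital",
)


@pytest.fixture(scope="session")
def gamma1_plan():
    return c.build_band_plan(30, 57, 3)


@pytest.fixture(scope="session")
def full_plan():
    return c.build_wavelet_plan()


@pytest.fixture(scope="session")
def locked_subject_measures(full_plan):
    """One strongly chirp-locked subject with realistic background noise."""
    profile = c.SubjectProfile(
        subject_id="locked", kappa_chirp=100.0, chirp_amp=2.0,
        gamma_bg_power=0.5, alpha_power=1.0, noise_1f_scale=2.0)
    ep = c.synthesize_subject_epochs(
        profile, nodes=("lh-superiortemporal",), n_trials=60, seed=1,
    )["lh-superiortemporal"]
    return c.compute_measures(ep.data, full_plan)


def cohort_sa_means(seed: int, n_per_cell: int = 20, n_trials: int = 60):
    """Mean temporal SA ratio per group for a male-only synthetic cohort."""
    cfg = c.SyntheticCohortConfig(
        n_per_cell=n_per_cell, n_trials=n_trials, node_set=SA_NODE_SET,
        effect_map=c.default_effect_map(), seed=seed, sexes=("M",))
    cohort = c.generate_cohort(cfg)
    plan = c.build_band_plan(30, 57, 3)
    measures = {(sid, node): c.compute_measures(ep.data, plan)
                for sid, eps in cohort.iter_epochs()
                for node, ep in eps.items()}
    table = c.compute_feature_table(measures, windows=GAMMA1_WINDOWS)
    _, sa = c.compute_sa_ratio(table)
    merged = sa.merge(cohort.metadata, on="subject_id")
    return merged.groupby("group")["sa_ratio"].mean()


def null_feature_table(seed: int, n_per_cell: int = 10, nodes_per_region: int = 3):
    """Feature-level null cohort: pure subject + node noise, no effects."""
    rng = np.random.default_rng(seed)
    region_map = c.load_region_map()
    nodes_by_region: dict[str, list[str]] = {}
    for node, region in region_map.items():
        nodes_by_region.setdefault(region, []).append(node)
    rows, meta = [], []
    i = 0
    for group in ("FXS", "TDC"):
        for sex in ("M", "F"):
            for _ in range(n_per_cell):
                sid = f"S{i:03d}"
                i += 1
                meta.append({"subject_id": sid, "group": group, "sex": sex})
                subject_level = rng.standard_normal()
                for region in c.REGION_NAMES:
                    for node in sorted(nodes_by_region[region])[:nodes_per_region]:
                        rows.append({
                            "subject_id": sid, "node": node, "region": region,
                            "gamma1_stp": subject_level
                            + 0.5 * rng.standard_normal(),
                        })
    return pd.DataFrame(rows), pd.DataFrame(meta)
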