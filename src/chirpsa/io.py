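"""Epoch container I/O, trial rejection and the end-to-end pipeline driver.

Epoched node time series are stored in an HDF5 container with the layout
``/subjects/<subject>/<node>`` (trials x samples float datasets) and a JSON
metadata sidecar carrying group/sex assignments, the epoch window, sample
rate and seeds.  All tabular outputs are CSV.  ``run_pipeline`` chains
simulate -> epoch/reject -> time-frequency -> features (incl. the SA
ratio) -> transfer entropy -> statistics and writes a manifest with a
content hash per output, so identical configs reproduce identical trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import stats as st
from . import synthdata as sd
from . import timefreq as tf
from . import transfer_entropy as te

logger = logging.getLogger(__name__)

AMPLITUDE_UNIT = "microvolt-equivalent source a.u."
DEFAULT_REJECT_THRESHOLD = 120.0


# ----------------------------------------------------------------------
# epoching and rejection
# ----------------------------------------------------------------------

def epoch_continuous(
    recording: np.ndarray,
    event_times_ms,
    window: tuple[float, float] = (-500.0, 2750.0),
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Cut one epoch per event from a continuous 1-D recording.

    Events whose window exceeds the recording bounds are dropped with a
    warning.  Returns ``(n_events_kept, n_samples)`` with
    ``n_samples = span_ms * sample_rate / 1000``.
    """
    recording = np.asarray(recording, dtype=float)
    n_samples = int(round((window[1] - window[0]) * sample_rate / 1000.0))
    epochs = []
    for onset in np.atleast_1d(np.asarray(event_times_ms, dtype=float)):
        start = int(round((onset + window[0]) * sample_rate / 1000.0))
        if start < 0 or start + n_samples > recording.size:
            logger.warning("event at %.1f ms exceeds recording bounds; dropped",
                           onset)
            continue
        epochs.append(recording[start:start + n_samples])
    if not epochs:
        return np.empty((0, n_samples))
    return np.stack(epochs)


def reject_trials(
    epochs_by_node: dict[str, sd.NodeEpochs],
    threshold: float = DEFAULT_REJECT_THRESHOLD,
):
    """Drop trials whose peak |amplitude| exceeds ``threshold`` in any node.

    Returns ``(retained_epochs_by_node, report)`` where the report records
    totals, the threshold and the retained trial indices.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    nodes = list(epochs_by_node)
    n_trials = epochs_by_node[nodes[0]].n_trials
    bad = np.zeros(n_trials, dtype=bool)
    for node in nodes:
        bad |= np.abs(epochs_by_node[node].data).max(axis=1) > threshold
    retained_idx = np.flatnonzero(~bad)
    if retained_idx.size == 0:
        raise ValueError("all trials rejected; downstream measures undefined")
    retained = {
        node: sd.NodeEpochs(
            subject_id=ep.subject_id, node=node, data=ep.data[retained_idx],
            epoch_window=ep.epoch_window, sample_rate=ep.sample_rate)
        for node, ep in epochs_by_node.items()
    }
    report = {
        "subject_id": epochs_by_node[nodes[0]].subject_id,
        "trials_total": int(n_trials),
        "trials_rejected": int(bad.sum()),
        "threshold": float(threshold),
        "unit": AMPLITUDE_UNIT,
        "retained_indices": retained_idx.tolist(),
    }
    return retained, report


# ----------------------------------------------------------------------
# HDF5 container
# ----------------------------------------------------------------------

def write_epochs(path, cohort_iter, metadata: pd.DataFrame, extra_meta=None):
    """Write per-subject node epochs to ``<path>.h5`` + ``<path>.json``.

    ``cohort_iter`` yields ``(subject_id, {node: NodeEpochs})``.
    """
    path = Path(path)
    sidecar: dict = {"subjects": {}, "unit": AMPLITUDE_UNIT}
    sidecar.update(extra_meta or {})
    with h5py.File(path.with_suffix(".h5"), "w") as h5:
        grp = h5.create_group("subjects")
        for sid, nodes in cohort_iter:
            sgrp = grp.create_group(sid)
            for node, ep in nodes.items():
                sgrp.create_dataset(node, data=ep.data)
                sidecar["subjects"].setdefault(sid, {})
                sidecar["subjects"][sid][node] = {
                    "epoch_window": list(ep.epoch_window),
                    "sample_rate": ep.sample_rate,
                    "n_trials": int(ep.n_trials),
                }
    meta_records = metadata.to_dict(orient="records")
    sidecar["metadata"] = meta_records
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path):
    """Read the container back: ``({subject: {node: NodeEpochs}}, metadata)``."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    out: dict[str, dict[str, sd.NodeEpochs]] = {}
    with h5py.File(path.with_suffix(".h5"), "r") as h5:
        for sid, sgrp in h5["subjects"].items():
            out[sid] = {}
            for node, dset in sgrp.items():
                meta = sidecar["subjects"][sid][node]
                out[sid][node] = sd.NodeEpochs(
                    subject_id=sid, node=node, data=dset[()],
                    epoch_window=tuple(meta["epoch_window"]),
                    sample_rate=meta["sample_rate"],
                )
    metadata = pd.DataFrame(sidecar["metadata"])
    return out, metadata


def write_measures(path, measures: dict):
    """Write per-node TF measures to HDF5: ``/subject/node/{itpc,stp,ersp}``.

    ``measures`` maps ``(subject_id, node)`` to :class:`~chirpsa.TFMeasures`.
    """
    with h5py.File(path, "w") as h5:
        for (sid, node), m in measures.items():
            grp = h5.require_group(f"{sid}/{node}")
            grp.create_dataset("itpc_raw", data=m.itpc_raw)
            grp.create_dataset("itpc_corrected", data=m.itpc_corrected)
            grp.create_dataset("stp", data=m.stp)
            grp.create_dataset("ersp", data=m.ersp)
            grp.create_dataset("freqs", data=m.freqs)
            grp.create_dataset("times", data=m.times)
            grp.create_dataset("valid", data=m.valid)
            grp.attrs["r_critical"] = m.r_critical
            grp.attrs["n_trials"] = m.n_trials


def read_measures(path) -> dict:
    """Inverse of :func:`write_measures`."""
    out = {}
    with h5py.File(path, "r") as h5:
        for sid, sgrp in h5.items():
            for node, grp in sgrp.items():
                out[(sid, node)] = tf.TFMeasures(
                    freqs=grp["freqs"][()], times=grp["times"][()],
                    itpc_raw=grp["itpc_raw"][()],
                    itpc_corrected=grp["itpc_corrected"][()],
                    r_critical=float(grp.attrs["r_critical"]),
                    stp=grp["stp"][()], ersp=grp["ersp"][()],
                    n_trials=int(grp.attrs["n_trials"]),
                    valid=grp["valid"][()],
                )
    return out


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": None,                      # required
    "cohort": {
        "n_per_cell": 4,
        "n_trials": 60,
        "node_set": list(sd.REDUCED_NODE_SET),
        "use_default_effects": True,
    },
    "reject_threshold": DEFAULT_REJECT_THRESHOLD,
    "wavelet": {"f_min": 2.0, "f_max": 120.0, "step": 2.0,
                "c_min": 1.0, "c_max": 30.0},
    "time_step_ms": 5.0,
    "te": {"enabled": False, "q": 0.5, "n_boot": 100, "alpha": 0.01,
           "max_trials": 20},
    "stats": {"responses": ["gamma1_itpc", "gamma1_stp"]},
}


def validate_config(config: dict) -> dict:
    """Merge with defaults and enforce the seed requirement."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    if merged.get("seed") is None:
        raise ValueError("config must set an explicit integer seed")
    merged["seed"] = int(merged["seed"])
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["outputs"][path.name] = hashlib.sha256(
        path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Run simulate -> reject -> tfr -> features/SA -> (te) -> stats.

    Writes feature, SA, contrast (and optionally TE) CSVs plus a JSON
    manifest with a content hash per output.  Fully deterministic under the
    config's seed.
    """
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config, "config_hash": config_hash(config),
                "outputs": {}}
    stage = "simulate"
    try:
        ccfg = config["cohort"]
        cohort = sd.generate_cohort(sd.SyntheticCohortConfig(
            n_per_cell=ccfg["n_per_cell"],
            n_trials=ccfg["n_trials"],
            node_set=tuple(ccfg["node_set"]),
            effect_map=(sd.default_effect_map()
                        if ccfg.get("use_default_effects") else ()),
            seed=config["seed"],
        ))
        wcfg = config["wavelet"]
        plan = tf.build_wavelet_plan(
            wcfg["f_min"], wcfg["f_max"], wcfg["step"],
            wcfg["c_min"], wcfg["c_max"], sample_rate=1000.0)

        stage = "reject+tfr"
        measures = {}
        rejection_rows = []
        te_inputs = {}
        te_nodes = ({n for pair in te.DEFAULT_PAIRS for n in pair}
                    if config["te"]["enabled"] else set())
        for sid, nodes in cohort.iter_epochs():
            retained, report = reject_trials(nodes, config["reject_threshold"])
            rejection_rows.append({k: v for k, v in report.items()
                                   if k != "retained_indices"})
            for node, ep in retained.items():
                measures[(sid, node)] = tf.compute_measures(
                    ep.data, plan, epoch_window=ep.epoch_window,
                    time_step_ms=config["time_step_ms"])
            if te_nodes:
                te_inputs[sid] = {
                    n: retained[n].data[: config["te"]["max_trials"]]
                    for n in te_nodes if n in retained}

        stage = "features"
        table = feat.compute_feature_table(measures)
        _write_csv(table, out_dir / "features.csv", manifest)
        _write_csv(pd.DataFrame(rejection_rows),
                   out_dir / "rejection_report.csv", manifest)
        _write_csv(cohort.metadata, out_dir / "metadata.csv", manifest)
        _, sa_summary = feat.compute_sa_ratio(table)
        _write_csv(sa_summary, out_dir / "sa_ratio.csv", manifest)

        if config["te"]["enabled"]:
            stage = "transfer-entropy"
            tcfg = te.TEConfig(q=config["te"]["q"],
                               n_boot=config["te"]["n_boot"],
                               alpha=config["te"]["alpha"],
                               seed=config["seed"])
            te_rows = []
            for sid, arrays in te_inputs.items():
                df = te.compute_te_percent(arrays, cfg=tcfg, subject_id=sid)
                te_rows.append(df.drop(columns=["te_trials", "p_trials"]))
            _write_csv(pd.concat(te_rows, ignore_index=True),
                       out_dir / "te_percent.csv", manifest)

        stage = "stats"
        contrast_frames = []
        for response in config["stats"]["responses"]:
            transform = ("itpc_transform" if response.endswith("_itpc")
                         else "none")
            offset = (1.0 if transform == "itpc_transform" else 0.0)
            fit = st.fit_region_model(
                table, cohort.metadata, response,
                transform=transform, transform_offset=offset)
            contrast_frames.append(st.posthoc_contrasts(fit))
        _write_csv(pd.concat(contrast_frames, ignore_index=True),
                   out_dir / "contrasts.csv", manifest)

        try:
            sa_compare = st.compare_sa_groups(sa_summary, cohort.metadata)
            _write_csv(sa_compare, out_dir / "sa_comparisons.csv", manifest)
        except ValueError as exc:
            logger.warning("SA group comparison skipped: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d outputs in %s",
                len(manifest["outputs"]), out_dir)
    return manifest
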