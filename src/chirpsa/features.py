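"""Band x window feature extraction, region aggregation and the SA ratio.

Ten response variables are summarised per subject and node from the
time-frequency measures: onset / gamma1 / gamma2 / offset ITPC, and
alpha / gamma1 / gamma2 STP and ERSP.  The ITPC windows track the chirp's
linear frequency law f(t) = 50 * t Hz (so the 30–57 Hz gamma1 band pairs
with 600–1140 ms, and the 63–100 Hz gamma2 band with 1260–2000 ms); power
windows span the whole stimulus.

The synchronous-to-asynchronous (SA) ratio divides gamma1 ITPC (stimulus
phase locking, "signal") by gamma1 STP min-max normalised onto the ITPC
scale (asynchronous background power, "noise"), evaluated per temporal
node and averaged within the left and right temporal regions per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._atlas import (DK_NODES, REDUCED_NODE_SET, REGION_NAMES,  # noqa: F401
                     load_region_map, regions_of)
from .timefreq import TFMeasures

#: gamma1 STP cap used by the original protocol (its data's max gamma1 ITPC)
PROTOCOL_STP_CAP = 0.0164


@dataclass(frozen=True)
class BandWindow:
    name: str
    measure: str                  # ITPC | STP | ERSP
    f_range: tuple[float, float]  # Hz, inclusive
    t_range: tuple[float, float]  # ms, inclusive

    def __post_init__(self) -> None:
        if self.measure not in ("ITPC", "STP", "ERSP"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if not (self.f_range[0] < self.f_range[1] and self.t_range[0] < self.t_range[1]):
            raise ValueError("empty band window")


def default_windows() -> tuple[BandWindow, ...]:
    """The ten response variables (ITPC windows follow the chirp law)."""
    return (
        BandWindow("onset_itpc", "ITPC", (2, 13), (0, 500)),
        BandWindow("gamma1_itpc", "ITPC", (30, 57), (600, 1140)),
        BandWindow("gamma2_itpc", "ITPC", (63, 100), (1260, 2000)),
        BandWindow("offset_itpc", "ITPC", (2, 13), (2000, 2500)),
        BandWindow("alpha_stp", "STP", (8, 12), (0, 2000)),
        BandWindow("gamma1_stp", "STP", (30, 57), (0, 2000)),
        BandWindow("gamma2_stp", "STP", (63, 100), (0, 2000)),
        BandWindow("alpha_ersp", "ERSP", (8, 12), (0, 2000)),
        BandWindow("gamma1_ersp", "ERSP", (30, 57), (0, 2000)),
        BandWindow("gamma2_ersp", "ERSP", (63, 100), (0, 2000)),
    )


def extract_feature(measures: TFMeasures, bw: BandWindow) -> float:
    """Mean of the measure over the rectangular time-frequency window."""
    arr = {"ITPC": measures.itpc_corrected,
           "STP": measures.stp,
           "ERSP": measures.ersp}[bw.measure]
    f_sel = (measures.freqs >= bw.f_range[0]) & (measures.freqs <= bw.f_range[1])
    t_sel = (measures.times >= bw.t_range[0]) & (measures.times <= bw.t_range[1])
    if not f_sel.any() or not t_sel.any():
        raise ValueError(f"window {bw.name} outside the analysis grid")
    return float(arr[np.ix_(f_sel, t_sel)].mean())


def compute_feature_table(
    measures_by_node: dict[tuple[str, str], TFMeasures],
    windows: tuple[BandWindow, ...] | None = None,
    region_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """FeatureTable: one row per (subject, node) with the response variables.

    ``measures_by_node`` maps ``(subject_id, node)`` to that node's
    time-frequency measures.  Rows are tagged with the node's region.
    """
    windows = windows or default_windows()
    region_map = region_map or load_region_map()
    rows = []
    for (subject, node), m in measures_by_node.items():
        if node not in region_map:
            raise KeyError(f"unknown node label: {node}")
        row = {"subject_id": subject, "node": node, "region": region_map[node]}
        for bw in windows:
            row[bw.name] = extract_feature(m, bw)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_to_regions(
    features: pd.DataFrame, region_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tag rows with regions, keeping nodes as replicates (no averaging)."""
    region_map = region_map or load_region_map()
    unmapped = sorted(set(features["node"]) - set(region_map))
    if unmapped:
        raise KeyError(f"unmapped nodes: {unmapped}")
    out = features.copy()
    out["region"] = out["node"].map(region_map)
    return out


def region_means(features: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: node replicates averaged per subject x region."""
    value_cols = [c for c in features.columns
                  if c not in ("subject_id", "node", "region")]
    return (features.groupby(["subject_id", "region"], sort=True)[value_cols]
            .mean().reset_index())


def normalize_stp(values, cap: float | None = None) -> np.ndarray:
    """Min-max rescale pooled STP values onto ``[0, cap]``.

    ``cap`` defaults to the analysis set's maximum gamma1 ITPC when the
    caller passes it; the original protocol's constant (0.0164) is exposed
    as :data:`PROTOCOL_STP_CAP`.
    """
    values = np.asarray(values, dtype=float)
    if cap is None:
        raise ValueError("cap is required (pass the set's max gamma1 ITPC "
                         "or PROTOCOL_STP_CAP)")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("degenerate scale: all STP values identical")
    return cap * (values - lo) / (hi - lo)


def compute_sa_ratio(
    features: pd.DataFrame,
    cap: float | None = None,
    floor_frac: float = 1e-6,
    region_map: dict[str, str] | None = None,
    scope: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SA ratio per temporal node and its left/right temporal summary.

    gamma1 STP values are min-max normalised onto ``[0, cap]`` across the
    pooled subjects x nodes of the analysis set (``scope="all"``; pass
    ``scope="temporal"`` to rescale within the temporal nodes only — note
    that scope pins some temporal node at exactly 0, which the floor then
    clips).  The ratio ``gamma1_itpc / gamma1_stp_norm`` is computed per
    temporal node and then averaged within the left and right temporal
    regions per subject.  Normalised STP at or below ``floor_frac * cap``
    is clipped to the floor and flagged.

    Returns ``(node_table, summary)``: the temporal-node rows with
    ``gamma1_stp_norm``, ``sa_ratio`` and ``floored`` columns, and the
    per-subject per-side summary.
    """
    region_map = region_map or load_region_map()
    feats = aggregate_to_regions(features, region_map)
    temporal = feats[feats["region"].isin(["left_temporal", "right_temporal"])].copy()
    if temporal.empty:
        raise ValueError("no temporal nodes in the feature table")
    if cap is None:
        cap = float(temporal["gamma1_itpc"].max())
        if cap <= 0:
            raise ValueError("max gamma1 ITPC is non-positive; pass an "
                             "explicit cap (e.g. PROTOCOL_STP_CAP)")
    floor = floor_frac * cap
    if scope == "all":
        pool = feats["gamma1_stp"].to_numpy()
    elif scope == "temporal":
        pool = temporal["gamma1_stp"].to_numpy()
    else:
        raise ValueError("scope must be 'all' or 'temporal'")
    lo, hi = pool.min(), pool.max()
    if hi == lo:
        raise ValueError("degenerate scale: all STP values identical")
    stp_norm = cap * (temporal["gamma1_stp"].to_numpy() - lo) / (hi - lo)
    floored = stp_norm <= floor
    stp_norm = np.maximum(stp_norm, floor)
    temporal["gamma1_stp_norm"] = stp_norm
    temporal["floored"] = floored
    temporal["sa_ratio"] = temporal["gamma1_itpc"].to_numpy() / stp_norm
    summary = (temporal
               .assign(side=temporal["region"].map(
                   {"left_temporal": "left", "right_temporal": "right"}))
               .groupby(["subject_id", "side"], sort=True)
               .agg(sa_ratio=("sa_ratio", "mean"),
                    gamma1_itpc=("gamma1_itpc", "mean"),
                    gamma1_stp_norm=("gamma1_stp_norm", "mean"),
                    any_floored=("floored", "any"))
               .reset_index())
    return temporal, summary
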