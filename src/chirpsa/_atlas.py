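"""Desikan-Killiany cortical parcellation and the 14-region lobar grouping.

The 68 cortical nodes (34 labels per hemisphere, ``lh-``/``rh-`` prefixed)
are grouped into 14 regions: left/right x {prefrontal, frontal, central,
temporal, parietal, occipital, cingulate}.  The mapping ships as an
editable YAML config (``data/dk14_regions.yaml``); the insula is grouped
with the cingulate ("deep source") region since it is not a lobar surface
node.  Temporal regions include the banks of the superior temporal sulcus
and the transverse temporal gyrus.
"""

from __future__ import annotations

import importlib.resources

import yaml

#: the 34 Desikan-Killiany cortical labels (one hemisphere)
DK_LABELS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: all 68 node labels, e.g. "lh-superiortemporal"
DK_NODES: tuple[str, ...] = tuple(
    f"{hemi}-{label}" for hemi in ("lh", "rh") for label in DK_LABELS
)

#: stable integer index per node (used to derive per-node random streams)
DK_NODE_INDEX: dict[str, int] = {node: i for i, node in enumerate(DK_NODES)}

REGION_NAMES: tuple[str, ...] = tuple(
    f"{side}_{lobe}"
    for side in ("left", "right")
    for lobe in ("prefrontal", "frontal", "central", "temporal",
                 "parietal", "occipital", "cingulate")
)

#: reduced node set: exemplars covering all 14 regions plus the directed
#: connectivity nodes (right cMFG / pTRI / rMFG, bilateral STG)
REDUCED_NODE_SET: tuple[str, ...] = (
    "lh-rostralmiddlefrontal", "rh-rostralmiddlefrontal",
    "lh-superiorfrontal", "rh-caudalmiddlefrontal", "rh-parstriangularis",
    "lh-precentral", "rh-precentral",
    "lh-superiortemporal", "lh-transversetemporal",
    "rh-superiortemporal", "rh-transversetemporal",
    "lh-superiorparietal", "rh-superiorparietal",
    "lh-lateraloccipital", "rh-lateraloccipital",
    "lh-posteriorcingulate", "rh-posteriorcingulate",
    "rh-superiorfrontal",
)


def load_region_map(path=None) -> dict[str, str]:
    """Node label -> region label for all 68 DK nodes.

    Reads the packaged ``dk14_regions.yaml`` by default, or an editable
    override.  Raises if any DK node is unmapped or mapped twice.
    """
    if path is None:
        source = importlib.resources.files("chirpsa").joinpath(
            "data/dk14_regions.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    mapping: dict[str, str] = {}
    for region, labels in raw["regions"].items():
        for label in labels:
            for hemi, side in (("lh", "left"), ("rh", "right")):
                node = f"{hemi}-{label}"
                if node in mapping:
                    raise ValueError(f"node {node} mapped twice")
                mapping[node] = f"{side}_{region}"
    missing = set(DK_NODES) - set(mapping)
    if missing:
        raise ValueError(f"unmapped DK nodes: {sorted(missing)}")
    return mapping


def regions_of(nodes, region_map: dict[str, str] | None = None) -> dict[str, str]:
    """Region for each requested node, erroring on unknown labels."""
    region_map = region_map or load_region_map()
    out = {}
    for node in nodes:
        if node not in region_map:
            raise KeyError(f"unknown node label: {node}")
        out[node] = region_map[node]
    return out
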