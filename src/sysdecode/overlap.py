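"""Percentage overlap between topic surface maps and an intrinsic-network
partition, in both directions.

For each (seed, topic) the parcels of the topic surface map are rasterised
to voxels on the shared grid and compared against the network partition:
``pct_topic_in_network`` is the share of the topic map's voxels falling in
each network (these sum to 100 across networks plus the explicit
"unassigned" pseudo-network), and ``pct_network_in_topic`` is the share of
each network's voxels covered by the topic map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spatial import NetworkPartition, Parcellation, RegionMask, _require_same_grid
from .systems import TopicSurfaceMap

__all__ = ["rasterize_topic_map", "overlap_percentages", "topic_network_overlap"]

UNASSIGNED = 0


def rasterize_topic_map(topic_map: TopicSurfaceMap,
                        parcellation: Parcellation) -> dict[tuple[str, int], RegionMask]:
    """Union of each (seed, topic)'s parcels as a voxel mask."""
    known = set(parcellation.label_ids)
    out: dict[tuple[str, int], RegionMask] = {}
    for (seed, topic), parcels in topic_map.regions.items():
        unknown = set(parcels) - known
        if unknown:
            raise ValueError(f"unknown parcel labels {sorted(unknown)}")
        members = np.isin(parcellation.labels, sorted(parcels))
        out[(seed, topic)] = RegionMask(parcellation.grid, members,
                                        name=f"{seed}_topic{topic}")
    return out


def overlap_percentages(mask: RegionMask, nets: NetworkPartition) -> pd.DataFrame:
    """Both-direction percentage overlap of ``mask`` with every network.

    Returns one row per network (plus the label-0 "unassigned"
    pseudo-network) with columns network, network_name,
    pct_topic_in_network, pct_network_in_topic, empty_network.
    """
    _require_same_grid(mask.grid, nets.grid)
    if mask.is_empty:
        raise ValueError("empty mask")
    m = mask.members
    n_mask = m.sum()
    rows = []
    for k in [UNASSIGNED] + nets.network_ids:
        net = nets.labels == k
        n_net = int(net.sum())
        inter = int((m & net).sum())
        empty = n_net == 0
        rows.append({
            "network": k,
            "network_name": nets.names.get(k, "unassigned"),
            "pct_topic_in_network": 100.0 * inter / n_mask,
            "pct_network_in_topic": 0.0 if empty else 100.0 * inter / n_net,
            "empty_network": empty,
        })
    return pd.DataFrame(rows)


def topic_network_overlap(topic_map: TopicSurfaceMap, parcellation: Parcellation,
                          nets: NetworkPartition) -> pd.DataFrame:
    """Overlap table over all (seed, topic) maps: long format with columns
    seed, topic, topic_name, network, network_name, both percentage
    directions and the empty-network flag."""
    masks = rasterize_topic_map(topic_map, parcellation)
    frames = []
    for (seed, topic), mask in sorted(masks.items()):
        df = overlap_percentages(mask, nets)
        df.insert(0, "seed", seed)
        df.insert(1, "topic", topic)
        df.insert(2, "topic_name", topic_map.topic_names.get(topic, str(topic)))
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["seed", "topic", "topic_name", "network",
                                     "network_name", "pct_topic_in_network",
                                     "pct_network_in_topic", "empty_network"])
    return pd.concat(frames, ignore_index=True)
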