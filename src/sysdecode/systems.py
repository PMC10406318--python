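"""Systems-level decoding of seed-cortical pairs.

Each seed is decoded *jointly* with each of its functionally connected
cortical regions (a study counts as activating the pair when it activates
both masks — co-activation — or, optionally, their union), and the
connected region is decoded alone. The two resulting term lists are
compared: their intersection (logical-and conjunction) gives terms shared
with the region's own functional profile, and the set difference gives
terms *specific* to the seed-cortical pair. Iterating over all pairs
assembles a system map — for each (seed, term), the set of cortical
regions whose pairing with that seed was specifically associated with the
term — which is then aggregated into topics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .decoder import (
    ActivationVector,
    CoordinateDatabase,
    DecodingResult,
    activation_vector,
    decode_roi,
    select_terms,
)
from .spatial import Parcellation, RegionMask, any_overlap, mask_union

__all__ = [
    "DecodingParams",
    "PairDecoding",
    "SystemMap",
    "TopicMapping",
    "TopicSurfaceMap",
    "pair_activation",
    "decode_pair",
    "systems_decode",
    "group_into_topics",
    "seed_contribution",
]


@dataclass(frozen=True)
class DecodingParams:
    """Knobs shared by all decodings in a systems run.

    ``radius_mm`` defaults to 0 (strict in-mask focus membership): at the
    toy fixture scale, parcels are only a few voxels across and a
    millimetre-scale radius would blur adjacent regions together. For
    full-scale atlases a radius of ~6 mm is a reasonable setting.
    """

    radius_mm: float = 0.0
    prior: float = 0.5
    f_min: float = 0.001
    alpha: float = 0.05
    k: int = 30
    order: str = "rank_then_filter"
    pair_mode: str = "both"  # or "union"
    construct_allowlist: frozenset[str] | None = None


@dataclass(frozen=True)
class PairDecoding:
    """Term sets for one seed-cortical pair."""

    seed_name: str
    parcel_label: int
    terms_pair: frozenset[str]
    terms_region: frozenset[str]

    @property
    def terms_specific(self) -> frozenset[str]:
        """Terms of the joint decoding not explained by the region alone."""
        return self.terms_pair - self.terms_region

    @property
    def terms_shared(self) -> frozenset[str]:
        """Terms present in both the joint and the region-alone decoding."""
        return self.terms_pair & self.terms_region


@dataclass
class SystemMap:
    """(seed, term) -> set of parcel labels whose pairing with the seed was
    specifically associated with the term."""

    entries: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    pairs: list[PairDecoding] = field(default_factory=list)

    def add(self, seed: str, term: str, parcel: int) -> None:
        self.entries.setdefault((seed, term), set()).add(parcel)

    def terms(self, seed: str) -> list[str]:
        return sorted(t for s, t in self.entries if s == seed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"seed": s, "term": t, "parcel": p}
            for (s, t), parcels in sorted(self.entries.items())
            for p in sorted(parcels)
        ]
        return pd.DataFrame(rows, columns=["seed", "term", "parcel"])


@dataclass(frozen=True)
class TopicMapping:
    """Hard assignment of terms to named topics."""

    term_to_topic: dict[str, int]
    topic_names: dict[int, str]

    def __post_init__(self) -> None:
        unknown = set(self.term_to_topic.values()) - set(self.topic_names)
        if unknown:
            raise ValueError(f"topics without names: {sorted(unknown)}")

    @property
    def n_topics(self) -> int:
        return len(self.topic_names)

    @classmethod
    def from_loadings(cls, loadings: pd.DataFrame, topic_names: dict[int, str],
                      min_loading: float = 0.001) -> "TopicMapping":
        """Hard-assign each term to its argmax-loading topic, skipping terms
        whose best loading falls below ``min_loading``."""
        mapping: dict[str, int] = {}
        cols = list(loadings.columns)
        arr = loadings.to_numpy(dtype=float)
        best = arr.argmax(axis=1)
        for i, term in enumerate(loadings.index):
            if arr[i, best[i]] >= min_loading:
                mapping[str(term)] = int(cols[best[i]])
        return cls(mapping, topic_names)


@dataclass
class TopicSurfaceMap:
    """(seed, topic) -> set of parcel labels, the union over the topic's
    terms of the system map's region sets; the contributing terms are kept."""

    regions: dict[tuple[str, int], set[int]] = field(default_factory=dict)
    terms: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    topic_names: dict[int, str] = field(default_factory=dict)
    unmapped_terms: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"seed": s, "topic": k, "topic_name": self.topic_names.get(k, str(k)),
             "parcel": p}
            for (s, k), parcels in sorted(self.regions.items())
            for p in sorted(parcels)
        ]
        return pd.DataFrame(rows, columns=["seed", "topic", "topic_name", "parcel"])


def pair_activation(db: CoordinateDatabase, seed: RegionMask, parcel: RegionMask,
                    radius_mm: float = 6.0, mode: str = "both") -> ActivationVector:
    """Activation vector of a seed-cortical pair.

    ``both`` (default): a study is active iff it activates the seed AND the
    parcel — the co-activation reading. ``union``: active iff it activates
    the union mask.
    """
    if seed.is_empty or parcel.is_empty:
        raise ValueError("pair masks must be nonempty")
    if any_overlap(seed, parcel):
        raise ValueError("seed and parcel masks overlap")
    name = f"{seed.name}+{parcel.name}"
    if mode == "both":
        a = activation_vector(db, seed, radius_mm)
        b = activation_vector(db, parcel, radius_mm)
        return ActivationVector(a.active & b.active, a.studies, name, radius_mm)
    if mode == "union":
        joint = mask_union(seed, parcel, name=name)
        return activation_vector(db, joint, radius_mm)
    raise ValueError(f"unknown pair mode {mode!r}")


def decode_pair(db: CoordinateDatabase, seed: RegionMask, parcel: RegionMask,
                params: DecodingParams = DecodingParams(),
                parcel_label: int = 0) -> PairDecoding:
    """Decode the pair jointly and the region alone; derive the specific
    and shared term sets via set difference and conjunction."""
    act = pair_activation(db, seed, parcel, params.radius_mm, params.pair_mode)
    pair_res = decode_roi(db, act, prior=params.prior, f_min=params.f_min,
                          alpha=params.alpha)
    region_res = decode_roi(db, parcel, radius_mm=params.radius_mm,
                            prior=params.prior, f_min=params.f_min,
                            alpha=params.alpha)
    allow = params.construct_allowlist
    terms_pair = frozenset(select_terms(pair_res, params.k, allow, params.order))
    terms_region = frozenset(select_terms(region_res, params.k, allow, params.order))
    return PairDecoding(seed.name, parcel_label, terms_pair, terms_region)


def systems_decode(db: CoordinateDatabase, seeds: dict[str, RegionMask],
                   connected: dict[str, list[int]], parcellation: Parcellation,
                   params: DecodingParams = DecodingParams()) -> SystemMap:
    """Decode every seed-cortical pair and assemble the system map from the
    pair-specific term sets.

    Region-alone decodings are cached per parcel, since several seeds may
    share a connected region.
    """
    system = SystemMap()
    region_terms_cache: dict[int, frozenset[str]] = {}
    allow = params.construct_allowlist

    for seed_name in sorted(seeds):
        seed = seeds[seed_name]
        for label in sorted(connected.get(seed_name, [])):
            parcel = parcellation.parcel_mask(label)
            act = pair_activation(db, seed, parcel, params.radius_mm,
                                  params.pair_mode)
            pair_res = decode_roi(db, act, prior=params.prior,
                                  f_min=params.f_min, alpha=params.alpha)
            terms_pair = frozenset(
                select_terms(pair_res, params.k, allow, params.order))
            if label not in region_terms_cache:
                region_res = decode_roi(db, parcel, radius_mm=params.radius_mm,
                                        prior=params.prior, f_min=params.f_min,
                                        alpha=params.alpha)
                region_terms_cache[label] = frozenset(
                    select_terms(region_res, params.k, allow, params.order))
            pd_ = PairDecoding(seed_name, label, terms_pair,
                               region_terms_cache[label])
            system.pairs.append(pd_)
            for term in pd_.terms_specific:
                system.add(seed_name, term, label)
    return system


def group_into_topics(system: SystemMap, mapping: TopicMapping) -> TopicSurfaceMap:
    """Aggregate the system map's terms into topics: a (seed, topic) region
    set is the union of the region sets of the topic's terms. Terms absent
    from the mapping are reported, not silently dropped."""
    out = TopicSurfaceMap(topic_names=dict(mapping.topic_names))
    for (seed, term), parcels in system.entries.items():
        topic = mapping.term_to_topic.get(term)
        if topic is None:
            out.unmapped_terms.add(term)
            continue
        key = (seed, topic)
        out.regions.setdefault(key, set()).update(parcels)
        out.terms.setdefault(key, set()).add(term)
    return out


def seed_contribution(topic_map: TopicSurfaceMap,
                      parcellation: Parcellation) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of how seeds build each topic's system.

    Returns (counts, multiplicity): ``counts`` has one row per
    (topic, seed, hemisphere) with the number of system regions;
    ``multiplicity`` has one row per (topic, parcel) with the number of
    seeds whose system includes that parcel.
    """
    hemi = parcellation.table["hemisphere"].to_dict()
    count_rows = []
    mult: dict[tuple[int, int], int] = {}
    for (seed, topic), parcels in sorted(topic_map.regions.items()):
        per_hemi: dict[str, int] = {}
        for p in parcels:
            h = str(hemi.get(p, "?"))
            per_hemi[h] = per_hemi.get(h, 0) + 1
            mult[(topic, p)] = mult.get((topic, p), 0) + 1
        for h, c in sorted(per_hemi.items()):
            count_rows.append({"topic": topic,
                               "topic_name": topic_map.topic_names.get(topic, str(topic)),
                               "seed": seed, "hemisphere": h, "n_regions": c})
    counts = pd.DataFrame(count_rows,
                          columns=["topic", "topic_name", "seed", "hemisphere",
                                   "n_regions"])
    mult_rows = [{"topic": k[0], "parcel": k[1], "n_seeds": v}
                 for k, v in sorted(mult.items())]
    multiplicity = pd.DataFrame(mult_rows, columns=["topic", "parcel", "n_seeds"])
    return counts, multiplicity
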