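"""Synthetic fixtures with planted ground truth for the whole pipeline.

The generator emulates, at toy scale, every input the systems-level
decoding pipeline consumes: a block parcellation with a named
seven-network partition, probabilistic seed maps, multi-subject resting
BOLD with planted seed-parcel connectivity, a coordinate database with
planted term-system associations, and a hard term-to-topic mapping.

Planted associations come in two kinds:

``marginal``
    The term is associated with the activation of its ROI(s) outright: a
    study assigned to the term activates every ROI of the set with
    probability ``signal_rate`` (against a ``base_rate`` background). Such
    terms are recoverable by decoding the ROI alone.

``conjunction``
    The term is associated only with the *co-activation* of its ROI set.
    Every "system" ROI (each seed and each planted connected parcel) is
    activated with the same marginal probability ``coupling_rate`` in
    every study; in studies assigned to a conjunction term, the draws of
    its ROI set are perfectly coupled (one shared coin), while all other
    draws are independent. The marginal activation rate of each ROI is
    therefore identical across studies — the signal lives purely in the
    joint distribution, so these terms are invisible to single-ROI
    decoding and surface only under pair (co-activation) decoding.

Studies are assigned to at most one planted term per seed family
(studies investigate one construct), which keeps the planted effects from
washing each other out.

All generators are pure functions of their parameters and RNG seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .decoder import CoordinateDatabase
from .spatial import (
    NetworkPartition,
    Parcellation,
    ProbabilityMap,
    RegionMask,
    VolumeGrid,
    threshold_probability,
)
from .rsfc import Bold4D
from .systems import TopicMapping

__all__ = [
    "PlantedAssociation",
    "SyntheticTruth",
    "SyntheticFixture",
    "NETWORK_NAMES",
    "make_atlas",
    "make_seed_probability_maps",
    "plant_truth",
    "brain_mask",
    "simulate_bold",
    "simulate_coordinate_db",
    "make_topic_mapping",
    "make_fixture",
]

NETWORK_NAMES = {
    1: "Visual",
    2: "Somatomotor",
    3: "DorsalAttention",
    4: "VentralAttention",
    5: "Limbic",
    6: "Frontoparietal",
    7: "Default",
}


@dataclass(frozen=True)
class PlantedAssociation:
    """One planted term -> ROI-set association."""

    term: str
    rois: tuple[str, ...]
    kind: str  # "marginal" | "conjunction"

    def __post_init__(self) -> None:
        if self.kind not in ("marginal", "conjunction"):
            raise ValueError(f"unknown association kind {self.kind!r}")


@dataclass
class SyntheticTruth:
    """Ground truth planted into a fixture, serialisable to JSON."""

    planted_connected: dict[str, list[int]]
    associations: list[PlantedAssociation]
    expected_system: list[tuple[str, str, int]]  # (seed, term, parcel)
    pair_only_terms: list[str]
    seed_terms: dict[str, list[str]]
    base_rate: float = 0.1
    signal_rate: float = 0.8
    coupling_rate: float = 0.5
    effect_r: float = 0.5
    rng_seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["associations"] = [asdict(a) for a in self.associations]
        d["expected_system"] = [list(t) for t in self.expected_system]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["associations"] = [PlantedAssociation(a["term"], tuple(a["rois"]), a["kind"])
                             for a in d["associations"]]
        d["expected_system"] = [tuple(t) for t in d["expected_system"]]
        d["planted_connected"] = {k: [int(v) for v in vs]
                                  for k, vs in d["planted_connected"].items()}
        return cls(**d)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _factor3(n: int, region: tuple[int, int, int]) -> tuple[int, int, int]:
    """Factor n into (nx, ny, nz) block counts that fit the region, as
    balanced as possible, preferring an even nx so parcels split evenly
    across hemispheres."""
    best = None
    for nx in range(1, n + 1):
        if n % nx:
            continue
        rest = n // nx
        for ny in range(1, rest + 1):
            if rest % ny:
                continue
            nz = rest // ny
            if nx > region[0] or ny > region[1] or nz > region[2]:
                continue
            spread = max(nx, ny, nz) - min(nx, ny, nz)
            key = (nx % 2, spread, nx, ny, nz)  # even nx first, then balanced
            if best is None or key < best[0]:
                best = (key, (nx, ny, nz))
    if best is None:
        raise ValueError(f"cannot tile {n} parcels on region {region}")
    return best[1]


def make_atlas(grid_shape: tuple[int, int, int] = (24, 24, 24),
               n_parcels: int = 40, seed: int = 0, voxel_mm: float = 2.0,
               margin: int = 2,
               n_networks: int = 7) -> tuple[Parcellation, NetworkPartition]:
    """Block parcellation of the interior of the grid plus a named
    intrinsic-network partition; hemispheres split at the x midline."""
    grid = VolumeGrid.isotropic(grid_shape, voxel_mm)
    region = tuple(s - 2 * margin for s in grid_shape)
    if any(r < 1 for r in region):
        raise ValueError("margin leaves no interior region")
    nx, ny, nz = _factor3(n_parcels, region)

    labels = np.zeros(grid_shape, dtype=np.int32)
    edges = [np.linspace(margin, s - margin, c + 1).round().astype(int)
             for s, c in zip(grid_shape, (nx, ny, nz))]
    mid_x = grid_shape[0] / 2
    rows = []
    lab = 0
    rng = _rng(seed, 1)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lab += 1
                sl = (slice(edges[0][i], edges[0][i + 1]),
                      slice(edges[1][j], edges[1][j + 1]),
                      slice(edges[2][k], edges[2][k + 1]))
                labels[sl] = lab
                cx = (edges[0][i] + edges[0][i + 1] - 1) / 2
                rows.append({"label": lab, "name": f"P{lab:03d}",
                             "hemisphere": "L" if cx < mid_x else "R"})
    net_of_parcel = 1 + rng.permutation(n_parcels) % n_networks
    table = pd.DataFrame(rows).set_index("label")
    names = {k: v for k, v in NETWORK_NAMES.items() if k <= n_networks}
    table["group"] = [names[int(net_of_parcel[i])] for i in range(n_parcels)]

    net_labels = np.zeros(grid_shape, dtype=np.int32)
    for lab in range(1, n_parcels + 1):
        net_labels[labels == lab] = int(net_of_parcel[lab - 1])
    return Parcellation(grid, labels, table), NetworkPartition(grid, net_labels, names)


def make_seed_probability_maps(grid: VolumeGrid, k_seeds: int = 6, seed: int = 0,
                               peak: float = 0.9, sigma_mm: float = 3.0,
                               margin: int = 2) -> list[ProbabilityMap]:
    """Gaussian-falloff probability maps with pairwise-disjoint >0.25 cores,
    half per hemisphere, analogous to probabilistic cytoarchitectonic seed
    maps."""
    if k_seeds < 1:
        raise ValueError("k_seeds must be >= 1")
    n_left = (k_seeds + 1) // 2
    n_right = k_seeds - n_left
    sx, sy, sz = grid.shape
    maps = []
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers_mm = grid.voxel_centers(idx)

    def _make(hemi: str, i: int, count: int, name: str) -> ProbabilityMap:
        cx = margin + 0.25 * (sx - 2 * margin) if hemi == "L" else \
            margin + 0.75 * (sx - 2 * margin)
        cy = margin + (sy - 2 * margin) * (i + 0.5) / count
        cz = sz / 2
        c_mm = grid.voxel_centers(np.array([[cx, cy, cz]]))[0]
        d2 = ((centers_mm - c_mm) ** 2).sum(axis=1)
        vals = peak * np.exp(-d2 / (2 * sigma_mm**2))
        return ProbabilityMap(grid, vals.reshape(grid.shape), name=name)

    for i in range(n_left):
        maps.append(_make("L", i, n_left, f"seed_L{i + 1}"))
    for i in range(n_right):
        maps.append(_make("R", i, n_right, f"seed_R{i + 1}"))
    return maps


def _seed_masks(seed_maps: list[ProbabilityMap], tau: float = 0.25) -> dict[str, RegionMask]:
    return {m.name: threshold_probability(m, tau) for m in seed_maps}


def plant_truth(parcellation: Parcellation, seeds: dict[str, RegionMask],
                seed: int = 0, n_connected: int = 4,
                n_filler: int = 90) -> tuple[SyntheticTruth, list[str], list[str]]:
    """Choose planted connected parcels and term-system associations.

    Per seed: ``n_connected`` same-hemisphere parcels not touching any seed
    core, disjoint across seeds; three conjunction ("co-activation") terms
    whose parcel sets partition the connected parcels — one spanning the
    seed plus two parcels and two seed-parcel pair terms, of which the last
    is the designated pair-only probe; one anatomical-style term marginally
    associated with the seed alone (kept out of the construct allowlist,
    like "intraparietal"-type vocabulary); and one region term marginal on
    one parcel (recoverable from the region alone, hence subtracted as
    shared). Each parcel is coupled by exactly one conjunction term, so the
    planted effects do not mask each other. Returns
    (truth, vocabulary, construct allowlist).
    """
    if n_connected < 4:
        raise ValueError("need at least 4 connected parcels per seed")
    rng = _rng(seed, 2)
    mid_x = parcellation.grid.shape[0] / 2
    seed_union = np.zeros(parcellation.grid.shape, dtype=bool)
    for m in seeds.values():
        seed_union |= m.members

    hemi_of = {}
    for lab in parcellation.label_ids:
        hemi_of[lab] = str(parcellation.table.loc[lab, "hemisphere"])
    free = [lab for lab in parcellation.label_ids
            if not (seed_union & (parcellation.labels == lab)).any()]

    planted_connected: dict[str, list[int]] = {}
    used: set[int] = set()
    for name in sorted(seeds):
        hemi = "L" if seeds[name].voxel_indices()[:, 0].mean() < mid_x else "R"
        candidates = [lab for lab in free if hemi_of[lab] == hemi and lab not in used]
        if len(candidates) < n_connected:
            raise ValueError(f"not enough free parcels for seed {name}")
        pick = sorted(rng.choice(candidates, size=n_connected, replace=False).tolist())
        planted_connected[name] = [int(p) for p in pick]
        used.update(pick)

    associations: list[PlantedAssociation] = []
    expected: list[tuple[str, str, int]] = []
    pair_only: list[str] = []
    seed_terms: dict[str, list[str]] = {}
    vocabulary: list[str] = []

    non_construct: list[str] = []
    for name in sorted(seeds):
        p1, p2, p3, p4 = planted_connected[name][:4]
        pn = {p: f"parcel_{p:03d}" for p in (p1, p2, p3, p4)}
        t_coact = [f"coact_{name}_{j}" for j in (1, 2)]
        t_pair = f"pairterm_{name}"
        t_anat = f"anatterm_{name}"
        t_region = f"regionterm_{name}"
        associations += [
            PlantedAssociation(t_coact[0], (name, pn[p1], pn[p2]), "conjunction"),
            PlantedAssociation(t_coact[1], (name, pn[p3]), "conjunction"),
            PlantedAssociation(t_pair, (name, pn[p4]), "conjunction"),
            PlantedAssociation(t_anat, (name,), "marginal"),
            PlantedAssociation(t_region, (pn[p3],), "marginal"),
        ]
        pair_only.append(t_pair)
        seed_terms[name] = [t_anat]
        non_construct.append(t_anat)
        vocabulary += [*t_coact, t_pair, t_anat, t_region]
        # every (seed, conjunction term, member parcel) triple is expected
        # to surface as pair-specific
        expected += [(name, t_coact[0], p1), (name, t_coact[0], p2),
                     (name, t_coact[1], p3), (name, t_pair, p4)]

    # construct allowlist: planted construct terms (region terms must survive
    # the filter so they can be subtracted as shared) plus a third of the
    # fillers; anatomical seed terms and remaining fillers play the role of
    # non-construct vocabulary
    fillers = [f"filler_{i:03d}" for i in range(1, n_filler + 1)]
    allowlist = sorted((set(vocabulary) - set(non_construct))
                       | {f for i, f in enumerate(fillers) if i % 6 == 0})
    vocabulary += fillers

    truth = SyntheticTruth(
        planted_connected=planted_connected,
        associations=associations,
        expected_system=sorted(expected),
        pair_only_terms=sorted(pair_only),
        seed_terms=seed_terms,
        rng_seed=int(seed),
    )
    return truth, vocabulary, allowlist


def brain_mask(parcellation: Parcellation, seeds: dict[str, RegionMask]) -> RegionMask:
    """Labeled region plus all seed voxels."""
    members = parcellation.labels > 0
    for m in seeds.values():
        members = members | m.members
    return RegionMask(parcellation.grid, members, name="brain")


def simulate_bold(parcellation: Parcellation, seeds: dict[str, RegionMask],
                  truth: SyntheticTruth, n_subjects: int = 20, T: int = 400,
                  tr: float = 0.8, effect_r: float = 0.5, noise_sd: float = 1.0,
                  seed: int = 0, seed_voxel_r: float = 0.9) -> list[Bold4D]:
    """Multi-subject BOLD with planted seed-parcel connectivity.

    Per subject and per seed region a latent signal is shared by the seed's
    voxels (population correlation ``seed_voxel_r``) and by the voxels of
    its planted connected parcels (population correlation ``effect_r``);
    every other in-brain voxel is i.i.d. Gaussian noise.
    """
    return [simulate_subject_bold(parcellation, seeds, truth, i, T, tr,
                                  effect_r, noise_sd, seed, seed_voxel_r)
            for i in range(n_subjects)]


def simulate_subject_bold(parcellation: Parcellation, seeds: dict[str, RegionMask],
                          truth: SyntheticTruth, subject: int, T: int = 400,
                          tr: float = 0.8, effect_r: float = 0.5,
                          noise_sd: float = 1.0, seed: int = 0,
                          seed_voxel_r: float = 0.9) -> Bold4D:
    """One subject of :func:`simulate_bold` (memory-friendly iteration)."""
    if not (0.0 < effect_r < 1.0):
        raise ValueError("effect_r must lie in (0, 1)")
    if T < 50:
        raise ValueError("T must be >= 50")
    rng = _rng(seed, 3, subject)
    grid = parcellation.grid
    brain = brain_mask(parcellation, seeds)
    series = np.zeros(grid.shape + (T,))
    series[brain.members] = rng.standard_normal((brain.n_voxels, T))

    for name in sorted(seeds):
        latent = rng.standard_normal(T)
        sm = seeds[name].members
        a = seed_voxel_r
        series[sm] = a * latent + np.sqrt(1 - a**2) * series[sm]
        for lab in truth.planted_connected.get(name, []):
            pm = (parcellation.labels == lab) & ~sm
            series[pm] = effect_r * latent + np.sqrt(1 - effect_r**2) * series[pm]
    return Bold4D(grid, noise_sd * series, tr, subject_id=f"sub-{subject + 1:03d}")


def simulate_coordinate_db(vocabulary: list[str], rois: dict[str, RegionMask],
                           truth: SyntheticTruth, n_studies: int = 2000,
                           foci_per_study: int = 3, jitter_sd_mm: float = 4.0,
                           base_rate: float = 0.1, signal_rate: float = 0.8,
                           coupling_rate: float = 0.5,
                           term_prevalence: float = 0.25,
                           marginal_prevalence: float = 0.1,
                           filler_prevalence: float = 0.3,
                           labeled: RegionMask | None = None,
                           seed: int = 0) -> CoordinateDatabase:
    """Coordinate database with the planted associations of ``truth``.

    Studies are assigned to at most one planted conjunction term per
    association family (the conjunction associations of one seed form a
    family, assigned with per-term probability ``term_prevalence``);
    marginal associations are assigned independently with probability
    ``marginal_prevalence``. Activation of "system" ROIs (any ROI of a
    conjunction association) has flat marginal rate ``coupling_rate``;
    coupling happens only inside the assigned association's ROI set.
    Activated ROIs contribute one focus at a random member voxel with
    Gaussian jitter truncated to the ROI (so a planted focus never bleeds
    into a neighbouring parcel — at this toy spatial scale parcels are only
    a few voxels across); every study also reports ``foci_per_study``
    uniform background foci over the labeled region, and every ROI
    independently receives a chance focus with probability ``base_rate``.
    """
    if not (0.0 <= base_rate < signal_rate <= 1.0):
        raise ValueError("need 0 <= base_rate < signal_rate <= 1")
    if not (0.0 < coupling_rate < 1.0):
        raise ValueError("coupling_rate must lie in (0, 1)")
    rng = _rng(seed, 4)

    planted_terms = [a.term for a in truth.associations]
    missing = set(planted_terms) - set(vocabulary)
    if missing:
        raise ValueError(f"planted terms missing from vocabulary: {sorted(missing)}")
    roi_missing = {r for a in truth.associations for r in a.rois} - set(rois)
    if roi_missing:
        raise ValueError(f"association ROIs missing: {sorted(roi_missing)}")

    conj_pool = sorted({r for a in truth.associations
                        if a.kind == "conjunction" for r in a.rois})
    # association families: conjunction terms of one seed are mutually
    # exclusive within a study; marginal terms form independent singletons
    families: dict[str, list[PlantedAssociation]] = {}
    for a in truth.associations:
        key = a.rois[0] if a.kind == "conjunction" else f"marginal::{a.term}"
        families.setdefault(key, []).append(a)
    fam_items = sorted(families.items())

    centers = {name: m.voxel_centers_mm() for name, m in rois.items()}
    voxel_sets = {name: {tuple(v) for v in m.voxel_indices()}
                  for name, m in rois.items()}
    grids = {name: m.grid for name, m in rois.items()}
    for name, c in centers.items():
        if len(c) == 0:
            raise ValueError(f"ROI {name!r} is empty")

    def _roi_focus(rng: np.random.Generator, name: str) -> np.ndarray:
        """A jittered focus that stays inside the ROI (rejection sampling;
        falls back to an unjittered voxel center)."""
        c = centers[name]
        base = c[rng.integers(len(c))]
        g = grids[name]
        for _ in range(20):
            cand = base + rng.normal(0.0, jitter_sd_mm, size=3)
            if tuple(np.round(g.world_to_voxel(cand)[0]).astype(int)) in voxel_sets[name]:
                return cand
        return base
    if labeled is None:
        raise ValueError("labeled region mask is required for background foci")
    bg_centers = labeled.voxel_centers_mm()
    lo = bg_centers.min(axis=0)
    hi = bg_centers.max(axis=0)

    filler_terms = [t for t in vocabulary if t not in set(planted_terms)]
    study_ids = [f"study_{i + 1:05d}" for i in range(n_studies)]
    freq = np.zeros((n_studies, len(vocabulary)))
    col = {t: j for j, t in enumerate(vocabulary)}
    foci: dict[str, np.ndarray] = {}

    for i in range(n_studies):
        present: set[str] = set()
        active: set[str] = set()
        coupled_sets: list[tuple[PlantedAssociation, bool]] = []

        for key, fam in fam_items:
            prev = marginal_prevalence if key.startswith("marginal::") else term_prevalence
            pi = min(1.0, prev * len(fam))
            u = rng.random()
            if u < pi:
                a = fam[min(int(u / pi * len(fam)), len(fam) - 1)]
                present.add(a.term)
                if a.kind == "conjunction":
                    coupled_sets.append((a, rng.random() < coupling_rate))
                else:
                    if rng.random() < signal_rate:
                        active.update(a.rois)

        coupled_rois = {r for a, _ in coupled_sets for r in a.rois}
        for a, fired in coupled_sets:
            if fired:
                active.update(a.rois)
        for r in conj_pool:
            if r not in coupled_rois and rng.random() < coupling_rate:
                active.add(r)
        for r in sorted(rois):
            if rng.random() < base_rate:
                active.add(r)

        for t in filler_terms:
            if rng.random() < filler_prevalence:
                present.add(t)
        for t in present:
            freq[i, col[t]] = rng.uniform(0.01, 0.3)

        bg = bg_centers[rng.integers(len(bg_centers), size=foci_per_study)]
        bg = bg + rng.normal(0.0, jitter_sd_mm, size=bg.shape)
        pts = [np.clip(bg, lo, hi)]
        for r in sorted(active):
            pts.append(_roi_focus(rng, r)[None, :])
        foci[study_ids[i]] = np.vstack(pts)

    term_freq = pd.DataFrame(freq, index=study_ids, columns=vocabulary)
    return CoordinateDatabase(foci, term_freq)


def make_topic_mapping(vocabulary: list[str], n_topics: int = 8,
                       seed: int = 0) -> TopicMapping:
    """Deterministic round-robin hard assignment of every term to a topic."""
    if not (1 <= n_topics <= len(vocabulary)):
        raise ValueError("need 1 <= n_topics <= |vocabulary|")
    names = {k: f"topic_{k:02d}" for k in range(1, n_topics + 1)}
    mapping = {t: 1 + i % n_topics for i, t in enumerate(vocabulary)}
    return TopicMapping(mapping, names)


@dataclass
class SyntheticFixture:
    """Everything the pipeline needs, generated from one RNG seed."""

    parcellation: Parcellation
    networks: NetworkPartition
    seed_maps: list[ProbabilityMap]
    seed_masks: dict[str, RegionMask]
    truth: SyntheticTruth
    vocabulary: list[str]
    allowlist: list[str]
    db: CoordinateDatabase
    topics: TopicMapping
    params: dict = field(default_factory=dict)

    @property
    def labeled(self) -> RegionMask:
        return RegionMask(self.parcellation.grid, self.parcellation.labels > 0,
                          name="labeled")

    def rois(self) -> dict[str, RegionMask]:
        out = dict(self.seed_masks)
        for lab in self.parcellation.label_ids:
            out[f"parcel_{lab:03d}"] = self.parcellation.parcel_mask(lab)
        return out


def make_fixture(seed: int = 0, grid_shape: tuple[int, int, int] = (24, 24, 24),
                 n_parcels: int = 40, k_seeds: int = 6, n_studies: int = 2000,
                 n_topics: int = 8, seed_threshold: float = 0.25,
                 **db_kwargs) -> SyntheticFixture:
    """Generate the default toy study: atlas, seeds, truth, coordinate
    database and topic mapping, all derived from one seed."""
    parcellation, networks = make_atlas(grid_shape, n_parcels, seed=seed)
    seed_maps = make_seed_probability_maps(parcellation.grid, k_seeds, seed=seed)
    seed_masks = _seed_masks(seed_maps, seed_threshold)
    truth, vocabulary, allowlist = plant_truth(parcellation, seed_masks, seed=seed)

    rois = dict(seed_masks)
    needed = {r for a in truth.associations for r in a.rois} - set(rois)
    for r in sorted(needed):
        lab = int(r.split("_")[1])
        rois[r] = parcellation.parcel_mask(lab)
        rois[r] = RegionMask(parcellation.grid, rois[r].members, name=r)

    labeled = RegionMask(parcellation.grid, parcellation.labels > 0, name="labeled")
    db = simulate_coordinate_db(vocabulary, rois, truth, n_studies=n_studies,
                                labeled=labeled, seed=seed, **db_kwargs)
    topics = make_topic_mapping(vocabulary, n_topics, seed=seed)
    params = {"seed": int(seed), "grid_shape": list(grid_shape),
              "n_parcels": n_parcels, "k_seeds": k_seeds,
              "n_studies": n_studies, "n_topics": n_topics,
              "seed_threshold": seed_threshold}
    return SyntheticFixture(parcellation, networks, seed_maps, seed_masks,
                            truth, vocabulary, allowlist, db, topics, params)
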