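"""End-to-end orchestration: seed definition, RSFC, connected regions,
per-seed decoding, systems decoding, topic aggregation and network overlap.

The pipeline is deterministic given its configuration (every stochastic
stage consumes a recorded seed) and writes each stage's tables and maps to
an output directory, together with a serialised copy of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as sio
from .decoder import decode_roi, select_terms
from .overlap import topic_network_overlap
from .rsfc import fwe_threshold, group_map, seed_connectivity, seed_timeseries
from .spatial import threshold_probability
from .synthetic import (
    SyntheticFixture,
    brain_mask,
    make_fixture,
    simulate_subject_bold,
)
from .systems import (
    DecodingParams,
    group_into_topics,
    seed_contribution,
    systems_decode,
)
from .rsfc import connected_regions as _connected_regions

log = logging.getLogger("sysdecode")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with their defaults.

    Thresholds: seed probability > 0.25; voxel-level FWE alpha 0.05
    (Bonferroni by default); parcel overlap >= 0.8; decoding prior 0.5;
    term binarisation f_min 0.001; activation radius 0 mm (strict in-mask,
    appropriate for the toy fixture scale where parcels span only a few
    voxels); top-30 term selection; BH-FDR alpha 0.05.
    """

    seed_threshold: float = 0.25
    fwe_alpha: float = 0.05
    fwe_method: str = "bonferroni"
    min_overlap: float = 0.8
    prior: float = 0.5
    f_min: float = 0.001
    radius_mm: float = 0.0
    k: int = 30
    order: str = "rank_then_filter"
    pair_mode: str = "both"
    fdr_alpha: float = 0.05
    rng_seed: int = 0
    # synthetic-study conditions
    n_subjects: int = 20
    T: int = 400
    tr: float = 0.8
    effect_r: float = 0.5
    n_studies: int = 2000
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_parcels: int = 40
    k_seeds: int = 6
    n_topics: int = 8

    def __post_init__(self) -> None:
        if not (0 <= self.seed_threshold < 1):
            raise ValueError("seed_threshold must lie in [0, 1)")
        for name in ("fwe_alpha", "fdr_alpha"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0 < self.min_overlap <= 1):
            raise ValueError("min_overlap must lie in (0, 1]")
        if not (0 <= self.prior <= 1):
            raise ValueError("prior must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    config: PipelineConfig
    fixture: SyntheticFixture
    connected: dict[str, list[tuple[int, float]]]
    seed_decodings: dict[str, list[str]]
    system: object
    topic_map: object
    overlap: object
    contribution: object
    out_dir: Path | None = None


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 fixture: SyntheticFixture | None = None) -> PipelineResult:
    """Run every stage on a synthetic fixture (generated from the config's
    RNG seed unless one is supplied) and optionally write all products."""
    if fixture is None:
        log.info("stage simulate: seed=%d grid=%s parcels=%d seeds=%d studies=%d",
                 config.rng_seed, config.grid_shape, config.n_parcels,
                 config.k_seeds, config.n_studies)
        fixture = make_fixture(seed=config.rng_seed, grid_shape=config.grid_shape,
                               n_parcels=config.n_parcels, k_seeds=config.k_seeds,
                               n_studies=config.n_studies, n_topics=config.n_topics,
                               seed_threshold=config.seed_threshold)
    parc = fixture.parcellation

    # stage: seed definition (threshold probability maps)
    log.info("stage seeds: threshold > %.2f", config.seed_threshold)
    seed_masks = {m.name: threshold_probability(m, config.seed_threshold)
                  for m in fixture.seed_maps}
    for name, m in seed_masks.items():
        if m.is_empty:
            raise ValueError(f"seed {name} empty after thresholding")

    # stage: RSFC -> group map -> FWE -> connected regions, per seed
    brain = brain_mask(parc, seed_masks)
    all_seeds = list(seed_masks.values())
    connected: dict[str, list[tuple[int, float]]] = {}
    log.info("stage rsfc: N=%d T=%d effect_r=%.2f fwe=%s alpha=%.3f overlap>=%.2f",
             config.n_subjects, config.T, config.effect_r, config.fwe_method,
             config.fwe_alpha, config.min_overlap)
    subject_bolds = [
        simulate_subject_bold(parc, seed_masks, fixture.truth, i, T=config.T,
                              tr=config.tr, effect_r=config.effect_r,
                              seed=config.rng_seed)
        for i in range(config.n_subjects)
    ]
    for name in sorted(seed_masks):
        maps = []
        for bold in subject_bolds:
            ts = seed_timeseries(bold, seed_masks[name])
            maps.append(seed_connectivity(bold, ts, brain, seed_name=name))
        gmap = group_map(maps)
        supra = fwe_threshold(gmap, alpha=config.fwe_alpha,
                              method=config.fwe_method,
                              rng=config.rng_seed)
        connected[name] = _connected_regions(supra, parc, all_seeds,
                                             min_overlap=config.min_overlap,
                                             seed_name=name)
    del subject_bolds

    # stage: per-seed reverse-inference decoding
    log.info("stage decode: prior=%.2f f_min=%g radius=%.1fmm k=%d fdr=%.2f",
             config.prior, config.f_min, config.radius_mm, config.k,
             config.fdr_alpha)
    allow = frozenset(fixture.allowlist)
    seed_decodings: dict[str, list[str]] = {}
    seed_results = {}
    for name in sorted(seed_masks):
        res = decode_roi(fixture.db, seed_masks[name], radius_mm=config.radius_mm,
                         prior=config.prior, f_min=config.f_min,
                         alpha=config.fdr_alpha)
        seed_results[name] = res
        # per-seed reporting keeps all significant top-k terms (anatomical
        # vocabulary included); the construct filter applies downstream
        seed_decodings[name] = select_terms(res, config.k, None, config.order)

    # stage: systems-level decoding over all seed-cortical pairs
    params = DecodingParams(radius_mm=config.radius_mm, prior=config.prior,
                            f_min=config.f_min, alpha=config.fdr_alpha,
                            k=config.k, order=config.order,
                            pair_mode=config.pair_mode,
                            construct_allowlist=allow)
    log.info("stage systems: pair_mode=%s over %d pairs", config.pair_mode,
             sum(len(v) for v in connected.values()))
    conn_labels = {s: [lab for lab, _ in v] for s, v in connected.items()}
    system = systems_decode(fixture.db, seed_masks, conn_labels, parc, params)

    # stage: topic aggregation and network overlap
    topic_map = group_into_topics(system, fixture.topics)
    overlap = topic_network_overlap(topic_map, parc, fixture.networks)
    counts, multiplicity = seed_contribution(topic_map, parc)

    result = PipelineResult(config, fixture, connected, seed_decodings,
                            system, topic_map, overlap, (counts, multiplicity))
    if out_dir is not None:
        result.out_dir = _write_outputs(result, Path(out_dir), seed_results)
    return result


def _write_outputs(result: PipelineResult, out: Path, seed_results) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    (out / "config.json").write_text(cfg.to_json())
    (out / "provenance.json").write_text(json.dumps({
        "config_hash": cfg.config_hash, "rng_seed": cfg.rng_seed,
    }, indent=2))
    fx = result.fixture
    sio.write_parcellation(fx.parcellation, out / "parcellation.nii.gz",
                           out / "parcellation_labels.tsv")
    sio.write_network_partition(fx.networks, out / "networks.nii.gz",
                                out / "network_names.tsv")
    for m in fx.seed_maps:
        sio.write_probability_map(m, out / f"seedmap_{m.name}.nii.gz")
    sio.write_coordinate_db(fx.db, out / "foci.tsv", out / "term_frequencies.tsv")
    sio.write_allowlist(fx.allowlist, out / "construct_allowlist.txt")
    sio.write_topic_mapping(fx.topics, out / "topic_mapping.tsv")
    (out / "truth.json").write_text(fx.truth.to_json())

    sio.write_connected_regions(result.connected, fx.parcellation,
                                out / "connected_regions.tsv")
    for name, res in seed_results.items():
        sio.write_decoding_result(res, out / f"decoding_{name}.tsv")
    import pandas as pd
    sio.write_tsv(pd.DataFrame(
        [{"seed": s, "rank": i + 1, "term": t}
         for s in sorted(result.seed_decodings)
         for i, t in enumerate(result.seed_decodings[s])],
        columns=["seed", "rank", "term"]), out / "seed_terms.tsv")
    sio.write_system_map(result.system, out / "system_map.tsv")
    sio.write_topic_surface_map(result.topic_map, out / "topic_surface_map.tsv")
    ov = result.overlap.copy()
    for c in ("pct_topic_in_network", "pct_network_in_topic"):
        ov[c] = ov[c].map(lambda v: f"{v:.6f}")
    sio.write_tsv(ov, out / "network_overlap.tsv")
    counts, multiplicity = result.contribution
    sio.write_tsv(counts, out / "seed_contribution_counts.tsv")
    sio.write_tsv(multiplicity, out / "seed_contribution_multiplicity.tsv")
    return out
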