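"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as NIfTI-1 (probabilities float32, masks uint8, labels
int32; the affine lives in the header). Tables travel as TSV with fixed
column orders; floats are written in their shortest round-trip
representation, percentages with six decimals.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .decoder import CoordinateDatabase, DecodingResult
from .spatial import (
    NetworkPartition,
    Parcellation,
    ProbabilityMap,
    RegionMask,
    VolumeGrid,
)
from .systems import SystemMap, TopicMapping, TopicSurfaceMap

__all__ = [
    "read_probability_map", "write_probability_map",
    "read_mask", "write_mask",
    "read_parcellation", "write_parcellation",
    "read_network_partition", "write_network_partition",
    "read_coordinate_db", "write_coordinate_db",
    "read_allowlist", "write_allowlist",
    "read_topic_mapping", "write_topic_mapping",
    "write_decoding_result", "read_decoding_result",
    "write_connected_regions", "read_connected_regions",
    "write_system_map", "write_topic_surface_map",
    "write_tsv",
]


class MalformedTableError(ValueError):
    """A TSV row failed validation; the message names the offending line."""


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=None)


# -- volumes ---------------------------------------------------------------

def write_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    nib.save(pmap.to_nifti(), str(path))


def read_probability_map(path: str | Path, name: str = "") -> ProbabilityMap:
    return ProbabilityMap.from_nifti(nib.load(str(path)), name=name or Path(path).stem)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    nib.save(mask.to_nifti(), str(path))


def read_mask(path: str | Path, name: str = "") -> RegionMask:
    return RegionMask.from_nifti(nib.load(str(path)), name=name or Path(path).stem)


def write_parcellation(parc: Parcellation, nifti_path: str | Path,
                       table_path: str | Path) -> None:
    nib.save(parc.to_nifti(), str(nifti_path))
    t = parc.table.reset_index()
    t.columns = ["label", "name", "hemisphere", "group"]
    write_tsv(t, table_path)


def read_parcellation(nifti_path: str | Path, table_path: str | Path) -> Parcellation:
    table = _read_label_table(table_path)
    return Parcellation.from_nifti(nib.load(str(nifti_path)), table)


def _read_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "name", "hemisphere", "group"}
    if not required <= set(df.columns):
        raise MalformedTableError(
            f"{path}: label table needs columns {sorted(required)}")
    for i, row in df.iterrows():
        if row["hemisphere"] not in ("L", "R"):
            raise MalformedTableError(
                f"{path}: line {i + 2}: hemisphere must be L or R")
    return df.set_index("label")


def write_network_partition(nets: NetworkPartition, nifti_path: str | Path,
                            names_path: str | Path) -> None:
    nib.save(nets.to_nifti(), str(nifti_path))
    df = pd.DataFrame(sorted(nets.names.items()), columns=["network", "name"])
    write_tsv(df, names_path)


def read_network_partition(nifti_path: str | Path,
                           names_path: str | Path) -> NetworkPartition:
    img = nib.load(str(nifti_path))
    df = pd.read_csv(names_path, sep="\t")
    names = {int(r["network"]): str(r["name"]) for _, r in df.iterrows()}
    data = np.round(np.asarray(img.get_fdata())).astype(np.int32)
    return NetworkPartition(VolumeGrid(data.shape, img.affine), data, names)


# -- coordinate database ---------------------------------------------------

def write_coordinate_db(db: CoordinateDatabase, foci_path: str | Path,
                        freq_path: str | Path) -> None:
    rows = []
    for study in db.studies:
        for x, y, z in db.foci.get(study, np.empty((0, 3))):
            rows.append({"study_id": study, "x": x, "y": y, "z": z})
    write_tsv(pd.DataFrame(rows, columns=["study_id", "x", "y", "z"]), foci_path)
    tf = db.term_freq.reset_index()
    tf.columns = ["study_id", *db.vocabulary]
    write_tsv(tf, freq_path)


def read_coordinate_db(foci_path: str | Path,
                       freq_path: str | Path) -> CoordinateDatabase:
    foci_df = pd.read_csv(foci_path, sep="\t", dtype={"study_id": str})
    for i, row in foci_df.iterrows():
        try:
            [float(row[c]) for c in ("x", "y", "z")]
        except (TypeError, ValueError):
            raise MalformedTableError(
                f"{foci_path}: line {i + 2}: bad coordinate row") from None
    freq = pd.read_csv(freq_path, sep="\t", dtype={"study_id": str})
    freq = freq.set_index("study_id")
    foci = {str(s): g[["x", "y", "z"]].to_numpy(dtype=float)
            for s, g in foci_df.groupby("study_id")}
    return CoordinateDatabase(foci, freq)


# -- small text files ------------------------------------------------------

def write_allowlist(terms: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(terms) + "\n")


def read_allowlist(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_topic_mapping(mapping: TopicMapping, path: str | Path) -> None:
    rows = [{"term": t, "topic_id": k, "topic_name": mapping.topic_names[k]}
            for t, k in sorted(mapping.term_to_topic.items())]
    write_tsv(pd.DataFrame(rows, columns=["term", "topic_id", "topic_name"]), path)


def read_topic_mapping(path: str | Path) -> TopicMapping:
    df = pd.read_csv(path, sep="\t")
    required = {"term", "topic_id", "topic_name"}
    if not required <= set(df.columns):
        raise MalformedTableError(f"{path}: needs columns {sorted(required)}")
    mapping = {str(r["term"]): int(r["topic_id"]) for _, r in df.iterrows()}
    names = {int(r["topic_id"]): str(r["topic_name"]) for _, r in df.iterrows()}
    return TopicMapping(mapping, names)


# -- results ---------------------------------------------------------------

def write_decoding_result(result: DecodingResult, path: str | Path) -> None:
    write_tsv(result.rows, path)


def read_decoding_result(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_connected_regions(connected: dict[str, list[tuple[int, float]]],
                            parcellation: Parcellation, path: str | Path) -> None:
    rows = []
    for seed_name in sorted(connected):
        for lab, frac in connected[seed_name]:
            rows.append({"seed": seed_name, "parcel": lab,
                         "parcel_name": str(parcellation.table.loc[lab, "name"]),
                         "overlap_fraction": f"{frac:.6f}"})
    write_tsv(pd.DataFrame(rows, columns=["seed", "parcel", "parcel_name",
                                          "overlap_fraction"]), path)


def read_connected_regions(path: str | Path) -> dict[str, list[tuple[int, float]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, float]]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["seed"]), []).append(
            (int(r["parcel"]), float(r["overlap_fraction"])))
    return out


def write_system_map(system: SystemMap, path: str | Path) -> None:
    """Long format: one row per (seed, parcel, term, status)."""
    rows = []
    for pair in system.pairs:
        for term in sorted(pair.terms_specific):
            rows.append({"seed": pair.seed_name, "parcel": pair.parcel_label,
                         "term": term, "status": "specific"})
        for term in sorted(pair.terms_shared):
            rows.append({"seed": pair.seed_name, "parcel": pair.parcel_label,
                         "term": term, "status": "shared"})
    write_tsv(pd.DataFrame(rows, columns=["seed", "parcel", "term", "status"]), path)


def write_topic_surface_map(topic_map: TopicSurfaceMap, path: str | Path) -> None:
    write_tsv(topic_map.to_frame(), path)
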