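"""Seed-based resting-state functional connectivity.

Subject-level maps are Pearson correlations of each in-brain voxel's BOLD
series with the mean seed series, Fisher z-transformed (z = atanh(r), r
clipped to +/-(1 - 1e-7)). Subject z-maps enter a random-effects group
analysis (one-sample t against zero), the group map is thresholded with
voxel-level family-wise error control, and cortical parcels covered by the
suprathreshold map by at least ``min_overlap`` of their volume — and not
touching any seed — are retained as the seed's functionally coupled regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import stats

from .spatial import (
    Parcellation,
    RegionMask,
    VolumeGrid,
    _require_same_grid,
    any_overlap,
    overlap_fraction,
)

__all__ = [
    "Bold4D",
    "ConnectivityMap",
    "GroupMap",
    "ConnectedRegions",
    "seed_timeseries",
    "seed_connectivity",
    "group_map",
    "fwe_threshold",
    "connected_regions",
]

R_CLIP = 1.0 - 1e-7  # correlation magnitude cap before atanh


@dataclass(frozen=True)
class Bold4D:
    """A subject's 4-D BOLD run: per-voxel time series of length T."""

    grid: VolumeGrid
    series: np.ndarray  # shape grid.shape + (T,)
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        ser = np.asarray(self.series, dtype=float)
        if ser.shape[:3] != self.grid.shape or ser.ndim != 4:
            raise ValueError("series must have shape grid.shape + (T,)")
        if ser.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(ser)):
            raise ValueError("BOLD series must be finite")
        object.__setattr__(self, "series", ser)

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.series.astype(np.float32), self.grid.affine)
        img.header.set_zooms((*self.grid.voxel_size, self.tr))
        return img

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, subject_id: str = "",
                   tr: float | None = None) -> "Bold4D":
        data = np.asarray(img.get_fdata(), dtype=float)
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(VolumeGrid(data.shape[:3], img.affine), data, tr, subject_id)


@dataclass(frozen=True)
class ConnectivityMap:
    """Subject-level Fisher-z seed-correlation map, defined inside a brain
    mask and NaN outside."""

    grid: VolumeGrid
    stat: np.ndarray
    brain: RegionMask
    subject_id: str = ""
    seed_name: str = ""

    def __post_init__(self) -> None:
        st = np.asarray(self.stat, dtype=float)
        if st.shape != self.grid.shape:
            raise ValueError("stat must conform to grid")
        if not np.all(np.isfinite(st[self.brain.members])):
            raise ValueError("stat must be finite inside the brain mask")
        object.__setattr__(self, "stat", st)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.stat.astype(np.float32), self.grid.affine)


@dataclass(frozen=True)
class GroupMap:
    """Random-effects group map: one-sample t statistic per voxel."""

    grid: VolumeGrid
    tstat: np.ndarray
    df: int
    n_subjects: int
    brain: RegionMask
    seed_name: str = ""
    subject_stats: np.ndarray | None = None  # (N, n_brain_voxels), for permutation

    def __post_init__(self) -> None:
        if self.df != self.n_subjects - 1 or self.df < 1:
            raise ValueError("df must equal n_subjects - 1 and be >= 1")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.tstat.astype(np.float32), self.grid.affine)


@dataclass(frozen=True)
class ConnectedRegions:
    """Per-seed list of (parcel label, overlap fraction) retained as
    functionally coupled regions."""

    regions: dict[str, list[tuple[int, float]]] = field(default_factory=dict)

    def labels(self, seed_name: str) -> list[int]:
        return [lab for lab, _ in self.regions.get(seed_name, [])]

    def __iter__(self):
        return iter(self.regions.items())


def seed_timeseries(bold: Bold4D, seed: RegionMask) -> np.ndarray:
    """Mean BOLD series over the seed's voxels (length T)."""
    _require_same_grid(bold.grid, seed.grid)
    if seed.is_empty:
        raise ValueError("seed mask is empty")
    return bold.series[seed.members].mean(axis=0)


def seed_connectivity(bold: Bold4D, seed_ts: np.ndarray, brain: RegionMask,
                      subject_id: str | None = None,
                      seed_name: str = "") -> ConnectivityMap:
    """Correlate every in-brain voxel's series with the seed series.

    Returns Fisher z = atanh(r) per voxel; voxels with zero temporal
    variance get z = 0 (they can never be 'connected').
    """
    _require_same_grid(bold.grid, brain.grid)
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.shape != (bold.n_timepoints,):
        raise ValueError("seed series length must match BOLD length")
    if brain.is_empty:
        raise ValueError("brain mask is empty")
    s = seed_ts - seed_ts.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError("seed series has zero variance")
    s = s / s_norm

    X = bold.series[brain.members]  # (V, T)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    nz = norms > 0
    r = np.zeros(X.shape[0])
    r[nz] = (Xc[nz] @ s) / norms[nz]
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z[~nz] = 0.0

    stat = np.full(bold.grid.shape, np.nan)
    stat[brain.members] = z
    return ConnectivityMap(bold.grid, stat, brain,
                           subject_id=bold.subject_id if subject_id is None else subject_id,
                           seed_name=seed_name)


def group_map(maps: list[ConnectivityMap]) -> GroupMap:
    """One-sample t statistic of subject z-maps against zero (df = N-1).

    A voxel where all subjects agree on a nonzero constant has zero
    between-subject variance; its t is reported as +/-inf (sign of the
    mean). Zero mean with zero variance gives t = 0.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects for a random-effects map")
    grid = maps[0].grid
    brain = maps[0].brain
    for m in maps[1:]:
        _require_same_grid(grid, m.grid)
    Z = np.stack([m.stat[brain.members] for m in maps])  # (N, V)
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0

    tvol = np.full(grid.shape, np.nan)
    tvol[brain.members] = t
    return GroupMap(grid, tvol, df=n - 1, n_subjects=n, brain=brain,
                    seed_name=maps[0].seed_name, subject_stats=Z)


def _tail_p(t: np.ndarray, df: int, two_sided: bool) -> np.ndarray:
    if two_sided:
        return 2.0 * stats.t.sf(np.abs(t), df)
    return stats.t.sf(t, df)


def fwe_threshold(group: GroupMap, alpha: float = 0.05,
                  method: str = "bonferroni", two_sided: bool = False,
                  n_permutations: int = 1000,
                  rng: np.random.Generator | int | None = 0) -> RegionMask:
    """Voxels surviving voxel-level FWE control at ``alpha`` over the brain mask.

    ``bonferroni`` compares each voxel's t p-value against alpha / V.
    ``permutation`` builds a max-statistic null by sign-flipping the subject
    maps (requires the group map to carry its subject stats).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    brain = group.brain
    t = group.tstat[brain.members]

    if method == "bonferroni":
        p = _tail_p(t, group.df, two_sided)
        survived = p <= alpha / t.size
    elif method == "permutation":
        Z = group.subject_stats
        if Z is None:
            raise ValueError("permutation needs subject-level stats on the group map")
        n = group.n_subjects
        if n < 6:
            warnings.warn("permutation null with <6 subjects is coarse", stacklevel=2)
        rng = np.random.default_rng(rng)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        S2 = (Z**2).sum(axis=0)  # invariant under sign flips
        mean_b = (signs @ Z) / n  # (B, V)
        var_b = np.maximum(S2[None, :] - n * mean_b**2, 0.0) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_b = mean_b / np.sqrt(var_b / n)
        t_b = np.nan_to_num(t_b, nan=0.0, posinf=np.inf, neginf=-np.inf)
        max_null = np.abs(t_b).max(axis=1) if two_sided else t_b.max(axis=1)
        obs = np.abs(t) if two_sided else t
        # p_fwe includes the observed labelling so p >= 1/(B+1)
        exceed = (max_null[None, :] >= obs[:, None]).sum(axis=1)
        p_fwe = (1 + exceed) / (n_permutations + 1)
        survived = p_fwe <= alpha
    else:
        raise ValueError(f"unknown FWE method {method!r}")

    members = np.zeros(group.grid.shape, dtype=bool)
    members[brain.members] = survived
    return RegionMask(group.grid, members, name=f"{group.seed_name}_fwe")


def connected_regions(suprathreshold: RegionMask, parcellation: Parcellation,
                      seeds: list[RegionMask], min_overlap: float = 0.8,
                      seed_name: str = "") -> list[tuple[int, float]]:
    """Parcels covered by the suprathreshold map by >= ``min_overlap`` of
    their volume, excluding any parcel that shares a voxel with any seed.
    """
    _require_same_grid(suprathreshold.grid, parcellation.grid)
    out: list[tuple[int, float]] = []
    for label in parcellation.label_ids:
        if parcellation.parcel_size(label) == 0:
            continue
        frac = overlap_fraction(suprathreshold, parcellation, label)
        if frac < min_overlap:
            continue
        parcel = parcellation.parcel_mask(label)
        if any(any_overlap(parcel, s) for s in seeds):
            continue
        out.append((label, frac))
    return out
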