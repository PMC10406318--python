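"""Coordinate-based Bayesian reverse-inference decoding of a single ROI.

The decoder works against a coordinate database: a set of studies, each
with reported activation foci (MNI mm) and term frequencies in [0, 1]. A
study "activates" an ROI when at least one of its foci lies within
``radius_mm`` of an ROI voxel center. Terms are binarised at a frequency
cutoff ``f_min``; for each term the empirical likelihoods
P(activation | term) and P(activation | not term) are combined through a
fixed prior into the forward probability

    P(activation | term, p) = p * P(act | term) + (1 - p) * P(act | ~term)

and the reverse-inference posterior

    P(term | activation, p) = p * P(act | term) / P(activation | term, p).

The prior defaults to 0.5, which deliberately equates the very different
base rates of terms in the database so that posteriors are comparable
across terms. Association strength is additionally tested with a two-way
chi-square (df = 1, no continuity correction) and Benjamini-Hochberg FDR
across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .spatial import RegionMask

__all__ = [
    "CoordinateDatabase",
    "TermLabeling",
    "ActivationVector",
    "DecodingResult",
    "activation_vector",
    "condition_probs",
    "forward_inference",
    "reverse_inference",
    "chi_square_association",
    "fdr_correct",
    "decode_roi",
    "select_terms",
]


@dataclass(frozen=True)
class CoordinateDatabase:
    """Studies, their activation foci (MNI mm) and term frequencies.

    ``foci`` maps study id -> (n, 3) float array; ``term_freq`` is a
    DataFrame with study ids as index and the vocabulary as columns,
    entries in [0, 1].
    """

    foci: dict[str, np.ndarray]
    term_freq: pd.DataFrame

    def __post_init__(self) -> None:
        foci = {str(s): np.asarray(f, dtype=float).reshape(-1, 3)
                for s, f in self.foci.items()}
        unknown = set(foci) - set(map(str, self.term_freq.index))
        if unknown:
            raise ValueError(f"foci for unknown studies: {sorted(unknown)[:5]}")
        tf = self.term_freq
        if tf.columns.duplicated().any():
            raise ValueError("vocabulary has duplicate terms")
        vals = tf.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("term frequencies must lie in [0, 1]")
        object.__setattr__(self, "foci", foci)

    @property
    def studies(self) -> list[str]:
        return [str(s) for s in self.term_freq.index]

    @property
    def vocabulary(self) -> list[str]:
        return [str(t) for t in self.term_freq.columns]

    @property
    def n_studies(self) -> int:
        return len(self.term_freq)


@dataclass(frozen=True)
class TermLabeling:
    """Study x term binary matrix: 1 iff term frequency >= f_min."""

    matrix: pd.DataFrame
    f_min: float

    @classmethod
    def from_database(cls, db: CoordinateDatabase, f_min: float = 0.001) -> "TermLabeling":
        return cls((db.term_freq >= f_min).astype(np.int8), f_min)

    def column(self, term: str) -> np.ndarray:
        return self.matrix[term].to_numpy(dtype=bool)


@dataclass(frozen=True)
class ActivationVector:
    """Per-study boolean flag: does the study report a focus in/near the ROI."""

    active: np.ndarray
    studies: list[str]
    roi_name: str
    radius_mm: float

    def __post_init__(self) -> None:
        act = np.asarray(self.active, dtype=bool)
        if act.shape != (len(self.studies),):
            raise ValueError("activation vector length must match study count")
        object.__setattr__(self, "active", act)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


@dataclass(frozen=True)
class DecodingResult:
    """Per-term decoding table for one ROI.

    ``rows`` has columns: term, p_act_given_term, p_act_given_notterm,
    forward, posterior, chi2, p_value, q_value, significant.
    """

    roi_name: str
    prior: float
    rows: pd.DataFrame
    n_active_studies: int
    n_studies: int
    radius_mm: float = 0.0
    excluded_terms: list[str] = field(default_factory=list)


def activation_vector(db: CoordinateDatabase, roi: RegionMask,
                      radius_mm: float = 6.0) -> ActivationVector:
    """Flag each study active iff one of its foci lies within ``radius_mm``
    of an ROI voxel center (radius 0: the focus must fall inside an ROI
    voxel, i.e. within half a voxel of its center in each axis)."""
    if roi.is_empty:
        raise ValueError("ROI mask is empty")
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    centers = roi.voxel_centers_mm()
    studies = db.studies
    active = np.zeros(len(studies), dtype=bool)

    if radius_mm == 0:
        # in-voxel membership: map foci to voxel indices and test the mask
        inv_lookup = {tuple(ijk): True for ijk in map(tuple, roi.voxel_indices())}
        for i, s in enumerate(studies):
            f = db.foci.get(s)
            if f is None or len(f) == 0:
                continue
            vox = np.round(roi.grid.world_to_voxel(f)).astype(int)
            active[i] = any(tuple(v) in inv_lookup for v in vox)
    else:
        tree = cKDTree(centers)
        for i, s in enumerate(studies):
            f = db.foci.get(s)
            if f is None or len(f) == 0:
                continue
            d, _ = tree.query(f, k=1)
            active[i] = bool((d <= radius_mm).any())
    return ActivationVector(active, studies, roi.name, radius_mm)


def condition_probs(act: ActivationVector, lab: TermLabeling,
                    term: str) -> tuple[float, float]:
    """Empirical (P(act | term), P(act | ~term)) as simple proportions."""
    has = lab.column(term)
    n1, n0 = int(has.sum()), int((~has).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"term {term!r} has a degenerate stratum")
    a = act.active
    return float(a[has].mean()), float(a[~has].mean())


def forward_inference(pat: float, patn: float, prior: float) -> float:
    """P(activation | term, p) = p*P(act|term) + (1-p)*P(act|~term)."""
    for v in (pat, patn, prior):
        if not (0.0 <= v <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    return prior * pat + (1.0 - prior) * patn


def reverse_inference(pat: float, patn: float, prior: float = 0.5) -> float:
    """P(term | activation, p) = p*P(act|term) / P(activation|term, p)."""
    fwd = forward_inference(pat, patn, prior)
    if fwd == 0.0:
        raise ValueError("forward probability is zero; posterior undefined")
    return prior * pat / fwd


def chi_square_association(act: ActivationVector, lab: TermLabeling,
                           term: str, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) of the 2x2 activation x term table.

    A zero marginal makes the term uninformative: (0, 1) is returned.
    """
    has = lab.column(term)
    a = act.active
    table = np.array([
        [int((a & has).sum()), int((a & ~has).sum())],
        [int((~a & has).sum()), int((~a & ~has).sum())],
    ], dtype=float)
    return _chi2_from_table(table, correction)


def _chi2_from_table(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if n == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = np.outer(row, col) / n
    diff = np.abs(table - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def fdr_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, rejected flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected


def decode_roi(db: CoordinateDatabase, roi: RegionMask | ActivationVector,
               radius_mm: float = 6.0, prior: float = 0.5,
               f_min: float = 0.001, alpha: float = 0.05,
               correction: bool = False) -> DecodingResult:
    """Full reverse-inference decoding of one ROI against the database.

    ``roi`` may be a mask (the activation vector is derived from foci) or a
    pre-computed :class:`ActivationVector` (used for pair decoding).
    Terms with a degenerate stratum (labelled in all or no studies) are
    excluded and reported in ``excluded_terms``.
    """
    if db.n_studies < 2:
        raise ValueError("need at least 2 studies")
    if isinstance(roi, ActivationVector):
        act = roi
    else:
        act = activation_vector(db, roi, radius_mm)
    lab = TermLabeling.from_database(db, f_min)

    # vectorised 2x2 counts over the whole vocabulary
    L = lab.matrix.to_numpy(dtype=float)  # (S, M)
    a = act.active.astype(float)
    n = float(len(a))
    n_term = L.sum(axis=0)
    computable = (n_term > 0) & (n_term < n)
    n_act_term = a @ L
    n_act = a.sum()

    terms = np.array(db.vocabulary)
    excluded = [str(t) for t in terms[~computable]]

    nt = n_term[computable]
    at = n_act_term[computable]
    pat = at / nt
    patn = (n_act - at) / (n - nt)
    fwd = prior * pat + (1.0 - prior) * patn
    ok = fwd > 0
    excluded += [str(t) for t in terms[computable][~ok]]

    keep = np.flatnonzero(computable)[ok]
    pat, patn, fwd = pat[ok], patn[ok], fwd[ok]
    posterior = prior * pat / fwd

    # chi-square per kept term, vectorised via closed-form cells
    at_k = n_act_term[keep]
    nt_k = n_term[keep]
    cells = np.stack([
        at_k, n_act - at_k,
        nt_k - at_k, n - nt_k - (n_act - at_k),
    ], axis=1)  # a,b,c,d of [[a,b],[c,d]]
    aa, bb, cc, dd = cells.T
    denom = (aa + bb) * (cc + dd) * (aa + cc) * (bb + dd)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (aa * dd - bb * cc) ** 2 / denom
    if correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = n * np.maximum(np.abs(aa * dd - bb * cc) - n / 2, 0.0) ** 2 / denom
    stat = np.where(denom > 0, stat, 0.0)
    pval = np.where(denom > 0, stats.chi2.sf(stat, df=1), 1.0)

    q, rej = fdr_correct(pval, alpha)
    rows = pd.DataFrame({
        "term": terms[keep],
        "p_act_given_term": pat,
        "p_act_given_notterm": patn,
        "forward": fwd,
        "posterior": posterior,
        "chi2": stat,
        "p_value": pval,
        "q_value": q,
        "significant": rej,
    })
    return DecodingResult(
        roi_name=act.roi_name, prior=prior, rows=rows,
        n_active_studies=act.n_active, n_studies=db.n_studies,
        radius_mm=act.radius_mm, excluded_terms=sorted(excluded),
    )


def select_terms(result: DecodingResult, k: int = 30,
                 construct_allowlist: set[str] | list[str] | None = None,
                 order: str = "rank_then_filter") -> list[str]:
    """Pick the decoded terms to report for an ROI.

    Default ``rank_then_filter``: take the ``k`` terms with highest
    posterior (ties broken lexicographically), then drop terms that did not
    survive FDR, then keep only allowlisted (psychological-construct)
    terms — mirroring a post-hoc significance and construct filter applied
    to a fixed-size top list. ``filter_then_rank`` filters first and then
    takes the top ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if order not in ("rank_then_filter", "filter_then_rank"):
        raise ValueError(f"unknown order {order!r}")
    allow = set(construct_allowlist) if construct_allowlist else None
    if construct_allowlist is not None and not allow:
        import warnings
        warnings.warn("empty construct allowlist; skipping construct filter",
                      stacklevel=2)
        allow = None

    rows = result.rows.sort_values(
        ["posterior", "term"], ascending=[False, True], kind="mergesort"
    )
    if order == "rank_then_filter":
        rows = rows.head(k)
        rows = rows[rows["significant"]]
        if allow is not None:
            rows = rows[rows["term"].isin(allow)]
    else:
        rows = rows[rows["significant"]]
        if allow is not None:
            rows = rows[rows["term"].isin(allow)]
        rows = rows.head(k)
    return [str(t) for t in rows["term"]]
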