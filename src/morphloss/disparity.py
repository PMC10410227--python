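"""Disparity indices over distance matrices and ordinations.

Three pre-ordination indices work directly on pairwise dissimilarities
(mean pairwise distance, maximum pairwise distance, mean extant-fossil
pairwise distance) and three post-ordination indices on morphospace
coordinates (sum of variances, sum of ranges, distance between the extant
and fossil centroids).  Samples are multisets of taxon labels: bootstrap
duplicates are genuine sample members, so copies of the same taxon sit at
distance zero from one another and coincide in morphospace.

Batch variants (`*_batch`) evaluate an index for many subsamples at once
from a pre-built ``(n_subsamples, size)`` index array; they are exact
vectorisations of the scalar functions and are what the resampling layer
uses.  Undefined entries (a subsample lacking one status class for a
cross-class index) come back as NaN from the batch variants, whereas the
scalar functions raise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import TipStatus
from .distance import DistanceMatrixResult
from .ordinate import OrdinationResult

__all__ = [
    "mean_pairwise_distance",
    "max_pairwise_distance",
    "mean_extant_fossil_distance",
    "sum_of_variances",
    "sum_of_ranges",
    "centroid_distance",
    "PRE_ORDINATION_INDICES",
    "POST_ORDINATION_INDICES",
    "CROSS_CLASS_INDICES",
]

PRE_ORDINATION_INDICES = ("mpd", "maxpd", "mefd")
POST_ORDINATION_INDICES = ("sov", "sor", "centroid")
#: Indices requiring both an extant and a fossil member in the sample.
CROSS_CLASS_INDICES = ("mefd", "centroid")


def _indices(dm_or_ord, sample: Sequence[str]) -> np.ndarray:
    return np.array([dm_or_ord.index_of(t) for t in sample], dtype=np.int64)


def _status_mask(obj, sample: Sequence[str], which: TipStatus) -> np.ndarray:
    return np.array([obj.status[t] is which for t in sample], dtype=bool)


# ---------------------------------------------------------------- scalar


def mean_pairwise_distance(dm: DistanceMatrixResult, sample: Sequence[str]) -> float:
    """Mean dissimilarity over all unordered pairs of distinct sample positions."""
    idx = _indices(dm, sample)
    m = idx.size
    if m < 2:
        raise ValueError("mean pairwise distance needs a sample of size >= 2")
    S = dm.D[np.ix_(idx, idx)]
    return float(S.sum() / (m * (m - 1)))


def max_pairwise_distance(dm: DistanceMatrixResult, sample: Sequence[str]) -> float:
    """Largest dissimilarity between any two sample positions."""
    idx = _indices(dm, sample)
    if idx.size < 2:
        raise ValueError("max pairwise distance needs a sample of size >= 2")
    return float(dm.D[np.ix_(idx, idx)].max())


def mean_extant_fossil_distance(
    dm: DistanceMatrixResult, sample: Sequence[str]
) -> float:
    """Mean dissimilarity over all (extant, fossil) cross-class pairs."""
    idx = _indices(dm, sample)
    extant = _status_mask(dm, sample, TipStatus.EXTANT)
    if not extant.any() or extant.all():
        raise ValueError(
            "mean extant-fossil distance requires both classes in the sample"
        )
    return float(dm.D[np.ix_(idx[extant], idx[~extant])].mean())


def sum_of_variances(ord_: OrdinationResult, sample: Sequence[str]) -> float:
    """Sum over retained axes of the sample variance (n - 1 denominator)."""
    idx = _indices(ord_, sample)
    if idx.size < 2:
        raise ValueError("sum of variances needs a sample of size >= 2")
    return float(ord_.coordinates[idx].var(axis=0, ddof=1).sum())


def sum_of_ranges(ord_: OrdinationResult, sample: Sequence[str]) -> float:
    """Sum over retained axes of (max - min) of the sample scores."""
    idx = _indices(ord_, sample)
    if idx.size < 1:
        raise ValueError("sum of ranges needs a non-empty sample")
    coords = ord_.coordinates[idx]
    return float((coords.max(axis=0) - coords.min(axis=0)).sum())


def centroid_distance(ord_: OrdinationResult, sample: Sequence[str]) -> float:
    """Euclidean distance between the extant and fossil centroids."""
    idx = _indices(ord_, sample)
    extant = _status_mask(ord_, sample, TipStatus.EXTANT)
    if not extant.any() or extant.all():
        raise ValueError("centroid distance requires both classes in the sample")
    coords = ord_.coordinates[idx]
    gap = coords[extant].mean(axis=0) - coords[~extant].mean(axis=0)
    return float(np.linalg.norm(gap))


SCALAR_INDEX_FUNCTIONS = {
    "mpd": mean_pairwise_distance,
    "maxpd": max_pairwise_distance,
    "mefd": mean_extant_fossil_distance,
    "sov": sum_of_variances,
    "sor": sum_of_ranges,
    "centroid": centroid_distance,
}


# ----------------------------------------------------------------- batch


def pre_ordination_batch(
    dm: DistanceMatrixResult, draws: np.ndarray, indices: Sequence[str]
) -> dict[str, np.ndarray]:
    """Evaluate pre-ordination indices for each row of ``draws``.

    ``draws`` holds integer positions into ``dm.taxa`` with shape
    ``(n_subsamples, size)``.  Cross-class indices yield NaN for
    subsamples lacking either class.
    """
    out: dict[str, np.ndarray] = {}
    S = dm.D[draws[:, :, None], draws[:, None, :]]
    size = draws.shape[1]
    if "mpd" in indices:
        out["mpd"] = S.sum(axis=(1, 2)) / (size * (size - 1))
    if "maxpd" in indices:
        out["maxpd"] = S.max(axis=(1, 2))
    if "mefd" in indices:
        extant = np.array(
            [dm.status[t] is TipStatus.EXTANT for t in dm.taxa], dtype=float
        )[draws]
        fossil = 1.0 - extant
        pairs = extant.sum(axis=1) * fossil.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["mefd"] = np.where(
                pairs > 0,
                np.einsum("sij,si,sj->s", S, extant, fossil) / np.maximum(pairs, 1),
                np.nan,
            )
    return out


def post_ordination_batch(
    ord_: OrdinationResult, draws: np.ndarray, indices: Sequence[str]
) -> dict[str, np.ndarray]:
    """Evaluate post-ordination indices for each row of ``draws``."""
    out: dict[str, np.ndarray] = {}
    P = ord_.coordinates[draws]  # (n_sub, size, axes)
    if "sov" in indices:
        out["sov"] = P.var(axis=1, ddof=1).sum(axis=1)
    if "sor" in indices:
        out["sor"] = (P.max(axis=1) - P.min(axis=1)).sum(axis=1)
    if "centroid" in indices:
        extant = np.array(
            [ord_.status[t] is TipStatus.EXTANT for t in ord_.taxa], dtype=float
        )[draws]
        fossil = 1.0 - extant
        n_e = extant.sum(axis=1)
        n_f = fossil.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cent_e = np.einsum("sia,si->sa", P, extant) / np.maximum(n_e, 1)[:, None]
            cent_f = np.einsum("sia,si->sa", P, fossil) / np.maximum(n_f, 1)[:, None]
            dist = np.linalg.norm(cent_e - cent_f, axis=1)
        out["centroid"] = np.where((n_e > 0) & (n_f > 0), dist, np.nan)
    return out
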