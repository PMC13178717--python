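"""Representational similarity analysis (RSA).

A response matrix (images x units — model penultimate features, or a
reference pattern set such as voxel responses) is summarized by its
representational dissimilarity matrix (RDM) of pairwise Euclidean distances
between image rows.  Two systems are compared by Spearman rank correlation
between the vectorized strict upper triangles of their RDMs — a
second-order similarity that is invariant to any monotone rescaling of the
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .reliance import CorrelationResult

__all__ = ["ResponseMatrix", "RDM", "compute_rdm", "rsa_similarity", "save_rdm", "load_rdm"]


@dataclass(frozen=True)
class ResponseMatrix:
    """Images x units real responses with ordered image identifiers."""

    values: np.ndarray = field(repr=False)
    image_ids: tuple = ()
    source: str = "model_penultimate"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 images")
        if not np.all(np.isfinite(v)):
            raise ValueError("response matrix contains missing/non-finite values")
        if self.image_ids and len(self.image_ids) != v.shape[0]:
            raise ValueError("need one image id per row")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RDM:
    """Symmetric zero-diagonal matrix of pairwise dissimilarities."""

    dissimilarities: np.ndarray = field(repr=False)
    image_ids: tuple = ()

    def __post_init__(self) -> None:
        d = self.dissimilarities
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or np.any(d < 0):
            raise ValueError("RDM must be symmetric, nonnegative, zero-diagonal")

    @property
    def n_images(self) -> int:
        return self.dissimilarities.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major (diagonal excluded)."""
        n = self.n_images
        iu = np.triu_indices(n, k=1)
        return self.dissimilarities[iu]


def compute_rdm(responses: ResponseMatrix | np.ndarray, image_ids: tuple = ()) -> RDM:
    """Pairwise Euclidean distances between image response rows.

    No row normalization is applied: distances are taken on the raw
    patterns.
    """
    if isinstance(responses, ResponseMatrix):
        values = responses.values
        image_ids = image_ids or responses.image_ids
    else:
        values = np.asarray(responses, dtype=float)
        if values.ndim != 2 or values.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 images")
        if not np.all(np.isfinite(values)):
            raise ValueError("response matrix contains missing/non-finite values")
    d = squareform(pdist(values, metric="euclidean"))
    return RDM(dissimilarities=d, image_ids=tuple(image_ids))


def rsa_similarity(rdm_a: RDM, rdm_b: RDM) -> CorrelationResult:
    """Spearman's rho between the strict upper triangles of two RDMs.

    The two RDMs must describe the same image set in the same order;
    average ranks are used for ties.
    """
    if rdm_a.n_images != rdm_b.n_images:
        raise ValueError("RDMs cover different numbers of images")
    if rdm_a.image_ids and rdm_b.image_ids and rdm_a.image_ids != rdm_b.image_ids:
        raise ValueError("RDM image orderings do not match")
    res = stats.spearmanr(rdm_a.upper_triangle(), rdm_b.upper_triangle())
    n = rdm_a.n_images * (rdm_a.n_images - 1) // 2
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=n)


def save_rdm(rdm: RDM, path) -> None:
    np.savez(
        path,
        dissimilarities=rdm.dissimilarities,
        image_ids=np.asarray(rdm.image_ids),
    )


def load_rdm(path) -> RDM:
    with np.load(path, allow_pickle=False) as npz:
        d = npz["dissimilarities"]
        ids = tuple(npz["image_ids"].tolist()) if npz["image_ids"].size else ()
    return RDM(dissimilarities=d, image_ids=ids)
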