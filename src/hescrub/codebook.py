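"""The noiselet code-book: k-means under city-block (L1) distance.

Patch noiselet features are clustered into K codewords; any patch is then
quantized to its nearest codeword in L1 distance.  The centroid update is
the coordinate-wise median — the minimizer of the summed L1 distance — so
the clustering objective provably never increases across iterations.
Initialization is k-means++-style seeding adapted to L1, driven by a
seeded RNG for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ParameterError

__all__ = ["Codebook", "extract_patches", "build_codebook", "assign_code", "assign_codes"]


@dataclass(frozen=True)
class Codebook:
    """K centroids in patch-feature space under city-block distance."""

    centroids: np.ndarray = field(repr=False)
    patch_size: int
    seed: int
    distance: str = "cityblock"
    n_iter: int = 0
    objective: float = float("nan")
    #: summed L1 distance to assigned centroids after each update step
    objective_trace: tuple = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ParameterError("centroids must be a K x D matrix with K >= 1")
        if not np.all(np.isfinite(c)):
            raise ParameterError("centroids must be finite")
        object.__setattr__(self, "centroids", c)

    @property
    def n_codes(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "centroids": self.centroids.tolist(),
            "patch_size": self.patch_size,
            "seed": self.seed,
            "distance": self.distance,
            "normalization": "unitary",
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["centroids"]), patch_size=d["patch_size"],
                   seed=d["seed"], distance=d["distance"])


def extract_patches(region: np.ndarray, patch_size: int) -> np.ndarray:
    """Split an h x w region into its row-major grid of non-overlapping
    m x m patches, returned as an ((h/m)*(w/m), m, m) stack.

    ``patch_size`` must divide both region dimensions exactly.
    """
    arr = np.asarray(region)
    if arr.ndim != 2:
        raise ParameterError("region must be 2D")
    h, w = arr.shape
    m = int(patch_size)
    if m < 1 or h % m or w % m:
        raise ParameterError(f"patch size {m} must divide region shape {(h, w)}")
    return (arr.reshape(h // m, m, w // m, m)
               .transpose(0, 2, 1, 3)
               .reshape(-1, m, m))


def _l1_pp_init(features: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with L1 distances."""
    n = features.shape[0]
    centers = [features[rng.integers(n)]]
    for _ in range(1, k):
        d = cdist(features, np.asarray(centers), metric="cityblock").min(axis=1)
        total = d.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers.append(features[rng.integers(n)])
            continue
        centers.append(features[rng.choice(n, p=d / total)])
    return np.asarray(centers, dtype=float)


def build_codebook(
    features: np.ndarray,
    n_codes: int,
    seed: int = 0,
    max_iter: int = 100,
    patch_size: int | None = None,
) -> Codebook:
    """Cluster N x D features into ``n_codes`` codewords (L1 k-means).

    Iterates nearest-centroid assignment (city-block) and coordinate-wise
    median update until assignments stop changing or ``max_iter`` is hit.
    An emptied cluster is re-seeded from the point currently farthest (L1)
    from its assigned centroid.  Deterministic for a given seed.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ParameterError("features must be a non-empty N x D matrix")
    n = x.shape[0]
    k = int(n_codes)
    if k < 1 or k > n:
        raise ParameterError(f"need 1 <= n_codes <= n_samples, got K={k}, N={n}")
    rng = np.random.default_rng(seed)
    centers = _l1_pp_init(x, k, rng)
    assign = np.full(n, -1)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        d = cdist(x, centers, metric="cityblock")
        new_assign = d.argmin(axis=1)
        point_d = d[np.arange(n), new_assign]
        for j in range(k):
            mask = new_assign == j
            if mask.any():
                centers[j] = np.median(x[mask], axis=0)
            else:
                far = point_d.argmax()
                centers[j] = x[far]
                new_assign[far] = j
                point_d[far] = 0.0
        trace.append(float(cdist(x, centers, metric="cityblock")
                           .min(axis=1).sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return Codebook(centers, patch_size=patch_size or 0, seed=seed,
                    n_iter=it, objective=trace[-1],
                    objective_trace=tuple(trace))


def assign_codes(features: np.ndarray, book: Codebook) -> np.ndarray:
    """Nearest-codeword index (L1) per row; ties go to the lowest index."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != book.centroids.shape[1]:
        raise ParameterError(
            f"feature dimension {x.shape[1]} does not match codebook "
            f"dimension {book.centroids.shape[1]}"
        )
    return cdist(x, book.centroids, metric="cityblock").argmin(axis=1)


def assign_code(feature: np.ndarray, book: Codebook) -> int:
    """Quantize a single feature vector to its codeword index in [0, K)."""
    f = np.asarray(feature, dtype=float)
    if f.ndim != 1:
        raise ParameterError("feature must be a 1D vector")
    return int(assign_codes(f[None, :], book)[0])
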