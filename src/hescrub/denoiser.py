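"""Tile-level nuclei / non-nuclei discrimination and background removal.

An image is divided into non-overlapping tiles (e.g. 12x12 px).  Each
tile is split into patches, every patch is projected to the noiselet
space and quantized against the code-book, and the tile is summarized by
its histogram of codeword occurrences — a bag-of-words texture
descriptor.  A discrete AdaBoost ensemble of depth-1 decision stumps on
the histogram bins separates nuclei from non-nuclei tiles; tiles voted
non-nuclei are blanked out of the image before segmentation.

Histograms are kept as raw counts: for a fixed patch/tile configuration
every histogram sums to the same (t/m)^2, so normalization would only
rescale the stump thresholds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codebook import Codebook, assign_codes, extract_patches
from .exceptions import ParameterError
from .noiselet import NoiseletBasis, noiselet_basis, patch_features_batch

__all__ = [
    "NUCLEI", "NON_NUCLEI",
    "TileGrid", "DenoiserModel",
    "tile_image", "encode_tile", "encode_tiles", "label_tiles",
    "train_denoiser", "classify_tiles", "remove_background",
]

NUCLEI = 1
NON_NUCLEI = 0


@dataclass(frozen=True)
class TileGrid:
    """Row-major grid of non-overlapping t x t tiles anchored at (0, 0).

    Remainder pixels (image dimension mod t) are excluded from the grid
    and recorded in ``remainder``.
    """

    tile_size: int
    image_shape: tuple
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def remainder(self) -> tuple:
        return (self.image_shape[0] % self.tile_size,
                self.image_shape[1] % self.tile_size)

    def tile_slices(self, index: int) -> tuple:
        r, c = divmod(index, self.n_cols)
        t = self.tile_size
        return (slice(r * t, (r + 1) * t), slice(c * t, (c + 1) * t))

    def positions(self) -> np.ndarray:
        """(n_tiles, 2) array of (row, col) tile indices, row-major."""
        r, c = np.divmod(np.arange(self.n_tiles), self.n_cols)
        return np.column_stack([r, c])


def tile_image(image: np.ndarray, tile_size: int) -> TileGrid:
    """Build the tile grid of an h x w image; remainder pixels are cropped."""
    arr = np.asarray(image)
    if arr.ndim < 2:
        raise ParameterError("image must be at least 2D")
    h, w = arr.shape[:2]
    t = int(tile_size)
    if t < 1 or t > min(h, w):
        raise ParameterError(f"tile size {t} must be in [1, min(h, w)={min(h, w)}]")
    return TileGrid(tile_size=t, image_shape=(h, w), n_rows=h // t, n_cols=w // t)


def _tile_patch_count(tile_size: int, patch_size: int) -> int:
    if patch_size < 1 or tile_size % patch_size:
        raise ParameterError(
            f"patch size {patch_size} must divide tile size {tile_size}"
        )
    return (tile_size // patch_size) ** 2


def encode_tile(tile: np.ndarray, book: Codebook,
                basis: NoiseletBasis | None = None) -> np.ndarray:
    """Codeword-occurrence histogram of one t x t tile (counts sum to (t/m)^2)."""
    arr = np.asarray(tile, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ParameterError("tile must be square")
    m = book.patch_size
    n_patches = _tile_patch_count(arr.shape[0], m)
    basis = basis or noiselet_basis(m)
    feats = patch_features_batch(extract_patches(arr, m), basis)
    codes = assign_codes(feats, book)
    hist = np.bincount(codes, minlength=book.n_codes)
    assert hist.sum() == n_patches
    return hist


def encode_tiles(image: np.ndarray, grid: TileGrid, book: Codebook) -> np.ndarray:
    """Histogram matrix (n_tiles, K) for a whole image, vectorized.

    Equivalent to :func:`encode_tile` on every grid tile in row-major
    order, but quantizes all patches of the image in one pass.
    """
    arr = np.asarray(image, dtype=float)
    t, m = grid.tile_size, book.patch_size
    per_tile = _tile_patch_count(t, m)
    h = grid.n_rows * t
    w = grid.n_cols * t
    cropped = arr[:h, :w]
    basis = noiselet_basis(m)
    feats = patch_features_batch(extract_patches(cropped, m), basis)
    codes = assign_codes(feats, book)
    # patch grid -> tile-of-patch blocks, row-major per tile
    pr, pc = h // m, w // m
    tpr = t // m  # patches per tile edge
    codes2d = codes.reshape(pr, pc)
    blocks = (codes2d.reshape(grid.n_rows, tpr, grid.n_cols, tpr)
                    .transpose(0, 2, 1, 3)
                    .reshape(grid.n_tiles, per_tile))
    hists = np.stack([np.bincount(b, minlength=book.n_codes) for b in blocks])
    return hists


def label_tiles(grid: TileGrid, gt_mask: np.ndarray,
                overlap_threshold: float = 0.5) -> np.ndarray:
    """Per-tile binary labels from a ground-truth nuclei mask.

    A tile is ``NUCLEI`` iff the fraction of nucleus pixels inside it is
    at least ``overlap_threshold``.
    """
    mask = np.asarray(gt_mask) > 0
    if mask.shape != tuple(grid.image_shape):
        raise ParameterError("mask shape does not match the tiled image")
    t = grid.tile_size
    h, w = grid.n_rows * t, grid.n_cols * t
    frac = (mask[:h, :w]
            .reshape(grid.n_rows, t, grid.n_cols, t)
            .mean(axis=(1, 3))
            .reshape(-1))
    return np.where(frac >= overlap_threshold, NUCLEI, NON_NUCLEI)


@dataclass(frozen=True)
class DenoiserModel:
    """Weighted ensemble of decision stumps over histogram bins.

    Each stump is (feature index, threshold, polarity): it votes NUCLEI
    when ``polarity * (x[feature] - threshold) > 0``.  ``metadata``
    records the training configuration (patch size, tile size, K, seed)
    and a hash of the codebook so mismatched books are refused.
    """

    stumps: tuple            # ((feature, threshold, polarity), ...)
    stump_weights: tuple
    n_rounds: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.stumps) == len(self.stump_weights) == self.n_rounds):
            raise ParameterError("stumps, weights, and n_rounds must agree")
        if not all(np.isfinite(w) and w > 0 for w in self.stump_weights):
            raise ParameterError("stump weights must be positive and finite")

    def decision_function(self, histograms: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(histograms, dtype=float))
        k = self.metadata.get("n_codes")
        if k is not None and x.shape[1] != k:
            raise ParameterError(
                f"histogram dimension {x.shape[1]} does not match model K={k}"
            )
        score = np.zeros(x.shape[0])
        for (feat, thr, pol), w in zip(self.stumps, self.stump_weights):
            score += w * np.where(pol * (x[:, feat] - thr) > 0, 1.0, -1.0)
        return score

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "stumps": [list(s) for s in self.stumps],
            "stump_weights": list(self.stump_weights),
            "n_rounds": self.n_rounds,
            "metadata": self.metadata,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "DenoiserModel":
        d = json.loads(Path(path).read_text())
        return cls(tuple(tuple(s) for s in d["stumps"]),
                   tuple(d["stump_weights"]), d["n_rounds"], d["metadata"])


def codebook_hash(book: Codebook) -> str:
    payload = book.centroids.tobytes() + bytes([book.patch_size % 256])
    return hashlib.sha256(payload).hexdigest()[:16]


def _best_stump(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Minimal weighted-error stump over all features, thresholds, polarities.

    ``y`` in {-1, +1}.  Candidate thresholds are midpoints between
    consecutive distinct sorted feature values, plus sentinels outside
    the value range.  Ties resolve to the lowest feature index, then the
    lowest threshold, then polarity +1 — deterministic by construction.

    Returns ((feature, threshold, polarity), weighted_error).
    """
    n, d = x.shape
    best = (0, float(x[:, 0].min()) - 1.0, 1.0)
    best_err = np.inf
    for feat in range(d):
        col = x[:, feat]
        order = np.argsort(col, kind="stable")
        cs, ys, ws = col[order], y[order], w[order]
        cum_pos = np.concatenate([[0.0], np.cumsum(ws * (ys > 0))])
        cum_neg = np.concatenate([[0.0], np.cumsum(ws * (ys < 0))])
        w_pos, w_neg = cum_pos[-1], cum_neg[-1]
        splits = np.concatenate([[0], np.nonzero(np.diff(cs))[0] + 1, [n]])
        thr = np.empty(splits.shape[0])
        thr[0] = cs[0] - 1.0
        thr[-1] = cs[-1] + 1.0
        inner = splits[1:-1]
        thr[1:-1] = 0.5 * (cs[inner - 1] + cs[inner])
        # polarity +1 predicts NUCLEI for col > thr:
        #   errors = positives on the left + negatives on the right
        err_pos = cum_pos[splits] + (w_neg - cum_neg[splits])
        err_neg = cum_neg[splits] + (w_pos - cum_pos[splits])
        for errs, pol in ((err_pos, 1.0), (err_neg, -1.0)):
            j = int(errs.argmin())
            if errs[j] < best_err - 1e-12:
                best_err = float(errs[j])
                best = (feat, float(thr[j]), pol)
    return best, best_err


def train_denoiser(
    histograms: np.ndarray,
    labels: np.ndarray,
    n_rounds: int = 50,
    seed: int = 0,
    metadata: dict | None = None,
) -> DenoiserModel:
    """Discrete AdaBoost of decision stumps on tile histograms.

    Runs up to ``n_rounds`` boosting rounds; a round whose best stump has
    weighted error >= 0.5 cannot help and halts training, as does a
    perfect (zero-error) stump after it is added.  The procedure is
    deterministic; ``seed`` is recorded in the model metadata only.

    Raises
    ------
    ParameterError
        If only one class is present, fewer than 2 samples, or
        ``n_rounds < 1``.
    """
    x = np.atleast_2d(np.asarray(histograms, dtype=float))
    lab = np.asarray(labels)
    if n_rounds < 1:
        raise ParameterError("n_rounds must be >= 1")
    if x.shape[0] != lab.shape[0] or x.shape[0] < 2:
        raise ParameterError("need >= 2 labeled histograms")
    y = np.where(lab == NUCLEI, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise ParameterError("training requires both nuclei and non-nuclei tiles")
    n = x.shape[0]
    w = np.full(n, 1.0 / n)
    stumps, alphas = [], []
    for _ in range(n_rounds):
        (feat, thr, pol), err = _best_stump(x, y, w)
        err = err / w.sum()
        if err >= 0.5:
            break
        err = max(err, 1e-10)
        alpha = 0.5 * np.log((1.0 - err) / err)
        stumps.append((feat, thr, pol))
        alphas.append(float(alpha))
        h = np.where(pol * (x[:, feat] - thr) > 0, 1.0, -1.0)
        w = w * np.exp(-alpha * y * h)
        w = w / w.sum()
        if err <= 1e-10:
            break
    if not stumps:  # data irreducible from round one: fall back to majority vote
        maj = 1.0 if (y > 0).mean() >= 0.5 else -1.0
        stumps = [(0, float(x[:, 0].min()) - 1.0, maj)]
        alphas = [1e-8]
    return DenoiserModel(
        stumps=tuple(stumps),
        stump_weights=tuple(alphas),
        n_rounds=len(stumps),
        metadata={"seed": int(seed), "n_codes": int(x.shape[1]),
                  **(metadata or {})},
    )


def classify_tiles(model: DenoiserModel, histograms: np.ndarray):
    """Predicted tile labels and real-valued margins for N histograms."""
    x = np.asarray(histograms, dtype=float)
    if x.size == 0:
        return np.array([], dtype=int), np.array([])
    score = model.decision_function(x)
    return np.where(score > 0, NUCLEI, NON_NUCLEI), score


def remove_background(
    image: np.ndarray,
    grid: TileGrid,
    labels: np.ndarray,
    fill_value: float | None = None,
) -> np.ndarray:
    """Blank out tiles labeled non-nuclei; nuclei tiles stay bit-identical.

    ``fill_value`` defaults to background white (255) for RGB input and 0
    for single-channel (hematoxylin) input.  Remainder pixels outside the
    tile grid pass through unchanged.
    """
    arr = np.asarray(image)
    lab = np.asarray(labels)
    if arr.shape[:2] != tuple(grid.image_shape):
        raise ParameterError("image shape does not match the tile grid")
    if lab.shape[0] != grid.n_tiles:
        raise ParameterError(
            f"got {lab.shape[0]} labels for a grid of {grid.n_tiles} tiles"
        )
    if fill_value is None:
        fill_value = 255 if (arr.ndim == 3 and arr.shape[2] == 3) else 0
    out = arr.copy()
    for idx in np.nonzero(lab == NON_NUCLEI)[0]:
        out[grid.tile_slices(int(idx))] = fill_value
    return out
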