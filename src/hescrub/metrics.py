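"""Detection and segmentation evaluation.

Three measures are provided:

* Dice on the pooled nucleus foreground, DSC = 2|A∩B| / (|A|+|B|).
* Detection F-score with centroid matching: a detection counts as a true
  positive iff its mask intersects a ground-truth nucleus (>= 1 px) and
  the centroid distance is below 12 px; matching is greedy one-to-one in
  ascending distance.  F1 = TP / (TP + (FP + FN)/2).
* Pearson correlation between annotated and detected nucleus counts
  across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .exceptions import DegenerateInputError, ParameterError
from .segmenter import SegmentationResult

__all__ = ["DEFAULT_MATCH_DIST", "MatchReport", "dice", "match_nuclei",
           "count_correlation", "f1_from_counts"]

#: centroid distance (pixels) below which a detection can match a nucleus
DEFAULT_MATCH_DIST = 12.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks: 2|A∩B| / (|A|+|B|)."""
    ma = np.asarray(a).astype(bool)
    mb = np.asarray(b).astype(bool)
    if ma.shape != mb.shape:
        raise ParameterError("masks must share a shape")
    denom = ma.sum() + mb.sum()
    if denom == 0:
        raise DegenerateInputError("Dice is undefined for two empty masks")
    return 2.0 * np.logical_and(ma, mb).sum() / denom


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """Detection F-score: TP / (TP + (FP + FN)/2); 0 when no TP."""
    denom = tp + 0.5 * (fp + fn)
    return tp / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class MatchReport:
    """Outcome of one-to-one detection/ground-truth matching."""

    tp: int
    fp: int
    fn: int
    f1: float
    pairs: tuple  # ((detected label, gt label, centroid distance), ...)


def match_nuclei(
    detected: SegmentationResult,
    gt: SegmentationResult,
    max_dist: float = DEFAULT_MATCH_DIST,
) -> MatchReport:
    """Greedy one-to-one matching of detections to ground-truth nuclei.

    Candidate pairs require mask intersection (>= 1 shared pixel) and
    centroid distance strictly below ``max_dist``; pairs are accepted in
    ascending distance, each id used at most once.  Unmatched detections
    are false positives, unmatched ground-truth nuclei false negatives.
    """
    if detected.labels.shape != gt.labels.shape:
        raise ParameterError("detected and ground-truth frames differ in shape")
    n_det = detected.n_regions
    n_gt = gt.n_regions
    pairs = []
    if n_det and n_gt:
        d = cdist(detected.centroids, gt.centroids)
        # intersection test: which (det, gt) label pairs share pixels
        both = (detected.labels > 0) & (gt.labels > 0)
        inter = set(zip(detected.labels[both].ravel(), gt.labels[both].ravel()))
        cand = [(d[i, j], i + 1, j + 1)
                for i in range(n_det) for j in range(n_gt)
                if d[i, j] < max_dist and (i + 1, j + 1) in inter]
        cand.sort()
        used_det: set[int] = set()
        used_gt: set[int] = set()
        for dist, di, gi in cand:
            if di in used_det or gi in used_gt:
                continue
            used_det.add(di)
            used_gt.add(gi)
            pairs.append((di, gi, float(dist)))
    tp = len(pairs)
    fp = n_det - tp
    fn = n_gt - tp
    return MatchReport(tp=tp, fp=fp, fn=fn, f1=f1_from_counts(tp, fp, fn),
                       pairs=tuple(pairs))


def count_correlation(pairs) -> float:
    """Pearson correlation between annotated and detected nucleus counts.

    ``pairs`` is a sequence of (annotated count, detected count); at
    least 3 pairs and non-constant columns are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ParameterError("need >= 3 (annotated, detected) count pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError(
            "Pearson correlation is undefined for constant count vectors"
        )
    return float(pearsonr(a, b).statistic)
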