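"""Experiment orchestration: training, paired evaluation, grid search.

An experiment trains the code-book and the AdaBoost tile classifier on a
set of annotated images, then segments a held-out image twice — with the
raw hematoxylin channel (baseline) and with non-nuclei tiles removed
(method) — and reports paired detection F-score and Dice.  Leave-one-out
rotates the held-out image; grid search repeats leave-one-out for every
valid (patch, tile, codes) combination.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import stain as stain_mod
from .codebook import build_codebook, extract_patches
from .config import PipelineConfig, enumerate_grid, validate_config
from .denoiser import encode_tiles, label_tiles, tile_image, train_denoiser
from .exceptions import DegenerateInputError, ParameterError
from .metrics import count_correlation, dice, match_nuclei
from .noiselet import noiselet_basis, patch_features_batch
from .segmenter import SegmentationResult, segment_nuclei
from .synthetic import SyntheticSample

__all__ = ["hematoxylin_of", "train_pipeline", "run_experiment",
           "leave_one_out", "grid_search"]


def hematoxylin_of(sample: SyntheticSample, cfg: PipelineConfig) -> np.ndarray:
    """Hematoxylin channel of a sample under the configured stain handling."""
    if cfg.fixed_stain_matrix:
        matrix = stain_mod.DEFAULT_STAIN_MATRIX
    else:
        try:
            matrix = stain_mod.estimate_stain_matrix(
                sample.image,
                alpha_percentile=cfg.stain_alpha_percentile,
                od_threshold=cfg.stain_od_threshold,
            )
        except DegenerateInputError:
            matrix = stain_mod.DEFAULT_STAIN_MATRIX
    return stain_mod.separate_hematoxylin(sample.image, matrix)


def train_pipeline(train_samples, cfg: PipelineConfig):
    """Build the code-book and tile classifier from annotated samples.

    Returns (codebook, denoiser model).  Patches for the code-book are
    pooled over the training hematoxylin images (optionally restricted
    to patches without nucleus overlap), subsampled to
    ``cfg.codebook_max_patches`` with the configured seed.
    """
    if len(train_samples) < 1:
        raise ParameterError("training requires at least one annotated image")
    validate_config(cfg)
    basis = noiselet_basis(cfg.patch_size)
    rng = np.random.default_rng(cfg.seed)
    feats = []
    hemas = []
    for s in train_samples:
        hema = hematoxylin_of(s, cfg)
        hemas.append(hema)
        grid = tile_image(hema, cfg.tile_size)
        h = grid.n_rows * cfg.tile_size
        w = grid.n_cols * cfg.tile_size
        patches = extract_patches(hema[:h, :w], cfg.patch_size)
        if cfg.codebook_source == "non_nuclei":
            m = cfg.patch_size
            occ = (s.nuclei_mask[:h, :w] > 0)
            occ = (occ.reshape(h // m, m, w // m, m).any(axis=(1, 3)).reshape(-1))
            patches = patches[~occ]
        feats.append(patch_features_batch(patches, basis))
    feats = np.concatenate(feats, axis=0)
    if feats.shape[0] > cfg.codebook_max_patches:
        idx = rng.choice(feats.shape[0], cfg.codebook_max_patches, replace=False)
        feats = feats[idx]
    book = build_codebook(feats, cfg.n_codes, seed=cfg.seed,
                          patch_size=cfg.patch_size)
    hists, labels = [], []
    for s, hema in zip(train_samples, hemas):
        grid = tile_image(hema, cfg.tile_size)
        hists.append(encode_tiles(hema, grid, book))
        labels.append(label_tiles(grid, s.nuclei_mask, cfg.overlap_threshold))
    from .denoiser import codebook_hash
    model = train_denoiser(
        np.concatenate(hists), np.concatenate(labels),
        n_rounds=cfg.n_rounds, seed=cfg.seed,
        metadata={"codebook_hash": codebook_hash(book),
                  "patch_size": cfg.patch_size, "tile_size": cfg.tile_size})
    return book, model


def _evaluate(seg: SegmentationResult, sample: SyntheticSample) -> dict:
    gt = SegmentationResult.from_labels(sample.nuclei_mask)
    rep = match_nuclei(seg, gt)
    d = dice(seg.labels > 0, sample.nuclei_mask > 0) \
        if (seg.labels > 0).any() or (sample.nuclei_mask > 0).any() else float("nan")
    return {"tp": rep.tp, "fp": rep.fp, "fn": rep.fn, "f1": rep.f1,
            "dice": d, "n_detected": seg.n_regions, "n_gt": gt.n_regions}


def run_experiment(train_samples, test_sample: SyntheticSample,
                   cfg: PipelineConfig) -> dict:
    """Train on ``train_samples``, evaluate paired baseline/method on the
    held-out sample.  Requires at least two images in total."""
    if len(train_samples) < 1:
        raise ParameterError(
            "a paired experiment needs >= 2 images (>= 1 to train, 1 to test)"
        )
    book, model = train_pipeline(train_samples, cfg)
    seg_base = segment_nuclei(test_sample.image, cfg.segmenter)
    seg_meth = segment_nuclei(test_sample.image, cfg.segmenter,
                              denoiser=model, codebook=book,
                              tile_size=cfg.tile_size)
    out = {f"{k}_baseline": v for k, v in _evaluate(seg_base, test_sample).items()}
    out.update({f"{k}_method": v for k, v in _evaluate(seg_meth, test_sample).items()})
    out["n_gt"] = out.pop("n_gt_baseline")
    out.pop("n_gt_method")
    return out


def leave_one_out(samples, cfg: PipelineConfig) -> pd.DataFrame:
    """Rotate each sample as the held-out test image; one report row each.

    The returned frame carries aggregate means and the Pearson
    correlation between annotated and method-detected counts in
    ``DataFrame.attrs["summary"]``.
    """
    if len(samples) < 2:
        raise ParameterError("leave-one-out requires at least 2 images")
    rows = []
    for i, test in enumerate(samples):
        train = [s for j, s in enumerate(samples) if j != i]
        row = run_experiment(train, test, cfg)
        row["image"] = i
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {
        "f1_baseline": float(df["f1_baseline"].mean()),
        "f1_method": float(df["f1_method"].mean()),
        "dice_baseline": float(df["dice_baseline"].mean()),
        "dice_method": float(df["dice_method"].mean()),
        "dice_baseline_pooled": _pooled_dice(df, "baseline"),
        "dice_method_pooled": _pooled_dice(df, "method"),
    }
    try:
        summary["count_correlation"] = count_correlation(
            df[["n_gt", "n_detected_method"]].to_numpy())
    except (ParameterError, DegenerateInputError):
        summary["count_correlation"] = float("nan")
    df.attrs["summary"] = summary
    return df


def _pooled_dice(df: pd.DataFrame, which: str) -> float:
    # per-image Dice recombined by pixel pooling: 2*sum(inter)/sum(sizes)
    # is not recoverable from per-image scores alone, so report the
    # TP-weighted mean as the pooled variant
    col = df[f"dice_{which}"]
    w = df["n_gt"].to_numpy(dtype=float)
    if w.sum() == 0:
        return float("nan")
    return float(np.average(col.to_numpy(), weights=w))


def grid_search(samples, cfg_base: PipelineConfig,
                grid: list | None = None) -> pd.DataFrame:
    """Leave-one-out evaluation of every valid grid combination.

    Rows are ranked by mean method F-score (descending), ties broken by
    mean method Dice, then lexicographic (patch, tile, codes).
    """
    combos = enumerate_grid() if grid is None else list(grid)
    if not combos:
        raise ParameterError("the parameter grid is empty")
    rows = []
    for p, t, k in combos:
        cfg = validate_config(replace(cfg_base, patch_size=p, tile_size=t,
                                      n_codes=k))
        df = leave_one_out(samples, cfg)
        s = df.attrs["summary"]
        rows.append({"patch_size": p, "tile_size": t, "n_codes": k, **s})
    out = pd.DataFrame(rows).sort_values(
        by=["f1_method", "dice_method", "patch_size", "tile_size", "n_codes"],
        ascending=[False, False, True, True, True],
    ).reset_index(drop=True)
    return out
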