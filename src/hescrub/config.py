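"""Pipeline configuration and the experimental parameter grid.

The three parameters that define a preprocessing configuration are the
patch size (noiselet unit: 2, 4, or 8 px), the tile size (removal unit:
8, 12, 16, 20, or 24 px), and the number of codewords (2, 4, 8, or 16).
A configuration is valid only when the patch size divides the tile size;
of the 60 grid cells this admits exactly 52 combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .exceptions import ParameterError
from .segmenter import SegmenterParams

__all__ = ["GRID_PATCH_SIZES", "GRID_TILE_SIZES", "GRID_CODE_COUNTS",
           "PipelineConfig", "validate_config", "enumerate_grid"]

GRID_PATCH_SIZES = (2, 4, 8)
GRID_TILE_SIZES = (8, 12, 16, 20, 24)
GRID_CODE_COUNTS = (2, 4, 8, 16)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to train and apply the denoising pipeline."""

    patch_size: int = 2
    tile_size: int = 12
    n_codes: int = 8
    seed: int = 0
    n_rounds: int = 50                  # AdaBoost stumps
    overlap_threshold: float = 0.5      # tile-labeling nucleus-pixel fraction
    codebook_source: str = "all"        # 'all' or 'non_nuclei' training patches
    codebook_max_patches: int = 20000   # subsample cap for k-means
    stain_alpha_percentile: float = 0.01
    stain_od_threshold: float = 0.15
    fixed_stain_matrix: bool = False    # use the conventional matrix instead
                                        # of per-image estimation
    segmenter: SegmenterParams = field(default_factory=SegmenterParams)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        seg = d.pop("segmenter", None)
        cfg = cls(**d)
        if seg:
            seg = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in seg.items()}
            cfg = replace(cfg, segmenter=SegmenterParams(**seg))
        return cfg


def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    """Check enum membership and the patch-divides-tile constraint."""
    if cfg.patch_size not in GRID_PATCH_SIZES:
        raise ParameterError(f"patch size must be one of {GRID_PATCH_SIZES}")
    if cfg.tile_size not in GRID_TILE_SIZES:
        raise ParameterError(f"tile size must be one of {GRID_TILE_SIZES}")
    if cfg.n_codes not in GRID_CODE_COUNTS:
        raise ParameterError(f"code count must be one of {GRID_CODE_COUNTS}")
    if cfg.tile_size % cfg.patch_size:
        raise ParameterError(
            f"patch size {cfg.patch_size} does not divide tile size "
            f"{cfg.tile_size}; the configuration is invalid"
        )
    if cfg.codebook_source not in ("all", "non_nuclei"):
        raise ParameterError("codebook_source must be 'all' or 'non_nuclei'")
    if not 0 <= cfg.overlap_threshold <= 1:
        raise ParameterError("overlap_threshold must be in [0, 1]")
    return cfg


def enumerate_grid(
    patch_sizes=GRID_PATCH_SIZES,
    tile_sizes=GRID_TILE_SIZES,
    code_counts=GRID_CODE_COUNTS,
) -> list:
    """All valid (patch, tile, codes) combinations, lexicographic order.

    With the full default grid this yields 52 configurations (the 60
    cells minus the eight where an 8-px patch does not divide a 12- or
    20-px tile).
    """
    return [
        (p, t, k)
        for p, t, k in itertools.product(patch_sizes, tile_sizes, code_counts)
        if t % p == 0
    ]
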