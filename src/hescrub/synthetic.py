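"""Seeded generator of H&E-like fields of view with known ground truth.

Samples emulate the signal/noise structure the preprocessing exploits:
blob-like hematoxylin-dominant nuclei — smooth, near-normal intensity,
with optional chromatin speckle giving a bimodal histogram — over an
eosin-dominant background whose texture presets carry residual
hematoxylin with a much flatter intensity spectrum:

* ``flat``: clean background, nearly stain-free.
* ``fibrous_stroma``: oriented sinusoidal fiber bands (wavelength a few
  px), the high-frequency texture of collagen-rich stroma.
* ``fold_artifact``: a large dense smudge where folded tissue piles both
  stains, the classic whole-slide artifact.
* ``mixed``: fibers plus a fold.

Rendering is physical: per-pixel stain concentrations are converted to
RGB through Beer–Lambert with a conventional H&E optical-density matrix,
so the images round-trip through the stain-deconvolution module.  All
randomness flows from the seed; repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .exceptions import ParameterError
from .stain import DEFAULT_STAIN_MATRIX, StainMatrix

__all__ = ["SyntheticParams", "SyntheticSample", "generate_sample",
           "generate_dataset", "acceptance_preset"]

PRESETS = ("flat", "fibrous_stroma", "fold_artifact", "mixed")


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration.  Lengths in pixels, concentrations in OD units."""

    image_size: tuple = (512, 512)
    n_nuclei: int = 30
    radius_range: tuple = (10.0, 35.0)     # semi-major axis
    axis_ratio_range: tuple = (0.75, 1.0)  # minor/major
    hema_nucleus: tuple = (0.85, 0.08)     # per-nucleus mean, sd
    chromatin_fraction: float = 0.5        # nuclei given a second intensity mode
    chromatin_boost: float = 0.35
    eosin_nucleus: float = 0.08
    eosin_background: float = 0.30
    background_preset: str = "flat"
    noise_amplitude: float = 0.02          # iid Gaussian on concentration maps
    background_intensity: float = 255.0
    stain_matrix: StainMatrix = DEFAULT_STAIN_MATRIX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_preset not in PRESETS:
            raise ParameterError(f"unknown background preset {self.background_preset!r}")
        if self.n_nuclei < 0 or self.radius_range[0] <= 0:
            raise ParameterError("n_nuclei must be >= 0 and radii positive")


@dataclass(frozen=True)
class SyntheticSample:
    """One rendered field of view with its ground truth."""

    image: np.ndarray = field(repr=False)          # (H, W, 3) uint8
    nuclei_mask: np.ndarray = field(repr=False)    # (H, W) instance labels
    centroids: np.ndarray = field(repr=False)      # (n, 2) float (row, col)
    params: SyntheticParams = field(repr=False, default=None)

    @property
    def n_nuclei(self) -> int:
        return int(self.nuclei_mask.max())


def _fibrous_texture(shape, rng, n_bands: int = 6) -> np.ndarray:
    """Sum of oriented sinusoidal stripe fields under smooth band masks."""
    yy, xx = np.indices(shape, dtype=float)
    tex = np.zeros(shape)
    for _ in range(n_bands):
        theta = rng.uniform(0, np.pi)
        lam = rng.uniform(4.0, 9.0)
        phase = rng.uniform(0, 2 * np.pi)
        stripe = 0.5 * (1 + np.sin(
            2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / lam + phase))
        band = ndi.gaussian_filter(rng.standard_normal(shape), 24.0)
        band = (band > np.quantile(band, 0.5)).astype(float)
        tex += stripe * ndi.gaussian_filter(band, 3.0)
    peak = tex.max()
    return tex / peak if peak > 0 else tex


def _fold_texture(shape, rng) -> np.ndarray:
    """Blobby high-density smudge region with internal speckle, in [0, 1]."""
    blob = ndi.gaussian_filter(rng.standard_normal(shape), 40.0)
    region = ndi.gaussian_filter((blob > np.quantile(blob, 0.85)).astype(float), 5.0)
    speck = 0.5 + 0.5 * np.clip(
        2.0 * ndi.gaussian_filter(rng.standard_normal(shape), 2.0), -1, 1)
    return region * (0.55 + 0.45 * speck)


def _place_nuclei(params: SyntheticParams, rng):
    """Rejection-sample non-overlapping soft-edged ellipses.

    Returns (instance mask, hematoxylin contribution, interior mask).
    Raises ParameterError if the requested count cannot be packed within
    a bounded number of attempts.
    """
    h, w = params.image_size
    mask = np.zeros((h, w), dtype=np.int32)
    hema = np.zeros((h, w))
    placed = 0
    attempts = 0
    max_attempts = 300 * max(params.n_nuclei, 1)
    mean_h, sd_h = params.hema_nucleus
    while placed < params.n_nuclei:
        if attempts >= max_attempts:
            raise ParameterError(
                f"could not pack {params.n_nuclei} nuclei of radius "
                f"{params.radius_range} into {params.image_size} "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        a = rng.uniform(*params.radius_range)
        b = a * rng.uniform(*params.axis_ratio_range)
        phi = rng.uniform(0, np.pi)
        margin = a + 3
        if 2 * margin >= min(h, w):
            continue
        r0 = rng.uniform(margin, h - margin)
        c0 = rng.uniform(margin, w - margin)
        half = int(np.ceil(a)) + 3
        rs = slice(max(int(r0) - half, 0), min(int(r0) + half + 1, h))
        cs = slice(max(int(c0) - half, 0), min(int(c0) + half + 1, w))
        yy, xx = np.indices((rs.stop - rs.start, cs.stop - cs.start), dtype=float)
        dy = yy + rs.start - r0
        dx = xx + cs.start - c0
        u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
        v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
        rho = np.sqrt(u * u + v * v)
        core = rho <= 1.0
        buffer = rho <= 1.15  # 2-3 px separation between instances
        if mask[rs, cs][buffer].any():
            continue
        placed += 1
        base = max(rng.normal(mean_h, sd_h), 0.2)
        profile = np.clip((1.05 - rho) / 0.15, 0.0, 1.0)  # soft edge
        contrib = base * profile
        if rng.uniform() < params.chromatin_fraction:
            speck = ndi.gaussian_filter(rng.standard_normal(core.shape), 1.5)
            contrib = contrib + params.chromatin_boost * (
                (speck > 0.5 * speck.std()) & core)
        region_h = hema[rs, cs]
        region_m = mask[rs, cs]
        region_h[core] = contrib[core]
        region_m[core] = placed
    return mask, hema


def generate_sample(params: SyntheticParams) -> SyntheticSample:
    """Render one field of view; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    shape = (h, w)

    # background compartment
    c_e = params.eosin_background * (
        0.85 + 0.3 * ndi.gaussian_filter(rng.standard_normal(shape), 30.0))
    c_h = np.full(shape, 0.02)
    preset = params.background_preset
    if preset in ("fibrous_stroma", "mixed"):
        tex = _fibrous_texture(shape, rng)
        c_h = c_h + 0.40 * tex
        c_e = c_e + 0.25 * tex
    if preset in ("fold_artifact", "mixed"):
        fold = _fold_texture(shape, rng)
        c_h = c_h + 0.55 * fold
        c_e = c_e + 0.35 * fold

    # nuclei occlude whatever lies beneath them
    mask, nuc_h = _place_nuclei(params, rng)
    inside = mask > 0
    c_h = np.where(inside, nuc_h, c_h)
    c_e = np.where(inside, params.eosin_nucleus, c_e)

    if params.noise_amplitude > 0:
        c_h = c_h + rng.normal(0, params.noise_amplitude, shape)
        c_e = c_e + rng.normal(0, params.noise_amplitude, shape)
    c_h = np.clip(c_h, 0, None)
    c_e = np.clip(c_e, 0, None)

    od = (c_h[..., None] * params.stain_matrix.hematoxylin
          + c_e[..., None] * params.stain_matrix.eosin)
    img = params.background_intensity * np.exp(-od)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    cents = np.array(ndi.center_of_mass(inside, mask, range(1, mask.max() + 1))
                     ) if mask.max() else np.empty((0, 2))
    return SyntheticSample(image=img, nuclei_mask=mask, centroids=cents,
                           params=params)


def generate_dataset(n_images: int, params: SyntheticParams,
                     seed: int | None = None,
                     n_nuclei_range: tuple | None = None) -> list:
    """Independent samples from per-image seeds derived from a master seed.

    ``n_nuclei_range = (lo, hi)`` draws each image's nucleus count
    uniformly from [lo, hi]; count variation across fields is what makes
    an annotated-vs-detected count correlation well defined.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    master = params.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    child_seeds = ss.generate_state(n_images)
    counts = [params.n_nuclei] * n_images
    if n_nuclei_range is not None:
        lo, hi = n_nuclei_range
        counts = np.random.default_rng(ss.spawn(1)[0]).integers(
            lo, hi + 1, size=n_images).tolist()
    return [generate_sample(replace(params, seed=int(s), n_nuclei=int(n)))
            for s, n in zip(child_seeds, counts)]


def acceptance_preset(seed: int = 0) -> SyntheticParams:
    """Scaled-down noisy study conditions: 512x512 fields, 30 nuclei of
    24-40 px diameter, mixed fibrous-stroma and fold artifacts."""
    return SyntheticParams(
        image_size=(512, 512),
        n_nuclei=30,
        radius_range=(12.0, 20.0),
        background_preset="mixed",
        seed=seed,
    )
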