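"""Dataset directory I/O.

Layout convention consumed by the CLI::

    dataset/
      params.yaml            generator / pipeline parameters
      images/img_000.png     8-bit RGB fields of view
      masks/img_000.tif      16-bit instance label masks
      centroids/img_000.csv  label,row,col per nucleus
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .synthetic import SyntheticSample

__all__ = ["write_image", "read_image", "write_mask", "read_mask",
           "write_dataset", "read_dataset"]


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path))


def write_mask(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_dataset(samples, directory: str | Path) -> None:
    root = Path(directory)
    for sub in ("images", "masks", "centroids"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"img_{i:03d}"
        write_image(root / "images" / f"{stem}.png", s.image)
        write_mask(root / "masks" / f"{stem}.tif", s.nuclei_mask)
        pd.DataFrame({
            "label": np.arange(1, len(s.centroids) + 1),
            "row": s.centroids[:, 0] if len(s.centroids) else [],
            "col": s.centroids[:, 1] if len(s.centroids) else [],
        }).to_csv(root / "centroids" / f"{stem}.csv", index=False)
    if samples and samples[0].params is not None:
        p = samples[0].params
        meta = {
            "image_size": list(p.image_size),
            "n_nuclei": p.n_nuclei,
            "radius_range": list(p.radius_range),
            "background_preset": p.background_preset,
            "noise_amplitude": p.noise_amplitude,
            "seed": p.seed,
        }
        (root / "params.yaml").write_text(yaml.safe_dump(meta))


def read_dataset(directory: str | Path) -> list:
    """Load a dataset directory back into SyntheticSample records."""
    root = Path(directory)
    samples = []
    for img_path in sorted((root / "images").glob("img_*")):
        stem = img_path.stem
        image = read_image(img_path)
        mask = read_mask(root / "masks" / f"{stem}.tif")
        cent_path = root / "centroids" / f"{stem}.csv"
        if cent_path.exists():
            df = pd.read_csv(cent_path)
            cents = df[["row", "col"]].to_numpy()
        else:
            cents = np.empty((0, 2))
        samples.append(SyntheticSample(image=image, nuclei_mask=mask,
                                       centroids=cents, params=None))
    return samples
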