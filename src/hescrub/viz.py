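"""Optional 2D embedding of patch features, for inspecting class separation.

Returns coordinates only; plotting is left to the caller.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError

__all__ = ["embed_features"]


def embed_features(features: np.ndarray, method: str = "pca",
                   seed: int = 0) -> np.ndarray:
    """Project N x D features to N x 2 with PCA or t-SNE."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ParameterError("need an N x D matrix with N >= 2")
    if method == "pca":
        from sklearn.decomposition import PCA
        return PCA(n_components=2, random_state=seed).fit_transform(x)
    if method == "tsne":
        from sklearn.manifold import TSNE
        perp = min(30.0, max(2.0, x.shape[0] / 4))
        return TSNE(n_components=2, random_state=seed,
                    perplexity=perp, init="pca").fit_transform(x)
    raise ParameterError(f"unknown embedding method {method!r}")
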