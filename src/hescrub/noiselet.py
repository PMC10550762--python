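"""Discrete noiselet basis and transforms.

Noiselets are a complex-valued multiresolution family built on the
Haar–Walsh system.  The family is defined by the recursion

    f_1(x)      = chi_[0,1)(x)
    f_2n(x)     = (1-i) f_n(2x) + (1+i) f_n(2x-1)
    f_2n+1(x)   = (1+i) f_n(2x) + (1-i) f_n(2x-1)

Sampling f_m .. f_{2m-1} on the m dyadic subintervals of [0,1) yields an
m x m complex matrix whose entries all share magnitude sqrt(m).
We divide by m so the matrix is unitary and Parseval holds; distances in
coefficient space are then scale-free.

Two properties make noiselets useful as texture descriptors: every
localized (spiky) signal spreads flatly across the whole spectrum, and
low- and high-frequency content land 90 degrees apart in the complex
plane, so smooth and oscillatory patches are separated by coefficient
phase rather than by magnitude alone.

The basis is built by explicit recursion and applied by dense matrix
multiply; at the patch sizes used here (m <= 16) a fast butterfly would
gain nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "NoiseletBasis",
    "noiselet_basis",
    "noiselet_transform_1d",
    "inverse_noiselet_1d",
    "noiselet_transform_2d",
    "inverse_noiselet_2d",
    "patch_features",
    "feature_length",
]


def _is_power_of_two(m: int) -> bool:
    return m >= 1 and (m & (m - 1)) == 0


@dataclass(frozen=True)
class NoiseletBasis:
    """Unitary noiselet basis of dyadic size ``m``.

    Row ``r`` of ``matrix`` is the function f_{m+r} of the recursion,
    sampled on the m dyadic subintervals of [0,1) and divided by m.
    """

    size: int
    matrix: np.ndarray = field(repr=False)
    normalization: str = "unitary"

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.size, self.size):
            raise ParameterError("basis matrix shape does not match size")


def noiselet_basis(m: int) -> NoiseletBasis:
    """Build the unitary noiselet basis of size ``m`` (a power of 2).

    Raises
    ------
    ParameterError
        If ``m`` is not a positive power of 2; the noiselet recursion
        only defines bases of dyadic length.
    """
    if not isinstance(m, (int, np.integer)) or not _is_power_of_two(int(m)):
        raise ParameterError(f"noiselet basis size must be a power of 2, got {m!r}")
    m = int(m)
    u = np.ones((1, 1), dtype=np.complex128)
    size = 1
    a, b = 1.0 - 1.0j, 1.0 + 1.0j
    while size < m:
        nxt = np.empty((2 * size, 2 * size), dtype=np.complex128)
        # row r of the current level is f_{size+r}; its children f_{2(size+r)}
        # and f_{2(size+r)+1} sit at rows 2r and 2r+1 of the next level.
        nxt[0::2, :size] = a * u
        nxt[0::2, size:] = b * u
        nxt[1::2, :size] = b * u
        nxt[1::2, size:] = a * u
        u = nxt
        size *= 2
    return NoiseletBasis(size=m, matrix=u / m)


def _check_1d(signal: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    arr = np.asarray(signal)
    if arr.ndim != 1 or arr.shape[0] != basis.size:
        raise ParameterError(
            f"signal length {arr.shape} does not match basis size {basis.size}"
        )
    return arr


def noiselet_transform_1d(signal: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    """Project a length-m signal onto the noiselet basis (values = M @ x)."""
    return basis.matrix @ _check_1d(signal, basis).astype(np.complex128)


def inverse_noiselet_1d(coeffs: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    """Invert :func:`noiselet_transform_1d` (unitary: inverse is M^H)."""
    return basis.matrix.conj().T @ _check_1d(coeffs, basis).astype(np.complex128)


def _check_2d(patch: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    arr = np.asarray(patch)
    m = basis.size
    if arr.ndim != 2 or arr.shape != (m, m):
        raise ParameterError(f"patch shape {arr.shape} does not match basis {m}x{m}")
    return arr


def noiselet_transform_2d(patch: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    """Separable 2D noiselet transform: the basis applied along rows then columns.

    C = M P M^T, so Parseval and invertibility carry over from the 1D case.
    """
    p = _check_2d(patch, basis).astype(np.complex128)
    m = basis.matrix
    return m @ p @ m.T


def inverse_noiselet_2d(coeffs: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    """Exact inverse of :func:`noiselet_transform_2d`."""
    c = _check_2d(coeffs, basis).astype(np.complex128)
    m = basis.matrix
    return m.conj().T @ c @ m.conj()


def feature_length(m: int) -> int:
    """Length of the real feature vector of an m x m patch (2 m^2)."""
    return 2 * m * m


def patch_features(patch: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    """Real feature vector of one patch: 2D coefficients, real parts then
    imaginary parts, row-major.  Length 2 m^2 (8 for 2x2 patches)."""
    c = noiselet_transform_2d(patch, basis).ravel()
    return np.concatenate([c.real, c.imag])


def patch_features_batch(patches: np.ndarray, basis: NoiseletBasis) -> np.ndarray:
    """Vectorized :func:`patch_features` for an (N, m, m) stack -> (N, 2 m^2)."""
    arr = np.asarray(patches)
    if arr.ndim != 3 or arr.shape[1] != basis.size or arr.shape[2] != basis.size:
        raise ParameterError("patch stack must be (N, m, m) matching the basis")
    m = basis.matrix
    c = np.einsum("ij,njk,lk->nil", m, arr.astype(np.complex128), m)
    flat = c.reshape(arr.shape[0], -1)
    return np.concatenate([flat.real, flat.imag], axis=1)
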