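"""Orthonormal 2D discrete-cosine basis and the compressive-sensing matrix.

The basis matrix ``Psi`` is the m-by-m matrix whose columns are vectorized
2D DCT-II basis images (orthonormal normalization), so ``Psi.T @ Psi = I``.
Images are flattened in row-major (C) order everywhere in this package, and
basis columns are ordered by their 2D frequency pair in row-major order:
column ``k`` holds the basis image with (row-frequency, column-frequency)
``(k // width, k % width)``.

Coefficients are computed through :func:`scipy.fft.dctn` so the dense basis
matrix never needs to be materialized; :func:`build_basis` exists for small
problems, debugging and as the oracle against the fast-transform path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn, dct

__all__ = [
    "BasisSpec",
    "build_basis",
    "forward_coefficients",
    "inverse_coefficients",
    "sensing_matrix",
]


@dataclass(frozen=True)
class BasisSpec:
    """Shape and family of the analysis basis for images of ``height x width`` pixels."""

    height: int
    width: int
    family: str = "dct2"

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(
                f"basis dimensions must be positive, got {self.height}x{self.width}"
            )
        if self.family != "dct2":
            raise ValueError(f"unsupported basis family: {self.family!r}")

    @property
    def m(self) -> int:
        return self.height * self.width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def build_basis(spec: BasisSpec) -> np.ndarray:
    """Dense m-by-m orthonormal DCT-II basis matrix Psi.

    Column k is the vectorized basis image for frequency pair
    ``(k // width, k % width)``. Psi equals ``kron(D_h.T, D_w.T)`` where
    ``D_n`` is the orthonormal 1D DCT-II matrix, because a separable 2D basis
    image is the outer product of the two 1D basis vectors.
    """
    d_h = dct(np.eye(spec.height), axis=0, norm="ortho")
    d_w = dct(np.eye(spec.width), axis=0, norm="ortho")
    return np.kron(d_h.T, d_w.T)


def _check_length(vec: np.ndarray, spec: BasisSpec, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1 or vec.shape[0] != spec.m:
        raise ValueError(
            f"{name} has length {vec.shape}, expected ({spec.m},) for a "
            f"{spec.height}x{spec.width} basis"
        )
    return vec


def forward_coefficients(image_vector: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Analysis transform ``s = Psi.T @ x`` via the fast 2D DCT."""
    x = _check_length(image_vector, spec, "image vector")
    return dctn(x.reshape(spec.shape), norm="ortho").ravel()


def inverse_coefficients(coefficients: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Synthesis transform ``x = Psi @ s`` via the fast inverse 2D DCT."""
    s = _check_length(coefficients, spec, "coefficient vector")
    return idctn(s.reshape(spec.shape), norm="ortho").ravel()


def batch_forward(images: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Row-wise analysis transform of an (l, m) array of vectorized images."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != spec.m:
        raise ValueError(
            f"image array has shape {arr.shape}, expected (l, {spec.m})"
        )
    l = arr.shape[0]
    return dctn(
        arr.reshape(l, spec.height, spec.width), axes=(1, 2), norm="ortho"
    ).reshape(l, spec.m)


def sensing_matrix(stimuli, spec: BasisSpec) -> np.ndarray:
    """Compressive-sensing matrix ``Theta = Phi_c @ Psi``.

    Given a StimulusSet, rows are centered first (raw {0,1} entries minus
    the ensemble mean 0.5); a plain float array is taken as already-centered
    measurement rows and transformed as-is. Row i of the result is the DCT
    coefficient vector of measurement row i, since
    ``(Phi_c @ Psi)[i] = Psi.T @ phi_c_i``.
    """
    if hasattr(stimuli, "matrix"):
        phi = np.asarray(stimuli.matrix, dtype=float) - 0.5
    else:
        phi = np.asarray(stimuli, dtype=float)
    if phi.ndim != 2 or phi.shape[1] != spec.m:
        raise ValueError(
            f"stimulus dimension {phi.shape} does not match basis m={spec.m}"
        )
    return batch_forward(phi, spec)
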