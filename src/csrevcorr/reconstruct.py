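"""Template estimators: reverse correlation and closed-form 1-bit compressive sensing.

Reverse correlation estimates the template as the mean centered stimulus on
"yes" trials minus the mean centered stimulus on "no" trials (equivalently,
up to a scalar, ``Phi_c.T @ y`` for sign-coded responses). The compressive
sensing estimator works in the 2D-DCT coefficient domain: it forms the same
response-weighted average of the DCT-transformed centered stimuli,

    v = m^-1 Theta.T y,      Theta = Phi_c Psi,

keeps only the gamma largest-magnitude coefficients (optionally shrinking
the survivors — the soft-threshold operator P), rescales to unit norm by
zeta = ||P(v)||, and synthesizes the image estimate x_hat = Psi s_hat.
This is the analytic minimizer of the 1-bit sparse-recovery objective
``-m^-1 s.T Theta.T y + lambda ||s||_1`` over the unit ball, with lambda
always derived from gamma so the solution is exactly gamma-sparse.

Both estimators are invariant to positive rescaling for every metric used
downstream (r^2 and sign prediction), so leading scalars such as the
``m^-1`` factor are a bookkeeping convention, not substance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, forward_coefficients, inverse_coefficients
from .response_model import ResponseVector, StimulusSet

__all__ = [
    "SparseCoefficients",
    "Reconstruction",
    "revcorr_reconstruct",
    "soft_threshold_topk",
    "cs_reconstruct",
]


@dataclass(frozen=True)
class SparseCoefficients:
    """Unit-norm, gamma-sparse coefficient estimate s_hat in the basis domain."""

    s_hat: np.ndarray
    gamma: int
    lambda_used: float
    basis: BasisSpec

    def __post_init__(self) -> None:
        s = np.asarray(self.s_hat, dtype=float)
        object.__setattr__(self, "s_hat", s)
        nnz = int(np.count_nonzero(s))
        if nnz > self.gamma:
            raise ValueError(f"{nnz} nonzeros exceeds gamma={self.gamma}")
        nrm = np.linalg.norm(s)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError(f"s_hat must have unit norm, got {nrm}")

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.s_hat))


@dataclass(frozen=True)
class Reconstruction:
    """An estimate of the template with provenance."""

    x_hat: np.ndarray
    shape: tuple[int, int]
    method: str  # revcorr | cs | glm
    n_used: int
    gamma: int | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x_hat, dtype=float).ravel()
        object.__setattr__(self, "x_hat", x)
        h, w = self.shape
        if x.size != h * w:
            raise ValueError(f"x_hat length {x.size} != {h}x{w}")
        if not np.isfinite(x).all():
            raise ValueError("x_hat contains non-finite entries")

    def image(self) -> np.ndarray:
        return self.x_hat.reshape(self.shape)


def _infer_shape(stimuli: StimulusSet, shape: tuple[int, int] | None) -> tuple[int, int]:
    if shape is not None:
        return shape
    side = int(round(stimuli.m**0.5))
    if side * side != stimuli.m:
        raise ValueError(
            f"cannot infer an image shape from m={stimuli.m}; pass shape explicitly"
        )
    return (side, side)


def revcorr_reconstruct(
    stimuli: StimulusSet,
    responses: ResponseVector,
    shape: tuple[int, int] | None = None,
    form: str = "mean_difference",
) -> Reconstruction:
    """Classification image by reverse correlation on centered stimuli.

    ``form`` selects the estimator variant:

    - ``"mean_difference"`` (default): mean(centered stimuli | yes) minus
      mean(centered stimuli | no). Falls back to ``"phi_t_y"`` with a warning
      when all responses share one sign.
    - ``"phi_t_y"``: Phi_c.T @ y normalized by the trial count; proportional
      to the mean difference only for balanced responses, and the form the
      gamma = m compressive-sensing identity refers to.
    - ``"pinv"``: the full generalized-inverse regression
      (Phi_c.T Phi_c)^+ Phi_c.T y. Materializes the centered matrix; meant
      for small problems.
    """
    if responses.l != stimuli.l:
        raise ValueError(
            f"{responses.l} responses for {stimuli.l} stimuli"
        )
    shape = _infer_shape(stimuli, shape)
    y = responses.values.astype(float)
    if form == "mean_difference":
        pos = y > 0
        if pos.all() or (~pos).all():
            warnings.warn(
                "all responses share one sign; mean-difference reverse "
                "correlation is undefined, falling back to the Phi^T y form",
                stacklevel=2,
            )
            form = "phi_t_y"
        else:
            phi = stimuli.matrix
            # centering cancels in the difference of the two class means
            x_hat = phi[pos].mean(axis=0) - phi[~pos].mean(axis=0)
            return Reconstruction(x_hat, shape, "revcorr", stimuli.l,
                                  provenance={"form": "mean_difference"})
    if form == "phi_t_y":
        x_hat = stimuli.centered_tdot(y) / stimuli.l
    elif form == "pinv":
        phi_c = stimuli.matrix.astype(float) - 0.5
        x_hat, *_ = np.linalg.lstsq(phi_c, y, rcond=None)
    else:
        raise ValueError(f"unknown reverse-correlation form: {form!r}")
    return Reconstruction(x_hat, shape, "revcorr", stimuli.l,
                          provenance={"form": form})


def soft_threshold_topk(
    v: np.ndarray, gamma: int, mode: str = "soft"
) -> tuple[np.ndarray, float]:
    """Top-gamma thresholding operator P and the penalty level lambda it implies.

    ``hard`` keeps the gamma largest-|.| entries unchanged; ``soft``
    additionally shrinks the survivors toward zero by lambda, the
    (gamma+1)-th largest absolute value (0 when gamma >= len(v)). Ties at
    the threshold are broken toward lower indices. Returns (P(v), lambda).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1D coefficient vector")
    if gamma < 1:
        raise ValueError("gamma must be a positive integer")
    if mode not in ("soft", "hard"):
        raise ValueError(f"unknown thresholding mode: {mode!r}")
    if not np.any(v):
        raise ValueError("cannot threshold an all-zero vector")
    m = v.size
    if gamma >= m:
        return v.copy(), 0.0
    # stable argsort on -|v|: descending magnitude, lower index wins ties
    order = np.argsort(-np.abs(v), kind="stable")
    keep = order[:gamma]
    lam = float(np.abs(v[order[gamma]])) if mode == "soft" else 0.0
    out = np.zeros_like(v)
    if mode == "hard":
        out[keep] = v[keep]
    else:
        out[keep] = np.sign(v[keep]) * np.maximum(np.abs(v[keep]) - lam, 0.0)
    return out, lam


def cs_reconstruct(
    stimuli: StimulusSet,
    responses: ResponseVector,
    gamma: int,
    spec: BasisSpec | None = None,
    mode: str = "soft",
) -> tuple[SparseCoefficients, Reconstruction]:
    """Closed-form 1-bit compressive-sensing estimate in the 2D-DCT basis.

    Computes v = m^-1 Theta.T y (via the fast transform of Phi_c.T y, never
    materializing Theta), thresholds to gamma nonzeros, normalizes by
    zeta = ||P(v)|| to a unit-norm s_hat, and synthesizes x_hat = Psi s_hat.
    """
    if responses.l != stimuli.l:
        raise ValueError(f"{responses.l} responses for {stimuli.l} stimuli")
    if spec is None:
        spec = BasisSpec(*_infer_shape(stimuli, None))
    if spec.m != stimuli.m:
        raise ValueError(
            f"basis m={spec.m} does not match stimulus dimension {stimuli.m}"
        )
    y = responses.values.astype(float)
    back = stimuli.centered_tdot(y)  # Phi_c.T y
    v = forward_coefficients(back, spec) / spec.m
    pv, lam = soft_threshold_topk(v, gamma, mode=mode)
    zeta = np.linalg.norm(pv)
    if zeta == 0.0:
        raise ValueError(
            "thresholded coefficient vector is identically zero (zeta = 0); "
            "degenerate input"
        )
    s_hat = pv / zeta
    coeffs = SparseCoefficients(s_hat, gamma=gamma, lambda_used=lam, basis=spec)
    x_hat = inverse_coefficients(s_hat, spec)
    recon = Reconstruction(
        x_hat, spec.shape, "cs", stimuli.l, gamma=gamma,
        provenance={"mode": mode, "lambda": lam, "zeta": float(zeta)},
    )
    return coeffs, recon
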