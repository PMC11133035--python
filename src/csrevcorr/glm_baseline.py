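"""Sparse-GLM comparator: L1-penalized logistic regression in the DCT domain.

Fits basis-domain weights s by minimizing

    L(s) = sum_i log(1 + exp(-y_i (Theta s)_i)) + lambda ||s||_1,

where Theta = Phi_c Psi is the compressive-sensing matrix on centered
stimuli. The solver is FISTA (accelerated proximal gradient) with
backtracking line search and a monotone restart, applying Theta and its
transpose through the fast DCT so the l-by-m matrix is never stored.
The image-domain reconstruction Psi s is reported unit-normalized so it is
directly comparable to the other estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, forward_coefficients, inverse_coefficients
from .reconstruct import Reconstruction, _infer_shape
from .response_model import ResponseVector, StimulusSet

__all__ = ["GlmFit", "glm_reconstruct"]


@dataclass(frozen=True)
class GlmFit:
    s_glm: np.ndarray
    lambda_glm: float
    converged: bool
    n_iter: int
    objective: float

    def __post_init__(self) -> None:
        s = np.asarray(self.s_glm, dtype=float)
        object.__setattr__(self, "s_glm", s)
        if not np.isfinite(s).all():
            raise ValueError("GLM weights contain non-finite entries")


def _logistic_loss_grad(z: np.ndarray, y: np.ndarray):
    """Negative log-likelihood sum log(1+exp(-y z)) and d/dz, stably."""
    yz = y * z
    loss = np.logaddexp(0.0, -yz).sum()
    # d loss / dz = -y * sigmoid(-yz)
    grad_z = -y / (1.0 + np.exp(yz))
    return loss, grad_z


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def glm_reconstruct(
    stimuli: StimulusSet,
    responses: ResponseVector,
    lambda_glm: float,
    spec: BasisSpec | None = None,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> tuple[GlmFit, Reconstruction]:
    """L1-penalized logistic fit of responses on DCT-transformed stimuli.

    ``tol`` is the relative objective-change stopping criterion. A fit that
    reaches ``max_iter`` is returned with ``converged=False`` rather than
    raising.
    """
    if responses.l != stimuli.l:
        raise ValueError(f"{responses.l} responses for {stimuli.l} stimuli")
    if lambda_glm < 0:
        raise ValueError("lambda_glm must be nonnegative")
    if spec is None:
        spec = BasisSpec(*_infer_shape(stimuli, None))
    if spec.m != stimuli.m:
        raise ValueError(f"basis m={spec.m} != stimulus dimension {stimuli.m}")
    y = responses.values.astype(float)

    def theta_dot(s):  # Theta s = Phi_c (Psi s)
        return stimuli.centered_dot(inverse_coefficients(s, spec))

    def theta_tdot(r):  # Theta.T r = Psi.T (Phi_c.T r)
        return forward_coefficients(stimuli.centered_tdot(r), spec)

    def objective(sv, zv=None):
        if zv is None:
            zv = theta_dot(sv)
        loss, _ = _logistic_loss_grad(zv, y)
        return loss + lambda_glm * np.abs(sv).sum()

    def prox_step(point, step):
        """Backtracked proximal-gradient step from ``point``; returns (next, step)."""
        zp = theta_dot(point)
        loss_p, gz = _logistic_loss_grad(zp, y)
        grad = theta_tdot(gz)
        while True:
            cand = _soft(point - step * grad, step * lambda_glm)
            loss_c, _ = _logistic_loss_grad(theta_dot(cand), y)
            diff = cand - point
            quad = loss_p + grad @ diff + (diff @ diff) / (2.0 * step)
            if loss_c <= quad + 1e-12 * max(1.0, abs(loss_p)) or step < 1e-18:
                return cand, step
            step *= 0.5

    m = spec.m
    s = np.zeros(m)
    u_prev = s.copy()  # accelerated sequence
    t_mom = 1.0
    # initial step from a cheap spectral bound; backtracking tightens it
    step = 4.0 / max(0.25 * stimuli.l, 1.0)
    obj = objective(s)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = s + ((t_mom - 1.0) / t_mom) * (s - u_prev) if it > 1 else s
        u, step = prox_step(w, step)
        obj_u = objective(u)
        # MFISTA: the monotone iterate takes whichever of {u, s} is better
        if obj_u <= obj:
            s_new, obj_new = u, obj_u
            improved = True
            t_mom = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        else:  # momentum overshoot: keep s, restart acceleration
            s_new, obj_new = s, obj
            improved = False
            t_mom = 1.0
            u = s
        u_prev, s = u, s_new
        if improved and abs(obj - obj_new) <= tol * max(1.0, abs(obj)):
            obj = obj_new
            converged = True
            break
        obj = obj_new

    fit = GlmFit(s, lambda_glm=lambda_glm, converged=converged, n_iter=it,
                 objective=float(obj))
    x_hat = inverse_coefficients(s, spec)
    nrm = np.linalg.norm(x_hat)
    if nrm > 0:
        x_hat = x_hat / nrm
    recon = Reconstruction(
        x_hat, spec.shape, "glm", stimuli.l,
        provenance={"lambda": lambda_glm, "converged": converged, "n_iter": it},
    )
    return fit, recon
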