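"""Round-trip I/O for stimuli, responses, templates and reconstructions.

Two interchange formats: a compressed NumPy archive (.npz) and delimited
text. The text layout for a stimulus-response table is one row per trial —
the m pixel values followed by the response in a final column — with
responses written in the conventional 1 (yes) / 0 (no) coding. On load,
responses given as {1, 0} or {+1, -1} are both accepted and mapped to the
package's internal sign coding. This is the interface through which an
externally collected dataset (a trials-by-pixels stimulus matrix plus a
binary response vector) enters the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .reconstruct import Reconstruction, SparseCoefficients
from .response_model import ResponseVector, StimulusSet, Template

__all__ = [
    "save_dataset_npz",
    "load_dataset_npz",
    "save_dataset_text",
    "load_dataset_text",
    "load_real_data",
    "save_template_text",
    "load_template_text",
    "save_template_png",
    "save_reconstruction",
]


def _to_sign_coding(y: np.ndarray) -> np.ndarray:
    y = np.asarray(np.rint(y), dtype=np.int8)
    vals = set(np.unique(y).tolist())
    if vals <= {0, 1}:
        return np.where(y == 1, 1, -1).astype(np.int8)
    if vals <= {-1, 1}:
        return y
    raise ValueError(f"responses must be coded {{1,0}} or {{+1,-1}}, found {sorted(vals)}")


def save_dataset_npz(path, stimuli: StimulusSet, responses: ResponseVector) -> None:
    np.savez_compressed(
        path,
        stimuli=stimuli.matrix,
        responses=responses.values,
        seed=-1 if stimuli.seed is None else stimuli.seed,
        noise_sigma=responses.noise_sigma,
    )


def load_dataset_npz(path) -> tuple[StimulusSet, ResponseVector]:
    with np.load(path) as z:
        seed = int(z["seed"])
        stim = StimulusSet(z["stimuli"], seed=None if seed < 0 else seed)
        resp = ResponseVector(
            _to_sign_coding(z["responses"]), noise_sigma=float(z["noise_sigma"])
        )
    return stim, resp


def save_dataset_text(path, stimuli: StimulusSet, responses: ResponseVector) -> None:
    """One row per trial: m pixel values then the response as 1 (yes) / 0 (no)."""
    y01 = (responses.values > 0).astype(np.int8)
    table = np.column_stack([stimuli.matrix, y01])
    np.savetxt(path, table, fmt="%d")


def load_dataset_text(path, delimiter=None) -> tuple[StimulusSet, ResponseVector]:
    table = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    stim = StimulusSet(table[:, :-1].astype(np.int8))
    resp = ResponseVector(_to_sign_coding(table[:, -1]))
    return stim, resp


def load_real_data(stimuli_path, responses_path, delimiter=None):
    """Load a stimulus matrix and response vector from separate files.

    Accepts delimited text or .npy/.npz for either file; responses may be
    coded {1, 0} or {+1, -1}.
    """
    def _load(p):
        p = Path(p)
        if p.suffix == ".npy":
            return np.load(p)
        if p.suffix == ".npz":
            with np.load(p) as z:
                return z[list(z.files)[0]]
        return np.loadtxt(p, delimiter=delimiter)

    stim = StimulusSet(np.atleast_2d(_load(stimuli_path)).astype(np.int8))
    resp = ResponseVector(_to_sign_coding(np.ravel(_load(responses_path))))
    if resp.l != stim.l:
        raise ValueError(f"{resp.l} responses for {stim.l} stimuli")
    return stim, resp


def save_template_text(path, template: Template) -> None:
    np.savetxt(path, template.image(), fmt="%.6f", header=template.label)


def load_template_text(path, label="") -> Template:
    img = np.loadtxt(path, ndmin=2)
    return Template(img.ravel(), img.shape, label=label)


def _to_png(path, image: np.ndarray) -> None:
    from PIL import Image

    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)


def save_template_png(path, template: Template) -> None:
    _to_png(path, template.image())


def save_reconstruction(
    basepath,
    recon: Reconstruction,
    coeffs: SparseCoefficients | None = None,
) -> None:
    """Write <base>.png (min-max display scaling), <base>.txt (lossless
    x_hat), optional <base>.coeffs.txt, and a <base>.json metadata sidecar."""
    base = Path(basepath)
    _to_png(base.with_suffix(".png"), recon.image())
    np.savetxt(base.with_suffix(".txt"), recon.image(), fmt="%.12e")
    meta = {
        "method": recon.method,
        "n_used": recon.n_used,
        "gamma": recon.gamma,
        "shape": list(recon.shape),
        "provenance": recon.provenance,
    }
    if coeffs is not None:
        np.savetxt(base.with_suffix(".coeffs.txt"), coeffs.s_hat, fmt="%.12e")
        meta["lambda_used"] = coeffs.lambda_used
        meta["basis"] = {
            "height": coeffs.basis.height,
            "width": coeffs.basis.width,
            "family": coeffs.basis.family,
        }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
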