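"""Templates, binary noise stimuli, and simulated yes/no observers.

The observer model: on each trial a random binary stimulus ``phi_i`` is
compared against the latent template ``x`` and the observer answers yes/no
according to the sign of the (noisy) decision variable

    z_i = (phi_i - phi_bar) . (x - x_bar),        y_i = sign(z_i + eps_i),

where ``phi_bar = 0.5`` per pixel is the stimulus-ensemble mean and
``x_bar`` the template mean. Centering both factors keeps the noiseless
decision variable balanced around zero; with raw {0,1} stimuli and a
nonnegative template the inner product would be strictly positive and the
observer would answer "yes" on every trial. Responses are coded internally
as -1/+1 (the difference-of-means estimator and the 1-bit sparse estimator
both assume sign coding); the 1/0 yes/no coding is mapped at I/O boundaries.

Observer noise is parameterized by ``sigma``. Three mechanisms:

- ``flip`` (default): negates each noiseless response independently with
  probability ``sigma / 100`` — sigma is literally the expected percentage
  of incorrect responses, so sigma = 50 is a completely random responder
  and sigma = 100 a perfectly contrarian one.
- ``additive_gaussian``: adds eps_i ~ N(0, sigma) to the decision variable,
  with sigma read as the noise *variance*. The incorrect-response rate this
  induces depends on the scale of the decision variable, i.e. on the
  template; for the canonical 50x50 letters it lands near 12% at sigma = 25
  and 17% at sigma = 50, a moderately and a heavily degraded observer that
  both retain signal. This is the mechanism the noisy simulation studies
  use.
- ``calibrated_gaussian``: additive Gaussian noise whose scale is solved so
  the induced sign-flip rate is sigma percent. A sign flip from additive
  symmetric noise can never exceed 50%, so this covers sigma < 50 only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "Template",
    "StimulusSet",
    "ResponseVector",
    "NoiseSpec",
    "make_letter_template",
    "make_dot_template",
    "generate_stimuli",
    "simulate_responses",
    "decision_variable",
]

_SHIPPED_LETTERS = {("S", (50, 50)), ("K", (50, 50))}


@dataclass(frozen=True)
class Template:
    """Ground-truth latent representation: a grayscale image in [0, 1]."""

    pixels: np.ndarray  # flat m-vector, row-major
    shape: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float).ravel()
        object.__setattr__(self, "pixels", px)
        h, w = self.shape
        if h <= 0 or w <= 0:
            raise ValueError(f"template shape must be positive, got {self.shape}")
        if px.size != h * w:
            raise ValueError(
                f"template has {px.size} pixels, expected {h}x{w}={h * w}"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("template intensities must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.pixels.size

    def image(self) -> np.ndarray:
        return self.pixels.reshape(self.shape)

    def centered(self) -> np.ndarray:
        """Template minus its mean; the quantity the observer actually compares against."""
        return self.pixels - self.pixels.mean()


@dataclass(frozen=True)
class StimulusSet:
    """l binary {0,1} stimuli as rows of an l-by-m measurement matrix."""

    matrix: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2 or mat.shape[0] < 1:
            raise ValueError("stimulus matrix must be 2D with at least one row")
        vals = np.unique(mat)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("stimulus entries must be exactly 0 or 1")
        object.__setattr__(self, "matrix", mat.astype(np.int8, copy=False))

    @property
    def l(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def _matrix_float(self) -> np.ndarray:
        # lazy float64 copy: keeps repeated matvecs on the BLAS fast path
        cached = self.__dict__.get("_matrix_float_cache")
        if cached is None:
            cached = self.matrix.astype(np.float64)
            object.__setattr__(self, "_matrix_float_cache", cached)
        return cached

    def centered_dot(self, v: np.ndarray) -> np.ndarray:
        """(Phi - 0.5) @ v without materializing the centered float matrix."""
        v = np.asarray(v, dtype=float)
        return self._matrix_float @ v - 0.5 * v.sum()

    def centered_tdot(self, r: np.ndarray) -> np.ndarray:
        """(Phi - 0.5).T @ r without materializing the centered float matrix."""
        r = np.asarray(r, dtype=float)
        return r @ self._matrix_float - 0.5 * r.sum()

    def subset(self, idx: np.ndarray) -> "StimulusSet":
        return StimulusSet(self.matrix[idx], seed=self.seed)


@dataclass(frozen=True)
class ResponseVector:
    """l yes/no responses sign-coded as +1 (yes) / -1 (no)."""

    values: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (-1, 1)).all():
            raise ValueError("responses must be exactly -1 or +1")
        object.__setattr__(self, "values", v.astype(np.int8, copy=False))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def l(self) -> int:
        return self.values.size

    def subset(self, idx: np.ndarray) -> "ResponseVector":
        return ResponseVector(self.values[idx], self.noise_sigma, self.seed)


@dataclass(frozen=True)
class NoiseSpec:
    """Observer noise level sigma (percent scale) and mechanism."""

    sigma: float = 0.0
    mechanism: str = "flip"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.mechanism not in ("flip", "additive_gaussian", "calibrated_gaussian"):
            raise ValueError(f"unknown noise mechanism: {self.mechanism!r}")
        if self.mechanism == "flip" and self.sigma > 100:
            raise ValueError("flip mechanism requires sigma <= 100 (percent scale)")
        if self.mechanism == "calibrated_gaussian" and self.sigma >= 50:
            raise ValueError(
                "additive Gaussian noise cannot flip more than 50% of responses; "
                "use the flip mechanism for sigma >= 50"
            )


def _load_shipped_letter(letter: str, shape: tuple[int, int]) -> np.ndarray:
    fname = f"template_{letter}_{shape[0]}x{shape[1]}.txt"
    ref = importlib.resources.files("csrevcorr.data").joinpath(fname)
    with importlib.resources.as_file(ref) as path:
        return np.loadtxt(path)


def make_letter_template(letter: str, shape: tuple[int, int] = (50, 50)) -> Template:
    """Grayscale rasterization of a letter, scaled to ``shape``, in [0, 1].

    The canonical "S" and "K" at 50x50 ship as fixed plain-text fixtures so
    reconstruction targets do not depend on which fonts the host has
    installed. Other letters/sizes are rasterized at run time from the
    DejaVu Sans font bundled with matplotlib (horizontally stretched
    lowercase glyph, antialiased), mirroring how the fixtures were made.
    """
    if len(letter) != 1 or not letter.isprintable() or letter.isspace():
        raise ValueError(f"cannot rasterize letter {letter!r}")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"template shape must be positive, got {shape}")
    key = letter.upper()
    if (key, (h, w)) in _SHIPPED_LETTERS:
        img = _load_shipped_letter(key, (h, w))
        return Template(img.ravel(), (h, w), label=key)
    img = _rasterize_letter(letter, (h, w))
    return Template(img.ravel(), (h, w), label=key)


def _rasterize_letter(letter: str, shape: tuple[int, int], stretch: float = 1.6) -> np.ndarray:
    import os

    import matplotlib
    from PIL import Image, ImageDraw, ImageFont

    font_path = os.path.join(
        os.path.dirname(matplotlib.__file__), "mpl-data", "fonts", "ttf", "DejaVuSans.ttf"
    )
    font = ImageFont.truetype(font_path, 400)
    canvas = Image.new("L", (1200, 1200), 0)
    ImageDraw.Draw(canvas).text((600, 600), letter.lower(), fill=255, font=font, anchor="mm")
    box = canvas.getbbox()
    if box is None:
        raise ValueError(f"letter {letter!r} rasterized to an empty image")
    glyph = canvas.crop(box)
    glyph = glyph.resize((max(1, int(glyph.width * stretch)), glyph.height), Image.LANCZOS)
    glyph = glyph.resize((shape[1], shape[0]), Image.LANCZOS)
    return np.clip(np.asarray(glyph, dtype=float) / 255.0, 0.0, 1.0)


def make_dot_template(
    shape: tuple[int, int], center: tuple[int, int], radius: float
) -> Template:
    """Binary disc template: 1 within ``radius`` of ``center``, 0 outside."""
    h, w = shape
    ci, cj = center
    if not (0 <= ci < h and 0 <= cj < w):
        raise ValueError(f"center {center} lies outside a {h}x{w} image")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    ii, jj = np.mgrid[0:h, 0:w]
    disc = ((ii - ci) ** 2 + (jj - cj) ** 2 <= radius**2).astype(float)
    return Template(disc.ravel(), shape, label="dot")


def generate_stimuli(l: int, shape: tuple[int, int], seed: int) -> StimulusSet:
    """l i.i.d. Bernoulli(0.5) binary stimuli of the given image shape."""
    if l < 1:
        raise ValueError("need at least one trial")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"stimulus shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 2, size=(l, h * w), dtype=np.int8)
    return StimulusSet(mat, seed=seed)


def decision_variable(template_pixels: np.ndarray, stimuli: StimulusSet) -> np.ndarray:
    """Centered inner products z_i = (phi_i - 0.5) . (x - x_bar) for all trials.

    Works for any pixel vector standing in for the template (e.g. a
    reconstruction during response prediction).
    """
    x = np.asarray(template_pixels, dtype=float).ravel()
    if x.size != stimuli.m:
        raise ValueError(
            f"template has {x.size} pixels but stimuli have {stimuli.m}"
        )
    return stimuli.centered_dot(x - x.mean())


def _sign_plus(z: np.ndarray) -> np.ndarray:
    # fixed tie-break: sign(0) = +1
    return np.where(z >= 0, 1, -1).astype(np.int8)


def _calibrate_gaussian_scale(z: np.ndarray, target_rate: float) -> float:
    """Noise s.d. making the mean sign-flip probability equal target_rate.

    P(flip_i) = Phi(-|z_i| / scale) increases monotonically in scale from 0
    toward 0.5, so the root is bracketed and unique.
    """
    absz = np.abs(z)
    scale_ref = max(np.median(absz), 1e-12)

    def rate(scale: float) -> float:
        return norm.cdf(-absz / scale).mean() - target_rate

    lo, hi = 1e-9 * scale_ref, 1e9 * scale_ref
    return brentq(rate, lo, hi, xtol=1e-12 * scale_ref)


def simulate_responses(
    template: Template,
    stimuli: StimulusSet,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> ResponseVector:
    """Simulated yes/no responses: y = sign(z + eps) on centered quantities."""
    z = decision_variable(template.pixels, stimuli)
    y0 = _sign_plus(z)
    if noise.sigma == 0:
        return ResponseVector(y0, noise_sigma=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    if noise.mechanism == "flip":
        flips = rng.random(stimuli.l) < noise.sigma / 100.0
        y = np.where(flips, -y0, y0)
    else:
        if noise.mechanism == "additive_gaussian":
            scale = float(np.sqrt(noise.sigma))  # sigma is the variance
        else:
            scale = _calibrate_gaussian_scale(z, noise.sigma / 100.0)
        y = _sign_plus(z + rng.normal(0.0, scale, size=stimuli.l))
    return ResponseVector(y, noise_sigma=noise.sigma, seed=seed)
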