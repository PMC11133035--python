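"""Reconstruction-quality metrics and response-prediction cross-validation.

Two complementary measures: (1) template r^2 — the squared Pearson
correlation between a reconstruction and the ground-truth template,
available only in simulation where the template is observable; and
(2) balanced accuracy of the responses the reconstruction predicts for
held-out stimuli under the noiseless sign rule, which works for human data
where no template exists. r^2 is symmetric in sign (a perfectly
anti-correlated estimate also scores 1); the signed correlation is exposed
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold

from .reconstruct import Reconstruction, cs_reconstruct, revcorr_reconstruct
from .response_model import ResponseVector, StimulusSet, decision_variable

__all__ = [
    "QualityReport",
    "template_correlation",
    "template_r2",
    "predict_responses",
    "balanced_accuracy",
    "kfold_prediction_cv",
    "paired_accuracy_ttest",
]


@dataclass(frozen=True)
class QualityReport:
    balanced_accuracy: float
    n_eval: int
    folds: int
    per_fold: list = field(default_factory=list)
    r2: float | None = None
    flagged_folds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.balanced_accuracy <= 1.0):
            raise ValueError("balanced accuracy must lie in [0, 1]")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must lie in [0, 1]")


def _pixels(x) -> np.ndarray:
    if isinstance(x, Reconstruction):
        return x.x_hat
    if hasattr(x, "pixels"):
        return np.asarray(x.pixels, dtype=float).ravel()
    return np.asarray(x, dtype=float).ravel()


def template_correlation(x_hat, template) -> float:
    """Signed Pearson correlation between reconstruction and template pixels."""
    a, b = _pixels(x_hat), _pixels(template)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.corrcoef(a, b)[0, 1])


def template_r2(x_hat, template) -> float:
    """Squared Pearson correlation over vectorized pixels (sign-blind)."""
    return template_correlation(x_hat, template) ** 2


def predict_responses(x_hat, stimuli: StimulusSet) -> ResponseVector:
    """Deterministic responses a noiseless observer with template ``x_hat`` would give."""
    z = decision_variable(_pixels(x_hat), stimuli)
    return ResponseVector(np.where(z >= 0, 1, -1).astype(np.int8), noise_sigma=0.0)


def balanced_accuracy(predicted: ResponseVector, actual: ResponseVector) -> float:
    """Mean of the true-positive and true-negative rates."""
    p = predicted.values if isinstance(predicted, ResponseVector) else np.asarray(predicted)
    a = actual.values if isinstance(actual, ResponseVector) else np.asarray(actual)
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} predictions for {a.size} responses")
    present = np.unique(a)
    for cls in (-1, 1):
        if cls not in present:
            name = "yes (+1)" if cls == 1 else "no (-1)"
            raise ValueError(f"actual responses contain no {name} trials")
    return float(balanced_accuracy_score(a, p))


_FITTERS = {
    "revcorr": lambda st, re, params: revcorr_reconstruct(st, re, **params),
    "cs": lambda st, re, params: cs_reconstruct(st, re, **params)[1],
    "template": lambda st, re, params: params["template"],
}


def _fit_glm(st, re, params):
    from .glm_baseline import glm_reconstruct

    return glm_reconstruct(st, re, **params)[1]


_FITTERS["glm"] = _fit_glm


def kfold_prediction_cv(
    stimuli: StimulusSet,
    responses: ResponseVector,
    method: str = "revcorr",
    k: int = 5,
    method_params: dict | None = None,
    seed: int = 0,
    contiguous: bool = False,
    template=None,
) -> QualityReport:
    """Pooled held-out response-prediction balanced accuracy.

    For each of ``k`` folds the named estimator is fit on the other k-1
    folds, its reconstruction predicts the held-out responses via the
    noiseless sign rule, and predictions pooled over all folds are scored
    once against the actual responses. Folds are seeded random partitions by
    default; ``contiguous=True`` uses contiguous blocks instead. A fold
    whose actual responses contain a single class is flagged (its per-fold
    accuracy is nan) but still contributes to the pooled score. With
    ``template`` given, the report also carries the mean r^2 of the per-fold
    reconstructions against it.
    """
    if k < 2 or k > stimuli.l:
        raise ValueError(f"need 2 <= k <= l, got k={k}, l={stimuli.l}")
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; options: {sorted(_FITTERS)}")
    params = dict(method_params or {})
    splitter = KFold(n_splits=k, shuffle=not contiguous,
                     random_state=seed if not contiguous else None)
    pooled_pred = np.empty(stimuli.l, dtype=np.int8)
    per_fold, flagged, r2s = [], [], []
    for fold, (train, test) in enumerate(splitter.split(stimuli.matrix)):
        recon = _FITTERS[method](stimuli.subset(train), responses.subset(train), params)
        pred = predict_responses(recon, stimuli.subset(test))
        pooled_pred[test] = pred.values
        actual = responses.values[test]
        if np.unique(actual).size < 2:
            flagged.append(fold)
            per_fold.append(float("nan"))
        else:
            per_fold.append(float(balanced_accuracy_score(actual, pred.values)))
        if template is not None:
            r2s.append(template_r2(recon, template))
    pooled = balanced_accuracy(ResponseVector(pooled_pred), responses)
    return QualityReport(
        balanced_accuracy=pooled,
        n_eval=stimuli.l,
        folds=k,
        per_fold=per_fold,
        r2=float(np.mean(r2s)) if r2s else None,
        flagged_folds=flagged,
    )


def paired_accuracy_ttest(accuracies_a, accuracies_b):
    """Thin convenience wrapper: paired t test on per-subject accuracies.

    Off-the-shelf statistic, not part of the reconstruction method itself.
    Returns (t statistic, two-sided p value).
    """
    res = stats.ttest_rel(np.asarray(accuracies_a, float), np.asarray(accuracies_b, float))
    return float(res.statistic), float(res.pvalue)
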