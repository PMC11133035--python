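"""Sparsity-level (gamma) selection for the 1-bit compressive-sensing estimator.

Two protocols:

- :func:`select_gamma_heldout` — the simulation protocol: fit the CS
  estimator once per gamma on a training set, then score each fit's
  response-prediction balanced accuracy on several freshly simulated
  held-out stimulus-response sets; pick the gamma with the best mean.
- :func:`select_gamma_nested_cv` — the protocol for real subject data,
  where no fresh data can be simulated: per outer fold, train on 8/10 of
  the trials, pick gamma on a 1/10 validation slice, score on the remaining
  1/10 test slice; the final gamma is the mode of the per-fold winners.

Ties always break toward smaller gamma (the more parsimonious model). The
key convenience exploited throughout: the pre-threshold coefficient vector
``v = m^-1 Theta.T y`` does not depend on gamma, so one pass over the data
serves every grid point.

The default grids follow the two protocols: SIMULATION_GAMMA_GRID
{2, 4, ..., 2048} and HUMAN_GAMMA_GRID {2, 4, ..., 1024}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec
from .evaluate import balanced_accuracy, predict_responses
from .reconstruct import cs_reconstruct
from .response_model import (
    NoiseSpec,
    ResponseVector,
    StimulusSet,
    Template,
    generate_stimuli,
    simulate_responses,
)

__all__ = [
    "SIMULATION_GAMMA_GRID",
    "HUMAN_GAMMA_GRID",
    "GammaSearchResult",
    "select_gamma_heldout",
    "select_gamma_nested_cv",
    "select_lambda_glm_heldout",
]

SIMULATION_GAMMA_GRID = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024, 2048)
HUMAN_GAMMA_GRID = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)


@dataclass(frozen=True)
class GammaSearchResult:
    grid: tuple
    mean_accuracy: np.ndarray  # one entry per grid point; nan for failed fits
    best_gamma: int
    per_set_accuracy: np.ndarray  # (held-out sets, grid points)
    failed: tuple = ()

    def __post_init__(self) -> None:
        if self.best_gamma not in self.grid:
            raise ValueError("best_gamma must come from the grid")
        if len(self.mean_accuracy) != len(self.grid):
            raise ValueError("one mean accuracy per grid point required")


def _column_means(acc: np.ndarray) -> np.ndarray:
    """Per-column nan-aware means; all-nan columns stay nan without warnings."""
    out = np.full(acc.shape[1], np.nan)
    for i in range(acc.shape[1]):
        col = acc[:, i]
        good = ~np.isnan(col)
        if good.any():
            out[i] = col[good].mean()
    return out


def _argbest_smaller_tie(grid, means) -> int:
    """Index of the max mean accuracy; ties and near-ties go to smaller gamma."""
    means = np.asarray(means, dtype=float)
    if np.all(np.isnan(means)):
        raise ValueError("every gamma on the grid failed; nothing to select")
    best = np.nanmax(means)
    # grid is sorted ascending: first index within tie tolerance wins
    for i, v in enumerate(means):
        if not np.isnan(v) and v >= best - 1e-12:
            return i
    raise AssertionError("unreachable")


def select_gamma_heldout(
    template: Template,
    n: int,
    noise: NoiseSpec = NoiseSpec(),
    grid=SIMULATION_GAMMA_GRID,
    n_heldout_sets: int = 8,
    seed: int = 0,
    mode: str = "soft",
    n_heldout: int | None = None,
) -> GammaSearchResult:
    """Grid search for gamma by mean prediction accuracy on fresh held-out sets.

    A training set of ``n`` trials is simulated from ``template`` under
    ``noise``; the CS estimator is fit once per gamma. Each of
    ``n_heldout_sets`` independent sets (``n_heldout`` trials each,
    defaulting to ``n``) is then simulated from the same observer, and each
    gamma's reconstruction predicts its responses. best_gamma maximizes the
    mean balanced accuracy across sets.
    """
    grid = tuple(sorted(int(g) for g in grid))
    if not grid or grid[0] < 1:
        raise ValueError("gamma grid must be nonempty with entries >= 1")
    if n_heldout is None:
        n_heldout = n
    spec = BasisSpec(*template.shape)
    train_stim = generate_stimuli(n, template.shape, seed=seed)
    train_resp = simulate_responses(template, train_stim, noise, seed=seed + 1)

    recons, failed = {}, []
    for g in grid:
        try:
            _, recon = cs_reconstruct(train_stim, train_resp, g, spec, mode=mode)
            recons[g] = recon
        except ValueError:
            failed.append(g)

    acc = np.full((n_heldout_sets, len(grid)), np.nan)
    for j in range(n_heldout_sets):
        ho_stim = generate_stimuli(n_heldout, template.shape, seed=seed + 100 + 2 * j)
        ho_resp = simulate_responses(template, ho_stim, noise, seed=seed + 101 + 2 * j)
        for i, g in enumerate(grid):
            if g in recons:
                pred = predict_responses(recons[g], ho_stim)
                acc[j, i] = balanced_accuracy(pred, ho_resp)

    means = _column_means(acc)
    best = grid[_argbest_smaller_tie(grid, means)]
    return GammaSearchResult(grid, means, best, acc, failed=tuple(failed))


def select_gamma_nested_cv(
    stimuli: StimulusSet,
    responses: ResponseVector,
    grid=HUMAN_GAMMA_GRID,
    k_outer: int = 10,
    seed: int = 0,
    mode: str = "soft",
    shape: tuple[int, int] | None = None,
    selection_hook=None,
):
    """Nested slice-rotation gamma selection for measured (human) data.

    Trials are partitioned into ``k_outer`` seeded random slices. For outer
    fold i the validation slice is i and the test slice is (i+1) mod
    k_outer; the remaining k-2 slices train the estimator. gamma is chosen
    per fold by validation balanced accuracy (ties to smaller gamma), that
    winner is scored once on the test slice, and the returned gamma is the
    mode of the per-fold winners (modal ties to smaller gamma).

    ``selection_hook(fold, train_idx, val_idx)``, if given, is called with
    exactly the trial indices the selection path is allowed to see — the
    test slice is withheld by construction.

    Returns ``(per_fold_gammas, modal_gamma, per_fold_test_accuracy)``.
    """
    grid = tuple(sorted(int(g) for g in grid))
    l = stimuli.l
    if k_outer < 3 or k_outer > l:
        raise ValueError(f"need 3 <= k_outer <= l, got k_outer={k_outer}, l={l}")
    if shape is None:
        from .reconstruct import _infer_shape

        shape = _infer_shape(stimuli, None)
    spec = BasisSpec(*shape)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(l)
    slices = np.array_split(perm, k_outer)

    per_fold_gammas, per_fold_test_acc = [], []
    for i in range(k_outer):
        val_idx = slices[i]
        test_idx = slices[(i + 1) % k_outer]
        train_idx = np.concatenate(
            [slices[j] for j in range(k_outer) if j != i and j != (i + 1) % k_outer]
        )
        if selection_hook is not None:
            selection_hook(i, train_idx, val_idx)
        tr_s, tr_r = stimuli.subset(train_idx), responses.subset(train_idx)
        val_s = stimuli.subset(val_idx)
        val_actual = responses.subset(val_idx)
        means = np.full(len(grid), np.nan)
        recons = {}
        for gi, g in enumerate(grid):
            try:
                _, recon = cs_reconstruct(tr_s, tr_r, g, spec, mode=mode)
            except ValueError:
                continue
            recons[g] = recon
            try:
                means[gi] = balanced_accuracy(
                    predict_responses(recon, val_s), val_actual
                )
            except ValueError:  # single-class validation slice
                means[gi] = np.nan
        gi = _argbest_smaller_tie(grid, means)
        g_best = grid[gi]
        per_fold_gammas.append(g_best)
        try:
            test_acc = balanced_accuracy(
                predict_responses(recons[g_best], stimuli.subset(test_idx)),
                responses.subset(test_idx),
            )
        except ValueError:
            test_acc = float("nan")
        per_fold_test_acc.append(test_acc)

    counts = Counter(per_fold_gammas)
    top = max(counts.values())
    modal = min(g for g, c in counts.items() if c == top)
    return per_fold_gammas, modal, per_fold_test_acc


def select_lambda_glm_heldout(
    template: Template,
    n: int,
    noise: NoiseSpec = NoiseSpec(),
    lambda_grid=None,
    n_heldout_sets: int = 8,
    seed: int = 0,
    n_heldout: int | None = None,
    max_iter: int = 2000,
):
    """Held-out grid search for the GLM penalty, mirroring the gamma protocol.

    Default grid: 8 log-spaced values spanning 1e-2 .. 1e2 times sqrt(n)
    (the natural scale of the logistic gradient at s = 0).
    """
    from .glm_baseline import glm_reconstruct

    if lambda_grid is None:
        lambda_grid = tuple(np.sqrt(n) * np.logspace(-2, 2, 8))
    if n_heldout is None:
        n_heldout = n
    spec = BasisSpec(*template.shape)
    train_stim = generate_stimuli(n, template.shape, seed=seed)
    train_resp = simulate_responses(template, train_stim, noise, seed=seed + 1)
    recons = {}
    for lam in lambda_grid:
        _, recon = glm_reconstruct(train_stim, train_resp, lam, spec, max_iter=max_iter)
        if np.any(recon.x_hat):
            recons[lam] = recon
    acc = np.full((n_heldout_sets, len(lambda_grid)), np.nan)
    for j in range(n_heldout_sets):
        ho_stim = generate_stimuli(n_heldout, template.shape, seed=seed + 100 + 2 * j)
        ho_resp = simulate_responses(template, ho_stim, noise, seed=seed + 101 + 2 * j)
        for i, lam in enumerate(lambda_grid):
            if lam in recons:
                acc[j, i] = balanced_accuracy(
                    predict_responses(recons[lam], ho_stim), ho_resp
                )
    means = _column_means(acc)
    best = lambda_grid[_argbest_smaller_tie(tuple(lambda_grid), means)]
    return best, dict(zip(lambda_grid, means))
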