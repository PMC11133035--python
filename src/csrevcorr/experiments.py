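"""Seeded simulation studies: method x sample-size x noise grids and
subsample-efficiency comparisons.

These drive the package's main demonstration: simulate a yes/no observer
whose latent template is a 50x50 letter, reconstruct the template with each
estimator, and tabulate reconstruction quality (r^2 against the template)
and held-out response-prediction balanced accuracy across sample sizes,
noise levels and replicates. Every cell draws fresh stimuli under a seed
derived deterministically from the run seed, so identical configs give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisSpec
from .evaluate import balanced_accuracy, predict_responses, template_r2
from .glm_baseline import glm_reconstruct
from .model_select import select_gamma_heldout
from .reconstruct import cs_reconstruct, revcorr_reconstruct
from .response_model import (
    NoiseSpec,
    Template,
    generate_stimuli,
    make_letter_template,
    simulate_responses,
)

__all__ = ["ExperimentConfig", "run_grid", "summarize_grid", "run_subsample_comparison"]

#: held-out trials used to score response prediction per cell
DEFAULT_N_TEST = 2000


def derive_seed(base: int, *parts: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and index parts."""
    ss = np.random.SeedSequence([int(base), *[int(p) for p in parts]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    template_label: str = "S"
    shape: tuple[int, int] = (50, 50)
    sample_sizes: tuple = (1250, 2500, 5000, 10000, 20000)
    sigmas: tuple = (0.0, 25.0, 50.0)
    replicates: int = 10
    methods: tuple = ("revcorr", "cs", "glm")
    gamma: int = 64
    gamma_policy: str = "fixed"  # fixed | searched
    glm_lambda: float | None = None
    seed: int = 0
    n_test: int = DEFAULT_N_TEST
    mode: str = "soft"
    # the noisy study conditions add N(0, sigma) to the decision variable
    noise_mechanism: str = "additive_gaussian"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if any(not (0 <= s <= 100) for s in self.sigmas):
            raise ValueError("sigmas must lie in [0, 100]")
        bad = set(self.methods) - {"revcorr", "cs", "glm"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.gamma_policy not in ("fixed", "searched"):
            raise ValueError("gamma_policy must be 'fixed' or 'searched'")


def _template_for(config: ExperimentConfig) -> Template:
    return make_letter_template(config.template_label, config.shape)


def _fit(method, stimuli, responses, config, spec, gamma, glm_lambda):
    if method == "revcorr":
        return revcorr_reconstruct(stimuli, responses, shape=spec.shape), None
    if method == "cs":
        _, recon = cs_reconstruct(stimuli, responses, gamma, spec, mode=config.mode)
        return recon, gamma
    lam = glm_lambda if glm_lambda is not None else np.sqrt(stimuli.l)
    _, recon = glm_reconstruct(stimuli, responses, lam, spec)
    return recon, None


def run_grid(config: ExperimentConfig, template: Template | None = None) -> pd.DataFrame:
    """One row per method x n x sigma x replicate.

    Each replicate simulates a fresh training set, fits the method, and
    scores r^2 against the template plus balanced accuracy on a freshly
    simulated test set (noisy like the training responses, predicted
    noiselessly). Failures are recorded in the row's ``error`` column and
    the run continues.
    """
    template = template or _template_for(config)
    spec = BasisSpec(*template.shape)
    rows = []
    for ni, n in enumerate(config.sample_sizes):
        for si, sigma in enumerate(config.sigmas):
            noise = NoiseSpec(sigma=sigma, mechanism=config.noise_mechanism) \
                if sigma > 0 else NoiseSpec(0.0)
            if config.gamma_policy == "searched":
                gs = select_gamma_heldout(
                    template, n, noise,
                    seed=derive_seed(config.seed, 9, ni, si), mode=config.mode,
                )
                gamma = gs.best_gamma
            else:
                gamma = config.gamma
            for rep in range(config.replicates):
                cell_seed = derive_seed(config.seed, ni, si, rep)
                stim = generate_stimuli(n, template.shape, seed=cell_seed)
                resp = simulate_responses(template, stim, noise, seed=cell_seed + 1)
                test_stim = generate_stimuli(
                    config.n_test, template.shape, seed=cell_seed + 2
                )
                test_resp = simulate_responses(
                    template, test_stim, noise, seed=cell_seed + 3
                )
                for method in config.methods:
                    row = {
                        "method": method, "n": n, "sigma": sigma,
                        "replicate": rep, "seed": cell_seed,
                        "gamma": None, "r2": np.nan,
                        "balanced_accuracy": np.nan, "error": "",
                    }
                    try:
                        recon, g_used = _fit(
                            method, stim, resp, config, spec, gamma, config.glm_lambda
                        )
                        row["gamma"] = g_used
                        row["r2"] = template_r2(recon, template)
                        row["balanced_accuracy"] = balanced_accuracy(
                            predict_responses(recon, test_stim), test_resp
                        )
                    except (ValueError, FloatingPointError) as exc:
                        row["error"] = str(exc)
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Means and t-interval 95% CIs per method x n x sigma over replicates."""
    def ci_half(x):
        x = np.asarray(x, float)
        x = x[~np.isnan(x)]
        if x.size < 2:
            return np.nan
        return float(
            stats.t.ppf(0.5 + confidence / 2, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
        )

    out = (
        results.groupby(["method", "n", "sigma"], as_index=False)
        .agg(
            r2_mean=("r2", "mean"),
            r2_ci=("r2", ci_half),
            acc_mean=("balanced_accuracy", "mean"),
            acc_ci=("balanced_accuracy", ci_half),
            replicates=("replicate", "count"),
        )
        .sort_values(["method", "sigma", "n"])
        .reset_index(drop=True)
    )
    return out


def run_subsample_comparison(
    template: Template,
    n_full: int = 10000,
    fraction: float = 0.10,
    seed: int = 0,
    gamma: int = 64,
    noise: NoiseSpec = NoiseSpec(),
    mode: str = "soft",
    max_redraws: int = 20,
) -> dict:
    """Reverse correlation on all pairs vs CS on a random fraction of them.

    Reports the r^2 of each reconstruction against the template and their
    ratio. The subsample is drawn uniformly without replacement; a draw
    whose responses are single-class is redrawn with a fresh seed (logged in
    the returned dict).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    spec = BasisSpec(*template.shape)
    stim = generate_stimuli(n_full, template.shape, seed=seed)
    resp = simulate_responses(template, stim, noise, seed=seed + 1)
    rc = revcorr_reconstruct(stim, resp, shape=template.shape)

    n_sub = max(1, int(round(fraction * n_full)))
    rng = np.random.default_rng(seed + 2)
    redraws = 0
    while True:
        idx = rng.choice(n_full, size=n_sub, replace=False)
        sub_resp = resp.subset(idx)
        if np.unique(sub_resp.values).size == 2 or n_sub < 2:
            break
        redraws += 1
        if redraws > max_redraws:
            raise RuntimeError("could not draw a subsample containing both classes")
    _, cs = cs_reconstruct(stim.subset(idx), sub_resp, gamma, spec, mode=mode)

    r2_rc = template_r2(rc, template)
    r2_cs = template_r2(cs, template)
    return {
        "n_full": n_full,
        "n_sub": n_sub,
        "fraction": fraction,
        "gamma": gamma,
        "r2_revcorr_full": r2_rc,
        "r2_cs_subsample": r2_cs,
        "ratio": r2_cs / r2_rc,
        "redraws": redraws,
        "seed": seed,
    }
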