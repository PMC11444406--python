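"""Pseudo-ensemble inference and the NCA quality metric (NQM).

Because cell firing is stochastic, repeated forward passes of one trained
model on the same input differ; averaging them gives a pseudo-ensemble
prediction, and the spread between runs is a label-free reliability
signal.  The NQM score normalizes the total per-pixel standard deviation
across runs by the total mean prediction mass: 0 when all runs agree,
growing as the model becomes unsure — typically on inputs unlike the
training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import dice_coefficient

__all__ = ["EnsembleResult", "NQMScore", "pseudo_ensemble", "nqm", "qa_report"]


@dataclass(frozen=True)
class EnsembleResult:
    mean_prob: np.ndarray
    per_run_probs: np.ndarray
    n_e: int
    pixel_variance: np.ndarray


@dataclass(frozen=True)
class NQMScore:
    value: float
    n_runs: int
    per_pixel_sd: np.ndarray


def pseudo_ensemble(model, image: np.ndarray, n_e: int,
                    rng: np.random.Generator | None = None) -> EnsembleResult:
    """Run the model ``n_e`` times on one image and average the maps.

    Each run shares the input but draws independent firing randomness
    from ``rng``; the ensemble prediction is the arithmetic mean.
    """
    if n_e < 1:
        raise ValueError("ensemble size must be >= 1")
    rng = rng or np.random.default_rng(0)
    runs = np.stack([model._predict_proba_rng(image, rng) for _ in range(n_e)])
    return EnsembleResult(
        mean_prob=runs.mean(axis=0),
        per_run_probs=runs,
        n_e=n_e,
        pixel_variance=runs.var(axis=0),
    )


def nqm(per_run_probs: np.ndarray) -> NQMScore:
    """Relative inter-run deviation of a stack of probability maps (n, H, W).

    Per pixel, mu is the mean over runs and SD the population (divide by
    n) standard deviation; the score is sum(SD) / sum(mu) over pixels —
    zero iff all runs are identical, undefined when the mean prediction
    is identically zero.
    """
    probs = np.asarray(per_run_probs, dtype=float)
    if probs.ndim != 3 or probs.shape[0] < 2:
        raise ValueError("need a stack of at least two probability maps")
    mu = probs.mean(axis=0)
    if (probs == probs[0]).all():  # exact agreement: no rounding residue
        sd = np.zeros_like(mu)
    else:
        sd = probs.std(axis=0)  # population SD
    denom = mu.sum()
    if denom == 0:
        raise ValueError("NQM undefined: mean prediction mass is zero")
    return NQMScore(value=float(sd.sum() / denom), n_runs=probs.shape[0], per_pixel_sd=sd)


def qa_report(model, images, n_e: int = 10, rng: np.random.Generator | None = None,
              nqm_threshold: float = 0.25) -> pd.DataFrame:
    """Per-image NQM and ensemble agreement table.

    For every image: the NQM score, the mean Dice of each run's
    binarized map against the binarized ensemble mean (agreement), and a
    review flag where NQM exceeds ``nqm_threshold``.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for i, image in enumerate(images):
        ens = pseudo_ensemble(model, image, n_e, rng)
        try:
            score = nqm(ens.per_run_probs).value
        except ValueError:
            score = float("nan")
        consensus = (ens.mean_prob >= model.threshold).astype(float)
        agreement = float(
            np.mean(
                [
                    dice_coefficient((run >= model.threshold).astype(float), consensus)
                    for run in ens.per_run_probs
                ]
            )
        )
        rows.append(
            {
                "image": i,
                "nqm": score,
                "ensemble_dice": agreement,
                "flagged": bool(score > nqm_threshold) if np.isfinite(score) else True,
            }
        )
    return pd.DataFrame(rows)
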