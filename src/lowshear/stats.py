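"""Bootstrap uncertainty quantification and signal-to-noise ratios.

The distribution of the TTCF estimator is analytically intractable (the
covariance correction makes the response a nonlinear function of ensemble
means), so confidence intervals come from a nonparametric bootstrap: whole
daughter trajectories are resampled with replacement — never individual
timesteps, which are strongly correlated along a trajectory — and the full
estimator, covariance correction and integral included, is recomputed per
resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

from .ttcf import StressSeriesEnsemble, TTCFEstimate

__all__ = ["BootstrapSummary", "bootstrap_estimate", "attach_bootstrap", "snr"]


@dataclass
class BootstrapSummary:
    """Resample-distribution SE and percentile 95% CI, per timestep."""

    n_resamples: int
    se: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    resample_seed: int


def bootstrap_estimate(ens: StressSeriesEnsemble, estimator,
                       n_resamples: int = 1200,
                       seed: int = 0) -> BootstrapSummary:
    """Bootstrap the given (unfitted) estimator over daughter resamples.

    Each resample draws ``n_daughters`` rows with replacement and refits a
    clone of ``estimator`` (any scikit-learn style estimator exposing
    ``mean_response_`` after ``fit``).  SE is the standard deviation of the
    resample distribution; the CI is the (2.5, 97.5) percentile interval.
    Resample index b uses its own seed derived from (seed, b), so the
    procedure is deterministic and partitionable.

    For a mapped ensemble the resampling unit is the whole quadruplet (the
    four mapped daughters of one mother snapshot): the quadruplet members
    are not independent, and drawing rows singly would destroy the exact
    <P_yx(0)> = 0 cancellation that the mappings provide, grossly inflating
    the apparent uncertainty of the t=0 term.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    x = ens.values
    n = x.shape[0]
    groups = ens.mapped_groups
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    reps = np.empty((n_resamples, x.shape[1]))
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        if groups is None:
            idx = rng.integers(0, n, size=n)
        else:
            ng = groups.shape[0]
            idx = groups[rng.integers(0, ng, size=ng)].ravel()
        est = clone(estimator).fit(x[idx])
        reps[b] = est.mean_response_
    se = reps.std(axis=0, ddof=1)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return BootstrapSummary(n_resamples, se, lo, hi, seed)


def attach_bootstrap(estimate: TTCFEstimate,
                     summary: BootstrapSummary) -> TTCFEstimate:
    """Fill the uncertainty fields of an estimate from a bootstrap summary."""
    estimate.se = summary.se
    estimate.ci95_low = summary.ci95_low
    estimate.ci95_high = summary.ci95_high
    return estimate


def snr(mean_signal: float, se: float) -> float:
    """Signal-to-noise ratio: mean / standard error.

    In cross-method comparisons the numerator is always the TTCF mean (the
    direct average is too noisy to define the signal at low shear rates);
    callers pass the SE of whichever method is being assessed.
    """
    if se <= 0:
        raise ValueError("SNR undefined for non-positive standard error")
    return mean_signal / se
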