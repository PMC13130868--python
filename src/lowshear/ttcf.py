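"""The estimator core: phase-space mappings, direct averaging and the
transient-time correlation function.

Given an ensemble of daughter transients P_yx(t) launched from equilibrium
at t=0, the transient-time correlation function reconstructs the mean
response as

    <P_yx(t)> = <P_yx(0)> - (gammadot*V/kB*T) * Int_0^t <P_yx(0) P_yx(s)> ds

and, in the covariance-corrected form used when no mapping enforces
<P_yx(0)> = 0, the integrand is replaced by
<P_yx(0)P_yx(s)> - <P_yx(0)><P_yx(s)>.  Because the response is linear in
the initial correlation, the signal scales with gammadot while the noise of
the direct ensemble average does not, which is what makes the estimator
usable at arbitrarily low shear rates.

The analysis classes follow the scikit-learn estimator protocol: construct
with parameters, ``fit`` on the (n_daughters, n_steps+1) stress matrix, read
fitted ``*_`` attributes.  They compose with ``sklearn.clone``, which is how
the bootstrap re-runs them on resampled ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .dynamics import run_daughter, run_mother
from .forces import RandomStreamSpec
from .model import (BoxSpec, ForceFieldSpec, PhasePoint, SimulationParams,
                    init_configuration)

__all__ = [
    "StressSeriesEnsemble",
    "TTCFEstimate",
    "apply_mapping",
    "DirectAverage",
    "TransientTimeCorrelation",
    "dav",
    "ttcf",
    "ttcf_trajectorywise",
    "ExperimentResult",
    "run_ttcf_experiment",
]


@dataclass
class StressSeriesEnsemble:
    """Per-daughter P_yx time series on a common grid, with metadata.

    ``values`` has one row per daughter, one column per step (column 0 is
    t=0).  ``mapped_groups``, if present, groups rows into the quadruplets
    generated from one mother snapshot by the four phase-space mappings.
    """

    values: np.ndarray
    time_grid: np.ndarray
    shear_rate: float
    volume: float
    kbt: float
    mapped_groups: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (daughters x steps)")
        if self.values.shape[1] != self.time_grid.shape[0]:
            raise ValueError("time grid length must match the series")
        if self.time_grid[0] != 0.0:
            raise ValueError("time grid must start at 0")
        if self.mapped_groups is not None:
            g = np.asarray(self.mapped_groups)
            if g.ndim != 2 or g.shape[1] != 4:
                raise ValueError("mapped groups must be quadruplets")
            self.mapped_groups = g

    @property
    def n_daughters(self) -> int:
        return self.values.shape[0]


@dataclass
class TTCFEstimate:
    """Mean response with uncertainty bands for one estimation method."""

    method: str
    mean_response: np.ndarray
    se: Optional[np.ndarray] = None
    ci95_low: Optional[np.ndarray] = None
    ci95_high: Optional[np.ndarray] = None
    impose_zero_initial: bool = False


# --------------------------------------------------------------------------
# phase-space mappings

def apply_mapping(state: PhasePoint, map_id: int) -> PhasePoint:
    """One of the four planar-shear phase-space mappings.

    0: identity; 1: momentum reversal (-px,-py,-pz); 2: y-reflection with
    (px,-py,pz); 3: y-reflection with (-px,py,-pz).  For conservative force
    fields these satisfy P_yx(0) = P'_yx(0) = -P''_yx(0) = -P'''_yx(0), so
    the quadruplet mean of P_yx(0) vanishes identically.

    The y-reflection negates the coordinate (y -> -y) without re-wrapping
    into [0, Ly): negation is exact in floating point, so the quadruplet
    cancellation holds to the last bit, and minimum-image evaluation is
    indifferent to the wrap.
    """
    if map_id == 0:
        return state.copy()
    new = state.copy()
    if map_id == 1:
        new.momenta *= -1.0
    elif map_id == 2:
        new.positions[:, 1] *= -1.0
        new.momenta[:, 1] *= -1.0
    elif map_id == 3:
        new.positions[:, 1] *= -1.0
        new.momenta[:, 0] *= -1.0
        new.momenta[:, 2] *= -1.0
    else:
        raise ValueError("map_id must be 0, 1, 2 or 3")
    return new


# --------------------------------------------------------------------------
# estimators

class DirectAverage(BaseEstimator):
    """Plain ensemble average of the daughter responses (DAV).

    Fitted attributes: ``mean_response_``, ``se_`` (sample sd / sqrt(n)),
    ``ci95_low_``/``ci95_high_`` from the normal approximation.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        n = X.shape[0]
        self.n_daughters_ = n
        self.mean_response_ = X.mean(axis=0)
        self.se_ = X.std(axis=0, ddof=1) / np.sqrt(n)
        z = norm.ppf(0.5 + self.ci_level / 2.0)
        self.ci95_low_ = self.mean_response_ - z * self.se_
        self.ci95_high_ = self.mean_response_ + z * self.se_
        return self


class TransientTimeCorrelation(BaseEstimator):
    """Transient-time correlation function estimator of <P_yx(t)>.

    Parameters
    ----------
    shear_rate, volume, kbt
        Metadata of the transient ensemble (reduced units).
    dt
        Spacing of the uniform time grid; the correlation integral is
        evaluated with the trapezoidal rule on that grid.
    corrected
        Subtract <P_yx(0)><P_yx(s)> from the integrand (the covariance
        form); the right choice when mappings do not cancel <P_yx(0)>.
    impose_zero_initial
        Replace the additive <P_yx(0)> term with its exact equilibrium
        value 0.  Legal only because <P_yx> vanishes in equilibrium; the
        covariance subtraction still uses the empirical mean.

    Fitted attribute ``mean_response_`` holds <P_yx(t)>; standard errors are
    attached by the bootstrap (see `lowshear.stats`), not computed here.
    """

    def __init__(self, shear_rate: float = 0.0, volume: float = 1.0,
                 kbt: float = 1.0, dt: float = 0.01, corrected: bool = True,
                 impose_zero_initial: bool = False):
        self.shear_rate = shear_rate
        self.volume = volume
        self.kbt = kbt
        self.dt = dt
        self.corrected = corrected
        self.impose_zero_initial = impose_zero_initial

    def fit(self, X, y=None):
        if self.kbt <= 0:
            raise ValueError("kbt must be positive")
        X = check_array(X, ensure_min_samples=2)
        t = self.dt * np.arange(X.shape[1])
        p0 = X[:, 0]
        corr = (p0[:, None] * X).mean(axis=0)
        m0 = p0.mean()
        if self.corrected:
            integrand = corr - m0 * X.mean(axis=0)
        else:
            integrand = corr
        integral = cumulative_trapezoid(integrand, t, initial=0.0)
        base = 0.0 if self.impose_zero_initial else m0
        pref = self.shear_rate * self.volume / self.kbt
        self.time_grid_ = t
        self.mean_response_ = base - pref * integral
        self.n_daughters_ = X.shape[0]
        return self


def dav(ens: StressSeriesEnsemble, ci_level: float = 0.95) -> TTCFEstimate:
    """Direct-averaging estimate with analytic normal-approximation CI."""
    est = DirectAverage(ci_level=ci_level).fit(ens.values)
    return TTCFEstimate("DAV", est.mean_response_, est.se_,
                        est.ci95_low_, est.ci95_high_)


def ttcf(ens: StressSeriesEnsemble, corrected: bool = True,
         impose_zero_initial: bool = False) -> TTCFEstimate:
    """TTCF estimate of <P_yx(t)>; uncertainty left for the bootstrap."""
    dt = float(ens.time_grid[1] - ens.time_grid[0]) if len(ens.time_grid) > 1 \
        else 1.0
    est = TransientTimeCorrelation(
        shear_rate=ens.shear_rate, volume=ens.volume, kbt=ens.kbt, dt=dt,
        corrected=corrected, impose_zero_initial=impose_zero_initial,
    ).fit(ens.values)
    method = "TTCF_MAPPED" if ens.mapped_groups is not None else "TTCF_UNMAPPED"
    return TTCFEstimate(method, est.mean_response_,
                        impose_zero_initial=impose_zero_initial)


def ttcf_trajectorywise(ens: StressSeriesEnsemble, corrected: bool = True,
                        impose_zero_initial: bool = False) -> np.ndarray:
    """TTCF with the integral taken inside the ensemble mean.

    Mathematically identical to `ttcf` because ensemble averages and
    integrals are linear operators; kept as an independent evaluation route
    for the machine-precision linearity check.
    """
    x = ens.values
    t = ens.time_grid
    p0 = x[:, 0]
    per_traj = cumulative_trapezoid(x, t, axis=1, initial=0.0)
    mean_int = (p0[:, None] * per_traj).mean(axis=0)
    if corrected:
        mean_int = mean_int - p0.mean() * per_traj.mean(axis=0)
    base = 0.0 if impose_zero_initial else p0.mean()
    return base - (ens.shear_rate * ens.volume / ens.kbt) * mean_int


# --------------------------------------------------------------------------
# orchestration

@dataclass
class ExperimentResult:
    """Raw ensemble plus the per-method estimates of one experiment."""

    ensemble: StressSeriesEnsemble
    estimates: Dict[str, TTCFEstimate]
    seed: int


def _seed_streams(seed: int):
    s = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint32)
    return [int(x & 0x7FFFFFFF) for x in s]


def run_ttcf_experiment(params: SimulationParams, ff: ForceFieldSpec,
                        seed: int, *, density: float, box: BoxSpec,
                        lattice: str = "sc",
                        corrected: bool = True) -> ExperimentResult:
    """Mother -> (mappings x4) -> daughters -> DAV + TTCF estimates.

    The raw per-daughter series are retained in the returned ensemble (the
    unmapped approach needs the variable of interest at every step of every
    trajectory).  All randomness derives from ``seed``; a rerun with the
    same arguments is bit-identical.  Bootstrap uncertainties are attached
    separately via `lowshear.stats.bootstrap_estimate`.
    """
    init_seed, mother_seed, daughter_seed = _seed_streams(seed)
    state0 = init_configuration(density, box, ff.temperature, init_seed,
                                lattice=lattice, kB=ff.kB)
    mother_rng = RandomStreamSpec(mother_seed)
    stride = params.daughter_length + 1
    rows = []
    d_idx = 0
    for snap in run_mother(state0, ff, params, mother_rng):
        starts = ([apply_mapping(snap, m) for m in range(4)]
                  if params.use_mappings else [snap])
        for g0 in starts:
            d_rng = RandomStreamSpec(daughter_seed, d_idx * stride)
            series = run_daughter(g0, ff, params, d_rng)
            rows.append(series.pyx)
            d_idx += 1
    values = np.asarray(rows)
    groups = (np.arange(values.shape[0]).reshape(-1, 4)
              if params.use_mappings else None)
    t = params.timestep * np.arange(stride)
    ens = StressSeriesEnsemble(values, t, params.shear_rate,
                               box.volume, ff.kB * ff.temperature,
                               mapped_groups=groups)
    estimates = {
        "DAV": dav(ens),
        "TTCF": ttcf(ens, corrected=corrected,
                     impose_zero_initial=params.impose_zero_initial),
    }
    return ExperimentResult(ens, estimates, seed)
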