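"""Synthetic chronoamperograms, calibration data and surface-kinetics
trajectories.

No raw electrode traces are publicly deposited for this system, so the
package ships a generator that reproduces the statistical structure the
analysis assumes: Cottrellian t^(-1/2) decays, two-phase exponential decays
with the published rate constants, linear steady-state calibration lines,
and trajectories of the adsorbed-glucose surface kinetics scheme

    Au2O + glucose --k1--> [GLU]*ads --k2--> gluconolactone + 2 AuOH

read as a surface-coverage balance: second-order (bilinear) formation of the
adsorbed intermediate on free sites, first-order decay,

    d(theta)/dt = k1 c (1 - theta) - k2 theta,        i(t) = n F A_site k2 theta.

Under constant excess glucose this linear ODE has the closed-form relaxation
theta(t) = theta_ss (1 - exp(-(k1 c + k2) t)) with
theta_ss = k1 c / (k1 c + k2), which doubles as the integrator's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .fitting import Chronoamperogram
from .models import (
    CONSTANTS,
    BiexpParams,
    CottrellParams,
    biexp_current,
    cottrell_current,
)

__all__ = [
    "NoiseSpec",
    "KineticTrajectory",
    "CHRONO_PARAMS",
    "CALIBRATION_PARAMS",
    "default_time_grid",
    "generate_chronoamperogram",
    "generate_calibration_dataset",
    "theta_constant_glucose",
    "simulate_surface_kinetics",
]

# ---------------------------------------------------------------------------
# Published transient and calibration parameters for the four gold
# nanostructures (10 mM glucose in 0.1 M NaOH). These are the generating
# parameter sets for all synthetic fixtures.

#: Transient model per electrode: either a Cottrell amplitude (A s^1/2) or a
#: full two-phase exponential decay parameter set (amplitudes in A, rates s^-1).
CHRONO_PARAMS: dict[str, Union[CottrellParams, BiexpParams]] = {
    "nanoporous": BiexpParams(a1=6.74e-4, a2=0.00339, a3=0.00333, k1=0.363, k2=0.0625),
    "thermal_8nm_300C": CottrellParams(B0=0.00633),
    "thermal_17nm_400C": BiexpParams(a1=3.58e-4, a2=0.00265, a3=0.00119, k1=0.425, k2=0.0586),
    "laser": CottrellParams(B0=0.00152),
}

#: Steady-state calibration lines j = a + b x (j in uA cm^-2, x in mM),
#: valid over the physiological 2.5-10 mM range.
CALIBRATION_PARAMS: dict[str, tuple[float, float]] = {
    "nanoporous": (95.49, 55.69),
    "thermal_8nm_300C": (9.48, 32.74),
    "thermal_17nm_400C": (17.54, 27.29),
    "laser": (30.60, 15.38),
}

#: Concentrations (mM) at which the calibration lines were established.
CALIBRATION_CONCENTRATIONS_MM = (2.5, 5.0, 7.5, 10.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for generated data.

    kind ``none`` | ``additive_gaussian`` (sigma in output units) |
    ``proportional_gaussian`` (sigma as a fraction of the signal).
    """

    kind: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive_gaussian", "proportional_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def apply(self, signal: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0.0:
            return signal.copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.standard_normal(signal.shape)
        if self.kind == "additive_gaussian":
            return signal + self.sigma * eps
        return signal * (1.0 + self.sigma * eps)


@dataclass(frozen=True)
class KineticTrajectory:
    """Surface-kinetics trajectory: coverage theta(t) of the adsorbed
    intermediate and the resulting decay current."""

    t: np.ndarray
    theta: np.ndarray
    current: np.ndarray


def default_time_grid(t_min: float = 0.1, t_max: float = 150.0, dt: float = 0.1) -> np.ndarray:
    """Acquisition grid matching the chronoamperometric window (0.1-150 s)."""
    n = int(round((t_max - t_min) / dt)) + 1
    return t_min + dt * np.arange(n)


def generate_chronoamperogram(
    model_id: str,
    params: Union[CottrellParams, BiexpParams],
    t_grid: Optional[np.ndarray] = None,
    noise: NoiseSpec = NoiseSpec(),
) -> Chronoamperogram:
    """Synthesize a current-time trace from a named transient model.

    The noiseless output evaluated at t equals the corresponding model
    function to machine precision; metadata records the generator, its
    parameters and the noise seed.
    """
    t = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if model_id == "cottrell":
        if not isinstance(params, CottrellParams):
            raise TypeError("cottrell generation requires CottrellParams")
        clean = np.asarray(cottrell_current(t, params))
    elif model_id == "biexp":
        if not isinstance(params, BiexpParams):
            raise TypeError("biexp generation requires BiexpParams")
        clean = np.asarray(biexp_current(t, params))
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    i = noise.apply(clean)
    meta = {
        "generator": model_id,
        "params": {k: float(v) for k, v in vars(params).items()},
        "noise": {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed},
        "synthetic": True,
    }
    return Chronoamperogram(t=t, i=i, meta=meta)


def generate_calibration_dataset(
    a: float,
    b: float,
    concentrations: Sequence[float] = CALIBRATION_CONCENTRATIONS_MM,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Steady-state calibration points j = a + b x (+ noise).

    a: intercept (uA cm^-2); b: sensitivity (uA cm^-2 mM^-1); concentrations
    in mM. Returns columns ``conc_mM``, ``j_uA_cm2``.
    """
    x = np.asarray(list(concentrations), dtype=float)
    if x.size == 0:
        raise ValueError("concentrations must be non-empty")
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    y = noise.apply(a + b * x)
    return pd.DataFrame({"conc_mM": x, "j_uA_cm2": y})


def theta_constant_glucose(t: np.ndarray, k1: float, k2: float, c: float) -> np.ndarray:
    """Closed-form coverage under constant glucose:
    theta(t) = theta_ss (1 - e^(-(k1 c + k2) t)), theta_ss = k1 c/(k1 c + k2)."""
    t = np.asarray(t, dtype=float)
    rate = k1 * c + k2
    if rate == 0.0:
        return np.zeros_like(t)
    theta_ss = k1 * c / rate
    return theta_ss * (1.0 - np.exp(-rate * t))


def simulate_surface_kinetics(
    k1: float,
    k2: float,
    c0: float,
    site_total: float,
    t_grid: np.ndarray,
    n_electrons: int = 2,
    area: float = 1e-4,
    glucose_cutoff_time: Optional[float] = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> KineticTrajectory:
    """Integrate the adsorbed-intermediate coverage balance.

    d(theta)/dt = k1 c(t) (1 - theta) - k2 theta, theta(0) = 0, with
    c(t) = c0 (dropped to 0 after ``glucose_cutoff_time`` if given, to probe
    the pure first-order decay whose log-slope is -k2). The Faradaic current
    of the two-electron decay step is i = n F A site_total k2 theta.

    k1 is the effective adsorption constant (s^-1 per mol m^-3), k2 the
    intermediate decay constant (s^-1), site_total the active-site density
    (mol m^-2) over electrode area ``area`` (m^2).
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be > 0")
    if c0 < 0:
        raise ValueError("glucose concentration must be >= 0")
    t = np.asarray(t_grid, dtype=float)

    def conc(ti: float) -> float:
        if glucose_cutoff_time is not None and ti >= glucose_cutoff_time:
            return 0.0
        return c0

    def rhs(ti, y):
        return [k1 * conc(ti) * (1.0 - y[0]) - k2 * y[0]]

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        [0.0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"kinetics integration failed: {sol.message}")
    theta = np.clip(sol.y[0], 0.0, 1.0)
    current = n_electrons * CONSTANTS["F"] * area * site_total * k2 * theta
    return KineticTrajectory(t=t, theta=theta, current=current)
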