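"""Closed-form current-time and current-potential models for glucose
electro-oxidation at nanostructured gold electrodes.

Every function here is a pure evaluator: planar semi-infinite diffusion
(Cottrell), convergent diffusion to a hemisphere or microdisk (Shoup-Szabo),
microdisk-array transients, the two-phase exponential decay used when surface
kinetics rather than diffusion controls the transient, and the anodic
Butler-Volmer current density.

Units are SI throughout (s, A, m, mol m^-3). Presentation units used in the
amperometric-sensing literature (mM, uA cm^-2) are handled by the helpers at
the bottom of the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Union

import numpy as np

__all__ = [
    "CONSTANTS",
    "AnalyteSpec",
    "ElectrodeSpec",
    "CottrellParams",
    "BiexpParams",
    "ButlerVolmerParams",
    "cottrell_current",
    "cottrell_amplitude",
    "hemispherical_limit_current",
    "shoup_szabo_f",
    "tau_of",
    "microdisk_current",
    "microdisk_array_current",
    "biexp_current",
    "butler_volmer_density",
    "diffusion_length",
    "mM_to_mol_per_m3",
    "mol_per_m3_to_mM",
    "uA_per_cm2_to_A_per_m2",
    "A_per_m2_to_uA_per_cm2",
]

ArrayLike = Union[float, np.ndarray]

#: Physical constants (read-only): Faraday constant F (C mol^-1) and molar
#: gas constant R (J mol^-1 K^-1).
CONSTANTS = MappingProxyType({"F": 96485.33, "R": 8.314})

_F = CONSTANTS["F"]
_R = CONSTANTS["R"]

#: Electrode labels used across the package for the four gold nanostructures:
#: electrochemically etched nanoporous film, thermally dewetted 8 nm / 300 C
#: and 17 nm / 400 C layers, and the laser-dewetted layer.
ELECTRODE_LABELS = ("nanoporous", "thermal_8nm_300C", "thermal_17nm_400C", "laser")


@dataclass(frozen=True)
class AnalyteSpec:
    """Redox analyte: electron count n, diffusion coefficient D (m^2 s^-1),
    bulk concentration c (mol m^-3)."""

    n: int
    D: float
    c: float
    name: str = "glucose"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"electron count n must be >= 1, got {self.n}")
        if self.D <= 0:
            raise ValueError(f"diffusion coefficient D must be > 0, got {self.D}")
        if self.c < 0:
            raise ValueError(f"bulk concentration c must be >= 0, got {self.c}")


#: Glucose in aqueous solution at room temperature: two-electron oxidation to
#: gluconolactone, D = 6.7e-10 m^2 s^-1, at the 10 mM level used for the
#: chronoamperometric transients.
GLUCOSE_10MM = AnalyteSpec(n=2, D=6.7e-10, c=10.0, name="glucose")


@dataclass(frozen=True)
class ElectrodeSpec:
    """Nanostructured electrode: electroactive area A (m^2), characteristic
    feature radius r (m), number of active disks N."""

    A: float
    r: float
    N: int = 1
    label: str = "nanoporous"

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"area A must be > 0, got {self.A}")
        if self.r <= 0:
            raise ValueError(f"feature radius r must be > 0, got {self.r}")
        if self.N < 1:
            raise ValueError(f"disk count N must be >= 1, got {self.N}")


@dataclass(frozen=True)
class CottrellParams:
    """Lumped Cottrell amplitude B0 = n F A c sqrt(D/pi), units A s^(1/2).

    B0 = 0 is admitted only as the degenerate zero-concentration case.
    """

    B0: float

    def __post_init__(self) -> None:
        if self.B0 < 0:
            raise ValueError(f"Cottrell amplitude B0 must be >= 0, got {self.B0}")


@dataclass(frozen=True)
class BiexpParams:
    """Two-phase exponential decay I = a1 + a2 e^(-k1 t) + a3 e^(-k2 t).

    a1 is the steady-state current (A); a2, a3 are the fast/slow transient
    amplitudes; k1 > k2 > 0 are the fast and slow rate constants (s^-1),
    interpreted as glucose adsorption onto the oxidized gold surface followed
    by first-order decay of the adsorbed intermediate to gluconolactone.
    """

    a1: float
    a2: float
    a3: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.a1 < 0:
            raise ValueError(f"steady-state amplitude a1 must be >= 0, got {self.a1}")
        if not (self.k1 > self.k2 > 0):
            raise ValueError(
                f"rate constants must satisfy k1 > k2 > 0, got k1={self.k1}, k2={self.k2}"
            )


@dataclass(frozen=True)
class ButlerVolmerParams:
    """Anodic Butler-Volmer parameters: heterogeneous rate constant k0
    (m s^-1), anodic charge-transfer coefficient alpha_a, formal potential
    Ef0 (V), temperature T (K)."""

    k0: float
    alpha_a: float
    Ef0: float
    T: float = 295.15

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"rate constant k0 must be > 0, got {self.k0}")
        if not (0 < self.alpha_a <= 1):
            raise ValueError(f"alpha_a must be in (0, 1], got {self.alpha_a}")
        if self.T <= 0:
            raise ValueError(f"temperature T must be > 0, got {self.T}")


def _require_positive(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be > 0 (singular or undefined otherwise)")
    return arr


def cottrell_current(t: ArrayLike, p: CottrellParams) -> ArrayLike:
    """Planar semi-infinite diffusion transient I(t) = B0 / sqrt(t).

    Valid for t > 0 only; the t = 0 singularity is rejected.
    """
    t_arr = _require_positive(t, "time t")
    out = p.B0 / np.sqrt(t_arr)
    return out if isinstance(t, np.ndarray) else float(out)


def cottrell_amplitude(analyte: AnalyteSpec, electrode: ElectrodeSpec) -> CottrellParams:
    """Lump n, F, A, c, D into the Cottrell amplitude B0 = n F A c sqrt(D/pi)."""
    b0 = analyte.n * _F * electrode.A * analyte.c * np.sqrt(analyte.D / np.pi)
    return CottrellParams(B0=float(b0))


def hemispherical_limit_current(analyte: AnalyteSpec, r: float) -> float:
    """Steady-state limit current at a hemispherical electrode of radius r:
    I = 2 pi r n F D c."""
    _require_positive(r, "radius r")
    return float(2.0 * np.pi * r * analyte.n * _F * analyte.D * analyte.c)


def shoup_szabo_f(tau: ArrayLike) -> ArrayLike:
    """Empirical microdisk transient shape function

        f(tau) = 0.7854 + 0.8862 tau^(-1/2) + 0.2146 exp(-0.7823 tau^(-1/2))

    interpolating between the Cottrellian short-time transient
    (f ~ 0.8862 tau^(-1/2) as tau -> 0) and the convergent-diffusion steady
    state (f -> 1 as tau -> inf).
    """
    tau_arr = _require_positive(tau, "dimensionless time tau")
    inv_sqrt = tau_arr ** -0.5
    out = 0.7854 + 0.8862 * inv_sqrt + 0.2146 * np.exp(-0.7823 * inv_sqrt)
    return out if isinstance(tau, np.ndarray) else float(out)


def tau_of(t: ArrayLike, analyte: AnalyteSpec, r: float) -> ArrayLike:
    """Dimensionless time tau = 4 D t / r^2: squared ratio of the diffusion
    length to the disk radius."""
    _require_positive(r, "radius r")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = 4.0 * analyte.D * t_arr / r**2
    return out if isinstance(t, np.ndarray) else float(out)


def microdisk_current(t: ArrayLike, analyte: AnalyteSpec, r: float) -> ArrayLike:
    """Single-microdisk chronoamperometric current I = 4 n F r D c f(tau);
    approaches the steady state 4 n F r D c as t -> inf."""
    prefactor = 4.0 * analyte.n * _F * r * analyte.D * analyte.c
    return prefactor * shoup_szabo_f(tau_of(t, analyte, r))


def microdisk_array_current(
    t: ArrayLike, analyte: AnalyteSpec, electrode: ElectrodeSpec
) -> ArrayLike:
    """Microdisk-array transient I = N 4 n F A D c / (pi r) f(tau) for N
    disks of average radius r within total electroactive area A."""
    prefactor = (
        electrode.N
        * 4.0
        * analyte.n
        * _F
        * electrode.A
        * analyte.D
        * analyte.c
        / (np.pi * electrode.r)
    )
    return prefactor * shoup_szabo_f(tau_of(t, analyte, electrode.r))


def biexp_current(t: ArrayLike, p: BiexpParams) -> ArrayLike:
    """Two-phase exponential decay I(t) = a1 + a2 e^(-k1 t) + a3 e^(-k2 t).

    I(0) = a1 + a2 + a3; I -> a1 (the steady-state current) as t -> inf.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = p.a1 + p.a2 * np.exp(-p.k1 * t_arr) + p.a3 * np.exp(-p.k2 * t_arr)
    return out if isinstance(t, np.ndarray) else float(out)


def butler_volmer_density(
    E: ArrayLike, analyte: AnalyteSpec, p: ButlerVolmerParams
) -> ArrayLike:
    """Anodic branch of the Butler-Volmer relation,

        J(E) = k0 F c exp(alpha_a F / (R T) (E - Ef0)),

    the current density (A m^-2) of the two-electron glucose oxidation peak
    as a function of electrode potential. log J is affine in E with slope
    alpha_a F / (R T)."""
    E_arr = np.asarray(E, dtype=float)
    out = (
        p.k0
        * _F
        * analyte.c
        * np.exp(p.alpha_a * _F / (_R * p.T) * (E_arr - p.Ef0))
    )
    return out if isinstance(E, np.ndarray) else float(out)


def diffusion_length(t: ArrayLike, analyte: AnalyteSpec) -> ArrayLike:
    """Root-mean-square displacement (diffusion length) delta = sqrt(2 D t)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = np.sqrt(2.0 * analyte.D * t_arr)
    return out if isinstance(t, np.ndarray) else float(out)


# ---------------------------------------------------------------------------
# Unit helpers: mM <-> mol m^-3 are numerically equal; 1 uA cm^-2 = 1e-2 A m^-2.

def mM_to_mol_per_m3(x: ArrayLike) -> ArrayLike:
    return x * 1.0


def mol_per_m3_to_mM(x: ArrayLike) -> ArrayLike:
    return x * 1.0


def uA_per_cm2_to_A_per_m2(x: ArrayLike) -> ArrayLike:
    return x * 1e-2


def A_per_m2_to_uA_per_cm2(x: ArrayLike) -> ArrayLike:
    return x * 1e2
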