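"""Nonlinear least-squares estimation of chronoamperometric model parameters.

Two transient models are fitted:

* ``cottrell`` — I(t) = B0 / sqrt(t), the diffusion-limited decay. Because the
  model is linear in B0, the exact least-squares solution is available in
  closed form (``cottrell_closed_form``); it initializes — and in tests
  cross-checks — the iterative fit.
* ``biexp``   — I(t) = a1 + a2 e^(-k1 t) + a3 e^(-k2 t), the surface-kinetics
  transient. Initialization uses curve peeling: the slow phase is estimated
  from the log-linear tail after subtracting the steady state, then the fast
  phase from the early-time remainder. The ordering k1 > k2 > 0 is enforced
  by reparametrizing k1 = k2 + dk with dk >= 0.

The module also classifies the diffusion regime by comparing the electrode's
characteristic feature size with the analyte diffusion length sqrt(2 D t):
features much smaller than the diffusion length see an effectively planar
concentration field (Cottrellian decay), while features comparable to it
retain a kinetically controlled transient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from lmfit import Model, Parameters

from .models import (
    AnalyteSpec,
    BiexpParams,
    CottrellParams,
    ElectrodeSpec,
    diffusion_length,
)

__all__ = [
    "Chronoamperogram",
    "FitResult",
    "RegimeAssessment",
    "adjusted_r2",
    "cottrell_closed_form",
    "fit_cottrell",
    "fit_biexp",
    "classify_regime",
]

#: Relative SSR convergence tolerance and iteration cap for the NLS fits.
FIT_XTOL = 1e-10
FIT_MAX_ITER = 500


@dataclass(frozen=True)
class Chronoamperogram:
    """Sampled current-time trace.

    t must be strictly increasing with t[0] > 0 (the potential step at t = 0
    is singular for the diffusive models); at least 5 points are required.
    """

    t: np.ndarray
    i: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        i = np.asarray(self.i, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "i", i)
        if t.ndim != 1 or i.ndim != 1 or len(t) != len(i):
            raise ValueError("t and i must be 1-D arrays of equal length")
        if len(t) < 5:
            raise ValueError(f"need at least 5 samples, got {len(t)}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(i))):
            raise ValueError("non-finite values in trace")
        if t[0] <= 0:
            raise ValueError(
                f"t[0] = {t[0]}: times must be > 0 (current is singular at the step)"
            )
        if np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 2  # 1-based, names the later sample
            raise ValueError(f"time axis not strictly increasing at row {row}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with standard errors and adjusted R^2."""

    model_id: str
    params: dict
    stderr: dict
    adj_r2: float
    residuals: np.ndarray
    converged: bool
    n_obs: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in ("cottrell", "biexp"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.converged and not all(
            np.isfinite(v) for v in self.params.values()
        ):
            raise ValueError("converged fit must have finite parameters")


@dataclass(frozen=True)
class RegimeAssessment:
    """Diffusion-regime call for an electrode/analyte/time combination.

    ratio = feature_size / delta_bar; the regime is ``cottrellian`` when the
    ratio is at most the configured threshold, ``kinetic_transient``
    otherwise.
    """

    delta_bar: float
    feature_size: float
    ratio: float
    regime: str
    threshold: float
    recommended_model: str


def adjusted_r2(residuals: np.ndarray, observations: np.ndarray, n_params: int) -> float:
    """Adjusted coefficient of determination
    1 - (1 - R^2) (n - 1) / (n - p - 1)."""
    residuals = np.asarray(residuals, dtype=float)
    y = np.asarray(observations, dtype=float)
    n = len(y)
    if n <= n_params + 1:
        raise ValueError(
            f"need more than n_params + 1 = {n_params + 1} observations, got {n}"
        )
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant data: R^2 undefined; 1 iff fit is exact
        r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def cottrell_closed_form(curve: Chronoamperogram) -> float:
    """Exact least-squares Cottrell amplitude.

    For I = B0 / sqrt(t) the SSR is quadratic in B0 and is minimized by
    B0 = sum(i / sqrt(t)) / sum(1 / t). Serves as initializer and as an
    independent oracle for the iterative path.
    """
    w = 1.0 / np.sqrt(curve.t)
    return float(np.dot(curve.i, w) / np.dot(w, w))


def _cottrell_model(t, B0):
    return B0 / np.sqrt(t)


def fit_cottrell(
    curve: Chronoamperogram, init: Optional[CottrellParams] = None
) -> FitResult:
    """Fit the one-parameter Cottrell decay I = B0 / sqrt(t) by NLS.

    Starts from the closed-form solution unless an explicit ``init`` is
    given (e.g. to exercise convergence from a perturbed start).
    """
    b0_init = init.B0 if init is not None else cottrell_closed_form(curve)
    if not np.isfinite(b0_init) or b0_init == 0.0:
        return FitResult(
            model_id="cottrell",
            params={"B0": np.nan},
            stderr={"B0": np.nan},
            adj_r2=-np.inf,
            residuals=curve.i.copy(),
            converged=False,
            n_obs=len(curve),
            diagnostics={"reason": "degenerate trace (zero or non-finite currents)"},
        )

    model = Model(_cottrell_model)
    params = model.make_params(B0=b0_init)
    out = model.fit(
        curve.i, params, t=curve.t, method="leastsq",
        max_nfev=FIT_MAX_ITER * 2,
        fit_kws={"xtol": FIT_XTOL, "ftol": FIT_XTOL},
    )
    resid = curve.i - out.best_fit
    stderr = out.params["B0"].stderr
    return FitResult(
        model_id="cottrell",
        params={"B0": float(out.params["B0"].value)},
        stderr={"B0": float(stderr) if stderr is not None else 0.0},
        adj_r2=adjusted_r2(resid, curve.i, 1),
        residuals=resid,
        converged=bool(out.success),
        n_obs=len(curve),
        diagnostics={"closed_form_B0": b0_init, "nfev": out.nfev},
    )


def _peel_initial_guess(curve: Chronoamperogram) -> tuple[float, float, float, float, float]:
    """Curve-peeling initializer for the biexponential decay.

    Steady state from the last 10% of points; slow rate k2 from a log-linear
    fit of (i - i_inf) over the tail; fast rate k1 from the early-time
    remainder after subtracting the slow phase.
    """
    t, i = curve.t, curve.i
    n = len(t)
    n_tail = max(n // 10, 3)
    a1 = float(np.mean(i[-n_tail:]))

    excess = i - a1
    floor = max(np.max(np.abs(excess)) * 1e-12, 1e-300)
    # slow phase: mid-to-late window where the fast phase has died out
    lo, hi = n // 3, max(2 * n // 3, n // 3 + 3)
    mask = excess[lo:hi] > floor
    if mask.sum() >= 3:
        slope, logc = np.polyfit(t[lo:hi][mask], np.log(excess[lo:hi][mask]), 1)
        k2 = max(-slope, 1e-6)
        a3 = float(np.exp(logc))
    else:
        k2, a3 = 1.0 / max(t[-1], 1.0), max(float(excess[0]) / 2, floor)

    # fast phase: what remains at early times
    remainder = excess - a3 * np.exp(-k2 * t)
    n_head = max(n // 10, 3)
    mask = remainder[:n_head] > floor
    if mask.sum() >= 3:
        slope, logc = np.polyfit(t[:n_head][mask], np.log(remainder[:n_head][mask]), 1)
        k1 = max(-slope, k2 * 2)
        a2 = float(np.exp(logc))
    else:
        k1, a2 = k2 * 10.0, max(float(remainder[0]), floor)

    if k1 <= k2:
        k1 = k2 * 5.0
    return a1, a2, a3, k1, k2


def _biexp_model(t, a1, a2, a3, k2, dk):
    return a1 + a2 * np.exp(-(k2 + dk) * t) + a3 * np.exp(-k2 * t)


def fit_biexp(
    curve: Chronoamperogram,
    init: Optional[Union[BiexpParams, dict]] = None,
) -> FitResult:
    """Fit the two-phase exponential decay by constrained NLS.

    The constraint k1 > k2 > 0 is built into the parametrization
    k1 = k2 + dk, k2 > 0, dk >= 0; a1 >= 0. ``init`` may be a
    ``BiexpParams`` or a plain mapping with keys a1, a2, a3, k1, k2; a
    label-switched start (k1 < k2) is re-ordered to the canonical k1 > k2,
    with the amplitudes following their rates.
    """
    if len(curve) < 6:
        raise ValueError("biexponential fit needs at least 6 points")

    if init is not None:
        d = vars(init) if isinstance(init, BiexpParams) else dict(init)
        a1, a2, a3 = d["a1"], d["a2"], d["a3"]
        k_hi, k_lo = max(d["k1"], d["k2"]), min(d["k1"], d["k2"])
        if d["k1"] < d["k2"]:  # swapped start: amplitudes follow their rates
            a2, a3 = a3, a2
        guess = (a1, a2, a3, k_hi, k_lo)
    else:
        guess = _peel_initial_guess(curve)

    a1_0, a2_0, a3_0, k1_0, k2_0 = guess
    model = Model(_biexp_model)
    params = Parameters()
    params.add("a1", value=max(a1_0, 0.0), min=0.0)
    params.add("a2", value=a2_0)
    params.add("a3", value=a3_0)
    params.add("k2", value=max(k2_0, 1e-9), min=1e-12)
    params.add("dk", value=max(k1_0 - k2_0, 1e-9), min=0.0)

    out = model.fit(
        curve.i, params, t=curve.t, method="leastsq",
        max_nfev=FIT_MAX_ITER * 6,
        fit_kws={"xtol": FIT_XTOL, "ftol": FIT_XTOL},
    )
    resid = curve.i - out.best_fit

    k2_hat = float(out.params["k2"].value)
    dk_hat = float(out.params["dk"].value)
    p_hat = {
        "a1": float(out.params["a1"].value),
        "a2": float(out.params["a2"].value),
        "a3": float(out.params["a3"].value),
        "k1": k2_hat + dk_hat,
        "k2": k2_hat,
    }

    def _se(name):
        se = out.params[name].stderr
        return float(se) if se is not None else 0.0

    # var(k1) = var(k2) + var(dk) + 2 cov; covariance from lmfit if available
    se_k2, se_dk = _se("k2"), _se("dk")
    cov_k2_dk = 0.0
    if out.covar is not None:
        names = [p for p in out.params if out.params[p].vary]
        if "k2" in names and "dk" in names:
            cov_k2_dk = float(out.covar[names.index("k2"), names.index("dk")])
    se_k1 = float(np.sqrt(max(se_k2**2 + se_dk**2 + 2 * cov_k2_dk, 0.0)))

    diagnostics: dict = {"init": guess, "nfev": out.nfev}
    if dk_hat < 1e-6 * max(k2_hat, 1e-300):
        warnings.warn(
            "k1 and k2 have collapsed to a common rate; the two phases are "
            "not separately identifiable on this trace",
            RuntimeWarning,
            stacklevel=2,
        )
        diagnostics["rate_collapse"] = True
    a1_hat = p_hat["a1"]
    small = [
        name for name in ("a2", "a3")
        if abs(p_hat[name]) < 1e-3 * max(a1_hat, 1e-300)
    ]
    if small:
        diagnostics["reduced_model_suggestion"] = (
            f"amplitude(s) {', '.join(small)} are < 0.1% of the steady state; "
            "a single-exponential (or constant) model may suffice"
        )

    return FitResult(
        model_id="biexp",
        params=p_hat,
        stderr={
            "a1": _se("a1"), "a2": _se("a2"), "a3": _se("a3"),
            "k1": se_k1, "k2": se_k2,
        },
        adj_r2=adjusted_r2(resid, curve.i, 5),
        residuals=resid,
        converged=bool(out.success),
        n_obs=len(curve),
        diagnostics=diagnostics,
    )


def classify_regime(
    electrode: ElectrodeSpec,
    analyte: AnalyteSpec,
    t_transient: float,
    threshold: float = 0.1,
    delta_override: Optional[float] = None,
) -> RegimeAssessment:
    """Decide whether a trace should be Cottrellian or kinetically controlled.

    The diffusion length delta = sqrt(2 D t_transient) is compared with the
    electrode feature radius: when features are at most ``threshold`` times
    the diffusion length, overlapping depletion layers make the array behave
    as a planar macroelectrode (Cottrellian); otherwise the early transient
    is dominated by surface kinetics and the biexponential model is
    recommended. ``delta_override`` substitutes an externally supplied
    diffusion length for the computed one.
    """
    if t_transient <= 0:
        raise ValueError("t_transient must be > 0")
    delta = (
        float(delta_override)
        if delta_override is not None
        else float(diffusion_length(t_transient, analyte))
    )
    ratio = electrode.r / delta
    regime = "cottrellian" if ratio <= threshold else "kinetic_transient"
    return RegimeAssessment(
        delta_bar=delta,
        feature_size=electrode.r,
        ratio=ratio,
        regime=regime,
        threshold=threshold,
        recommended_model="cottrell" if regime == "cottrellian" else "biexp",
    )
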