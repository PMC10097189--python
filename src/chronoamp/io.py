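"""File I/O, run configuration and the generation -> classification ->
fitting -> calibration pipeline.

CSV dialects (no vendor-neutral standard exists for chronoamperometry, so
the package fixes one):

* traces      — comma-separated, header ``time_s,current_A``, ``#`` comments;
* calibration — comma-separated, header ``conc_mM,j_uA_cm2``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import calibration as _calibration
from .fitting import Chronoamperogram, FitResult, classify_regime, fit_biexp, fit_cottrell
from .models import AnalyteSpec, BiexpParams, CottrellParams, ElectrodeSpec, GLUCOSE_10MM
from .synthetic import (
    CALIBRATION_CONCENTRATIONS_MM,
    CALIBRATION_PARAMS,
    CHRONO_PARAMS,
    NoiseSpec,
    default_time_grid,
    generate_calibration_dataset,
    generate_chronoamperogram,
)

__all__ = [
    "TRACE_COLUMNS",
    "CALIBRATION_COLUMNS",
    "RunConfig",
    "read_chronoamperogram",
    "write_chronoamperogram",
    "read_calibration_csv",
    "write_fixtures",
    "run_pipeline",
]

TRACE_COLUMNS = ("time_s", "current_A")
CALIBRATION_COLUMNS = ("conc_mM", "j_uA_cm2")


def read_chronoamperogram(path: Union[str, Path]) -> Chronoamperogram:
    """Read a two-column trace CSV (``time_s,current_A``; '#' comments).

    Rejects non-monotone time axes (naming the offending row) and any t <= 0
    row, where the diffusive current is singular.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if tuple(df.columns[:2]) != TRACE_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(TRACE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns[:2]))}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    i = df["current_A"].to_numpy(dtype=float)
    if len(t) and t[0] <= 0:
        raise ValueError(
            f"{path}: row 1 has time_s = {t[0]}; the current-time model is "
            "singular at the potential step, times must be > 0"
        )
    try:
        return Chronoamperogram(t=t, i=i, meta={"source": str(path)})
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_chronoamperogram(curve: Chronoamperogram, path: Union[str, Path]) -> Path:
    """Write a trace in the package CSV dialect (full float precision)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": curve.t, "current_A": curve.i})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_calibration_csv(path: Union[str, Path]) -> list[tuple[float, float]]:
    """Read calibration points from a ``conc_mM,j_uA_cm2`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if tuple(df.columns[:2]) != CALIBRATION_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(CALIBRATION_COLUMNS)}, "
            f"got {','.join(map(str, df.columns[:2]))}"
        )
    return list(zip(df["conc_mM"].astype(float), df["j_uA_cm2"].astype(float)))


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to/from JSON.

    ``model_override`` skips regime classification; otherwise the regime
    call (feature radius vs diffusion length at ``t_transient``) selects the
    transient model. All randomness flows from ``seed``.
    """

    electrode_label: str = "nanoporous"
    analyte_n: int = GLUCOSE_10MM.n
    analyte_D: float = GLUCOSE_10MM.D
    analyte_c: float = GLUCOSE_10MM.c
    electrode_A: float = 1e-4
    electrode_r: float = 1e-7
    electrode_N: int = 1
    model_override: Optional[str] = None
    noise_kind: str = "none"
    noise_sigma: float = 0.0
    t_min: float = 0.1
    t_max: float = 150.0
    t_step: float = 0.1
    t_transient: float = 1.0
    regime_threshold: float = 0.1
    delta_override: Optional[float] = None
    seed: int = 0
    trace_path: Optional[str] = None
    output_json: Optional[str] = None

    def analyte(self) -> AnalyteSpec:
        return AnalyteSpec(n=self.analyte_n, D=self.analyte_D, c=self.analyte_c)

    def electrode(self) -> ElectrodeSpec:
        return ElectrodeSpec(
            A=self.electrode_A, r=self.electrode_r, N=self.electrode_N,
            label=self.electrode_label,
        )

    def noise(self) -> NoiseSpec:
        return NoiseSpec(kind=self.noise_kind, sigma=self.noise_sigma, seed=self.seed)

    def t_grid(self) -> np.ndarray:
        return default_time_grid(self.t_min, self.t_max, self.t_step)

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _fit_report(fit: FitResult) -> dict:
    return {
        "model_id": fit.model_id,
        "params": fit.params,
        "stderr": fit.stderr,
        "adj_r2": fit.adj_r2,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
    }


def write_fixtures(out_dir: Union[str, Path], seed: int = 0) -> list[Path]:
    """Materialize the synthetic datasets for all four electrode types:
    one noiseless trace CSV per electrode plus its calibration CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, params in CHRONO_PARAMS.items():
        model_id = "cottrell" if isinstance(params, CottrellParams) else "biexp"
        curve = generate_chronoamperogram(model_id, params, noise=NoiseSpec(seed=seed))
        written.append(write_chronoamperogram(curve, out_dir / f"trace_{label}.csv"))
    for label, (a, b) in CALIBRATION_PARAMS.items():
        df = generate_calibration_dataset(
            a, b, CALIBRATION_CONCENTRATIONS_MM, NoiseSpec(seed=seed)
        )
        p = out_dir / f"calibration_{label}.csv"
        df.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
    return written


def run_pipeline(config: RunConfig) -> dict:
    """Classify the diffusion regime, fit the selected transient model, and
    (when the electrode has a published calibration line) fit the synthetic
    calibration; returns the full JSON-serializable report.

    The trace comes from ``config.trace_path`` if set, otherwise it is
    generated from the published parameter set for ``electrode_label``.
    """
    log: list[str] = []
    analyte = config.analyte()
    electrode = config.electrode()

    if config.trace_path:
        curve = read_chronoamperogram(config.trace_path)
        log.append(f"loaded trace from {config.trace_path} ({len(curve)} points)")
    else:
        params = CHRONO_PARAMS[config.electrode_label]
        gen_model = "cottrell" if isinstance(params, CottrellParams) else "biexp"
        curve = generate_chronoamperogram(
            gen_model, params, config.t_grid(), config.noise()
        )
        log.append(
            f"generated {gen_model} trace for {config.electrode_label} "
            f"({len(curve)} points, noise={config.noise_kind}, seed={config.seed})"
        )

    assessment = classify_regime(
        electrode, analyte, config.t_transient,
        threshold=config.regime_threshold, delta_override=config.delta_override,
    )
    log.append(
        f"regime: feature {assessment.feature_size:.3g} m vs diffusion length "
        f"{assessment.delta_bar:.3g} m (ratio {assessment.ratio:.3g}, threshold "
        f"{assessment.threshold}) -> {assessment.regime}"
    )

    model_id = config.model_override or assessment.recommended_model
    if config.model_override:
        log.append(f"model override: fitting {model_id}")
    else:
        log.append(f"fitting recommended model: {model_id}")

    fit = fit_cottrell(curve) if model_id == "cottrell" else fit_biexp(curve)
    if not fit.converged:
        raise RuntimeError(
            f"{model_id} fit did not converge: {fit.diagnostics}"
        )
    log.append(f"fit converged (adj R^2 = {fit.adj_r2:.6f})")

    report = {
        "config": asdict(config),
        "regime": {
            "delta_bar_m": assessment.delta_bar,
            "feature_size_m": assessment.feature_size,
            "ratio": assessment.ratio,
            "regime": assessment.regime,
            "recommended_model": assessment.recommended_model,
        },
        "fit": _fit_report(fit),
        "log": log,
    }

    if config.electrode_label in CALIBRATION_PARAMS and not config.trace_path:
        a, b = CALIBRATION_PARAMS[config.electrode_label]
        df = generate_calibration_dataset(
            a, b, CALIBRATION_CONCENTRATIONS_MM, config.noise()
        )
        cal = _calibration.fit_calibration(list(zip(df["conc_mM"], df["j_uA_cm2"])))
        report["calibration"] = {
            "a_uA_cm2": cal.a,
            "b_uA_cm2_mM": cal.b,
            "stderr_a": cal.stderr_a,
            "stderr_b": cal.stderr_b,
            "adj_r2": cal.adj_r2,
            "n_points": cal.n_points,
        }
        log.append(
            f"calibration: sensitivity {cal.b:.4g} uA cm^-2 mM^-1, "
            f"intercept {cal.a:.4g} uA cm^-2"
        )

    if config.output_json:
        Path(config.output_json).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        log.append(f"report written to {config.output_json}")
    return report
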