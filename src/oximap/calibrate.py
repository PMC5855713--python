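"""Calibration of the linear RGB -> (C_HbO, C_HbR, b) estimator.

For every tissue state of the calibration grid a diffuse reflectance spectrum
is simulated (or interpolated from an albedo lookup table) and converted to an
RGB triple with the camera forward model. Three multiple regressions with
regressors (1, R, G, B) — one per target C_HbO, C_HbR, b — are fit by ordinary
least squares over the grid; their coefficients form the 4x3 matrix N that is
later applied per pixel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraModel, spectrum_to_rgb
from .mcs import AlbedoLut, McsConfig, build_albedo_lut, simulate_spectrum
from .optics import GridSpec, TissueState, build_state_grid

__all__ = [
    "TrainingSet",
    "CalibrationMatrix",
    "build_training_set",
    "fit_matrix",
    "save_calibration",
    "load_calibration",
    "CalibrationLoadError",
    "FitError",
]

TARGETS = ("c_hbo", "c_hbr", "b")


class CalibrationLoadError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingSet:
    """Simulated (state, spectrum, RGB) rows plus provenance."""

    states: tuple[TissueState, ...]
    rgb: np.ndarray  # (n, 3)
    spectra: np.ndarray  # (n, n_wavelengths)
    provenance: dict

    def __post_init__(self) -> None:
        if self.rgb.shape != (len(self.states), 3):
            raise ValueError("rgb must have shape (n_states, 3)")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicated tissue states in training set")

    @property
    def targets(self) -> np.ndarray:
        """(n, 3) array of (c_hbo, c_hbr, b) per row."""
        return np.array([[s.c_hbo, s.c_hbr, s.b] for s in self.states])

    def design_matrix(self) -> np.ndarray:
        """(n, 4) regressor matrix [1, R, G, B]."""
        return np.column_stack([np.ones(len(self.states)), self.rgb])


def build_training_set(
    grid: GridSpec | None = None,
    cfg: McsConfig | None = None,
    model: CameraModel | None = None,
    lut: AlbedoLut | None = None,
    use_lut: bool = True,
) -> TrainingSet:
    """Simulate the training table over the calibration grid.

    With ``use_lut`` (default) the per-wavelength reflectances come from an
    albedo lookup table (built here if not supplied) rather than one Monte
    Carlo run per state and wavelength; the two routes agree within Monte
    Carlo error.
    """
    from .camera import default_camera_model  # local to avoid cycle at import

    grid = grid if grid is not None else GridSpec()
    cfg = cfg if cfg is not None else McsConfig()
    model = model if model is not None else default_camera_model()
    if use_lut and lut is None:
        lut = build_albedo_lut(cfg=cfg)

    states = tuple(build_state_grid(grid))
    spectra = []
    rgb = []
    for i, state in enumerate(states):
        curve = simulate_spectrum(
            state,
            cfg=cfg if use_lut else McsConfig(**{**cfg.to_dict(), "seed": cfg.seed + 1000 * i}),
            lut=lut if use_lut else None,
        )
        spectra.append(curve.values)
        rgb.append(spectrum_to_rgb(curve, model))
    provenance = {
        "grid": grid.to_dict(),
        "mcs": cfg.to_dict(),
        "camera_hash": model.hash(),
        "camera_name": model.name,
        "used_lut": bool(use_lut),
        "lut_n_photons": None if lut is None else lut.n_photons,
    }
    return TrainingSet(
        states=states,
        rgb=np.asarray(rgb),
        spectra=np.asarray(spectra),
        provenance=provenance,
    )


@dataclass(frozen=True)
class CalibrationMatrix:
    """The 4x3 coefficient matrix N.

    Columns correspond to the targets (C_HbO, C_HbR, b); rows to the
    regressors (intercept, R, G, B). Estimation computes
    [c_hbo, c_hbr, b] = N^T [1, R, G, B].
    """

    coefficients: np.ndarray
    diagnostics: dict
    provenance: dict

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (4, 3):
            raise ValueError(f"coefficients must be 4x3, got {coef.shape}")
        if not np.all(np.isfinite(coef)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coef)

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        """Map (..., 3) RGB values to (..., 3) (c_hbo, c_hbr, b) estimates."""
        rgb = np.asarray(rgb, dtype=float)
        x = np.concatenate([np.ones(rgb.shape[:-1] + (1,)), rgb], axis=-1)
        return x @ self.coefficients


def fit_matrix(training: TrainingSet) -> CalibrationMatrix:
    """Ordinary least squares of each target on (1, R, G, B)."""
    x = training.design_matrix()
    y = training.targets
    if x.shape[0] < 4:
        raise FitError("need at least 4 training rows")
    rank = np.linalg.matrix_rank(x)
    if rank < 4:
        # name the offending columns for the error message
        names = ["intercept", "R", "G", "B"]
        corr = np.corrcoef(x[:, 1:].T)
        pairs = [
            f"{names[i + 1]}~{names[j + 1]}"
            for i in range(3)
            for j in range(i + 1, 3)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise FitError(
            "regressor matrix [1, R, G, B] is rank deficient"
            + (f" (collinear: {', '.join(pairs)})" if pairs else "")
        )
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    resid = y - fitted
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - ss_res / ss_tot
    dof = max(x.shape[0] - 4, 1)
    diagnostics = {
        "r2": dict(zip(TARGETS, r2.tolist())),
        "residual_sd": dict(
            zip(TARGETS, np.sqrt(ss_res / dof).tolist())
        ),
        "n_rows": int(x.shape[0]),
    }
    return CalibrationMatrix(
        coefficients=coef, diagnostics=diagnostics, provenance=dict(training.provenance)
    )


def save_calibration(matrix: CalibrationMatrix, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "coefficients": matrix.coefficients.tolist(),
                "diagnostics": matrix.diagnostics,
                "provenance": matrix.provenance,
            },
            indent=1,
        )
    )


def load_calibration(
    path: str | Path, camera: CameraModel | None = None
) -> CalibrationMatrix:
    """Load a calibration file; warn if ``camera`` does not match its provenance."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CalibrationLoadError(f"{path}: not valid JSON: {exc}") from exc
    if "provenance" not in d or not d["provenance"]:
        raise CalibrationLoadError(f"{path}: missing provenance")
    coef = np.asarray(d.get("coefficients"), dtype=float)
    if coef.shape != (4, 3):
        raise CalibrationLoadError(
            f"{path}: coefficients must be 4x3, got {coef.shape}"
        )
    matrix = CalibrationMatrix(
        coefficients=coef,
        diagnostics=d.get("diagnostics", {}),
        provenance=d["provenance"],
    )
    if camera is not None:
        stored = matrix.provenance.get("camera_hash")
        if stored is not None and stored != camera.hash():
            warnings.warn(
                "calibration was trained with a different camera model "
                f"(stored hash {stored}, session hash {camera.hash()})",
                UserWarning,
                stacklevel=2,
            )
    return matrix
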