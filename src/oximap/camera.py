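"""RGB camera forward model and white-reference calibration.

A channel value is the integral over 400-700 nm of illuminant x channel
sensitivity x diffuse reflectance, evaluated with the rectangle rule on the
10-nm working grid and normalized per channel so a perfect reflector maps to
(1, 1, 1). Measured images are converted to the same reflectance scale by
dividing by an image of a white diffuser of known reflectance (99% default).

The camera of the original imaging system is not published; the default model
is synthetic: Gaussian channel sensitivities peaking at 460/540/610 nm with
70 nm FWHM under an equal-energy illuminant. Any model can be overridden by
CSV curves.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .optics import SpectralCurve, WORKING_GRID_NM, load_spectral_curve

__all__ = [
    "CameraModel",
    "RgbImage",
    "default_camera_model",
    "spectrum_to_rgb",
    "white_balance",
    "CalibrationStateError",
    "WhiteReferenceError",
]

_DLAMBDA_NM = 10.0
CHANNELS = ("r", "g", "b")


class CalibrationStateError(RuntimeError):
    """An operation expected a reflectance-calibrated (or raw) image."""


class WhiteReferenceError(ValueError):
    """White-reference image contains nonpositive pixels."""


@dataclass(frozen=True)
class CameraModel:
    """Illuminant + channel sensitivities + per-channel normalization.

    ``normalization[c]`` is the rectangle-rule integral of E*S_c, so that a
    unit reflectance spectrum maps to (1, 1, 1). All curves live on the
    working grid.
    """

    illuminant: SpectralCurve
    sensitivity_r: SpectralCurve
    sensitivity_g: SpectralCurve
    sensitivity_b: SpectralCurve
    name: str = "custom"

    def __post_init__(self) -> None:
        for curve in (self.illuminant, self.sensitivity_r, self.sensitivity_g, self.sensitivity_b):
            if not curve.on_working_grid():
                raise ValueError("camera curves must be resampled to the working grid")
        if np.any(self.normalization <= 0):
            raise ValueError("normalization constants must be strictly positive")

    @property
    def _sensitivities(self) -> tuple[SpectralCurve, SpectralCurve, SpectralCurve]:
        return (self.sensitivity_r, self.sensitivity_g, self.sensitivity_b)

    @property
    def normalization(self) -> np.ndarray:
        e = self.illuminant.values
        return np.array(
            [np.sum(e * s.values) * _DLAMBDA_NM for s in self._sensitivities]
        )

    def hash(self) -> str:
        """Stable fingerprint of the model's curves, for calibration provenance."""
        h = hashlib.sha256()
        for curve in (self.illuminant, *self._sensitivities):
            h.update(np.round(curve.values, 12).tobytes())
        return h.hexdigest()[:16]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.illuminant.to_csv(d / "illuminant.csv")
        for ch, curve in zip(CHANNELS, self._sensitivities):
            curve.to_csv(d / f"sensitivity_{ch}.csv")
        (d / "camera.json").write_text(
            json.dumps({"name": self.name, "hash": self.hash()}, indent=1)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "CameraModel":
        d = Path(directory)
        meta = json.loads((d / "camera.json").read_text())
        model = cls(
            illuminant=load_spectral_curve(d / "illuminant.csv", role="illuminant"),
            sensitivity_r=load_spectral_curve(d / "sensitivity_r.csv", role="sensitivity"),
            sensitivity_g=load_spectral_curve(d / "sensitivity_g.csv", role="sensitivity"),
            sensitivity_b=load_spectral_curve(d / "sensitivity_b.csv", role="sensitivity"),
            name=meta.get("name", "custom"),
        )
        return model


def default_camera_model() -> CameraModel:
    """Synthetic camera: Gaussian channels at 610/540/460 nm (R/G/B), 70 nm
    FWHM, equal-energy illuminant. A stand-in for the unpublished real camera.
    """
    wl = WORKING_GRID_NM
    sigma = 70.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def gauss(peak: float) -> SpectralCurve:
        return SpectralCurve(
            wl.copy(), np.exp(-0.5 * ((wl - peak) / sigma) ** 2), role="sensitivity"
        )

    return CameraModel(
        illuminant=SpectralCurve(wl.copy(), np.ones_like(wl), role="illuminant"),
        sensitivity_r=gauss(610.0),
        sensitivity_g=gauss(540.0),
        sensitivity_b=gauss(460.0),
        name="synthetic-gaussian-default",
    )


def spectrum_to_rgb(reflectance: SpectralCurve, model: CameraModel) -> np.ndarray:
    """Map a reflectance spectrum to a normalized (R, G, B) triple."""
    if not reflectance.on_working_grid():
        raise ValueError("reflectance spectrum must be on the working grid")
    e = model.illuminant.values
    o = reflectance.values
    raw = np.array(
        [np.sum(e * s.values * o) * _DLAMBDA_NM for s in model._sensitivities]
    )
    return raw / model.normalization


@dataclass(frozen=True)
class RgbImage:
    """A float RGB image, shape (height, width, 3), raw counts or calibrated
    reflectance."""

    data: np.ndarray
    calibration: str = "raw"  # "raw" | "reflectance"
    time_s: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("image data must have shape (height, width, 3)")
        if np.any(arr < 0):
            raise ValueError("image values must be nonnegative")
        if self.calibration not in ("raw", "reflectance"):
            raise ValueError("calibration must be 'raw' or 'reflectance'")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


def white_balance(
    raw: RgbImage, white_ref: RgbImage, ref_reflectance: float = 0.99
) -> RgbImage:
    """Convert raw counts to reflectance using a white-diffuser reference.

    calibrated = ref_reflectance * raw / white_ref, per pixel and channel.
    """
    if raw.data.shape != white_ref.data.shape:
        raise ValueError(
            f"image {raw.data.shape} and white reference {white_ref.data.shape} differ"
        )
    bad = int(np.count_nonzero(white_ref.data <= 0))
    if bad:
        raise WhiteReferenceError(
            f"white reference contains {bad} nonpositive pixel value(s)"
        )
    if not (0 < ref_reflectance <= 1):
        raise ValueError("ref_reflectance must be in (0, 1]")
    return RgbImage(
        data=ref_reflectance * raw.data / white_ref.data,
        calibration="reflectance",
        time_s=raw.time_s,
    )
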