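"""Per-pixel estimation, derived maps, ROI time courses and relative changes.

Applying the calibration matrix to a reflectance-calibrated RGB frame yields
per-pixel maps of C_HbO, C_HbR and scattering power b. Total hemoglobin is
their sum and oxygen saturation StO2 = 100 * C_HbO / C_HbT. Because the
estimator is a global linear fit to nonlinear physics, individual pixels may
overshoot (negative concentrations, StO2 beyond [0, 100]); estimates are kept
raw and flagged, and display clipping is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence
import warnings

import numpy as np
import pandas as pd

from .calibrate import CalibrationMatrix
from .camera import CameraModel, CalibrationStateError, RgbImage

__all__ = [
    "Roi",
    "ParameterMaps",
    "RoiSeries",
    "estimate_maps",
    "derive_saturation",
    "roi_timecourse",
    "relative_change",
    "RoiBoundsError",
    "NormalizationError",
]

#: Denominator guard for StO2, in concentration (%) units.
STO2_EPS = 1e-6


class RoiBoundsError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class Roi(NamedTuple):
    """Rectangle in pixel coordinates: 0-based, origin top-left, half-open on
    the right/bottom."""

    x0: int
    y0: int
    width: int
    height: int


@dataclass(frozen=True)
class ParameterMaps:
    """Co-registered per-pixel parameter planes for one frame.

    ``c_hbt``/``sto2`` are filled by :func:`derive_saturation`; ``invalid``
    marks pixels where StO2 is undefined (c_hbt <= eps). ``flagged`` counts
    out-of-range raw estimates per plane.
    """

    c_hbo: np.ndarray
    c_hbr: np.ndarray
    b: np.ndarray
    time_s: float | None = None
    c_hbt: np.ndarray | None = None
    sto2: np.ndarray | None = None
    invalid: np.ndarray | None = None
    flagged: dict | None = None

    def __post_init__(self) -> None:
        shape = self.c_hbo.shape
        for name in ("c_hbr", "b", "c_hbt", "sto2", "invalid"):
            plane = getattr(self, name)
            if plane is not None and plane.shape != shape:
                raise ValueError(f"plane {name} has shape {plane.shape}, expected {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_hbo.shape

    def plane(self, name: str) -> np.ndarray:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"plane {name!r} not computed (run derive_saturation)")
        return value


def estimate_maps(
    image: RgbImage,
    matrix: CalibrationMatrix,
    camera: CameraModel | None = None,
) -> ParameterMaps:
    """Apply the 4x3 calibration matrix per pixel: [c_hbo, c_hbr, b] =
    N^T [1, R, G, B]. Raw estimates are preserved (negatives flagged, not
    clipped)."""
    if image.calibration != "reflectance":
        raise CalibrationStateError(
            "estimate_maps requires a reflectance-calibrated image (run white_balance)"
        )
    if camera is not None:
        stored = matrix.provenance.get("camera_hash")
        if stored is not None and stored != camera.hash():
            warnings.warn(
                "image camera model differs from the calibration's provenance",
                UserWarning,
                stacklevel=2,
            )
    est = matrix.predict(image.data)
    c_hbo, c_hbr, b = est[..., 0], est[..., 1], est[..., 2]
    flagged = {
        "c_hbo_negative": int(np.count_nonzero(c_hbo < 0)),
        "c_hbr_negative": int(np.count_nonzero(c_hbr < 0)),
        "b_negative": int(np.count_nonzero(b < 0)),
    }
    return ParameterMaps(
        c_hbo=c_hbo, c_hbr=c_hbr, b=b, time_s=image.time_s, flagged=flagged
    )


def derive_saturation(
    maps: ParameterMaps, eps: float = STO2_EPS, clip_display: bool = False
) -> ParameterMaps:
    """Fill c_hbt = c_hbo + c_hbr and sto2 = 100 * c_hbo / c_hbt.

    Pixels with c_hbt <= eps are marked invalid (NaN in the sto2 plane).
    ``clip_display`` additionally clips sto2 into [0, 100] for presentation.
    """
    c_hbt = maps.c_hbo + maps.c_hbr
    invalid = ~(c_hbt > eps)
    sto2 = np.full(c_hbt.shape, np.nan)
    ok = ~invalid
    sto2[ok] = 100.0 * maps.c_hbo[ok] / c_hbt[ok]
    if clip_display:
        sto2 = np.clip(sto2, 0.0, 100.0)
    return replace(maps, c_hbt=c_hbt, sto2=sto2, invalid=invalid)


@dataclass(frozen=True)
class RoiSeries:
    """ROI-mean signal per frame."""

    times: np.ndarray
    values: np.ndarray
    roi: Roi
    signal: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False, float_format="%.17g"
        )


def roi_timecourse(
    stack: Sequence[ParameterMaps],
    roi: Roi,
    signal: str,
    times: Sequence[float] | None = None,
) -> RoiSeries:
    """Mean of one parameter plane over an ROI, per frame.

    Invalid pixels (undefined StO2) are excluded from the mean. Frame times
    come from each map's ``time_s`` unless ``times`` is given.
    """
    if not stack:
        raise ValueError("empty frame stack")
    h, w = stack[0].shape
    roi = Roi(*roi)
    if not (0 <= roi.x0 and 0 <= roi.y0 and roi.width > 0 and roi.height > 0
            and roi.x0 + roi.width <= w and roi.y0 + roi.height <= h):
        raise RoiBoundsError(f"ROI {roi} outside {w}x{h} image bounds")
    if times is None:
        times = [m.time_s if m.time_s is not None else i for i, m in enumerate(stack)]
    values = []
    for m in stack:
        plane = m.plane(signal)[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
        if m.invalid is not None:
            mask = ~m.invalid[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
            values.append(float(plane[mask].mean()) if mask.any() else np.nan)
        else:
            values.append(float(plane.mean()))
    return RoiSeries(
        times=np.asarray(times, dtype=float),
        values=np.asarray(values),
        roi=roi,
        signal=signal,
    )


def relative_change(
    series: RoiSeries, control_window: tuple[float, float]
) -> RoiSeries:
    """Relative signal change dM = (M - M_c) / M_c against a control window.

    M_c is the mean of the series over ``control_window`` (inclusive bounds),
    typically the normoxia baseline.
    """
    t0, t1 = control_window
    in_window = (series.times >= t0) & (series.times <= t1)
    if not in_window.any():
        raise NormalizationError("control window contains no frames")
    m_c = float(series.values[in_window].mean())
    if m_c == 0 or not np.isfinite(m_c):
        raise NormalizationError("control-window mean is zero or non-finite")
    return RoiSeries(
        times=series.times.copy(),
        values=(series.values - m_c) / m_c,
        roi=series.roi,
        signal=f"delta_{series.signal}",
    )
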