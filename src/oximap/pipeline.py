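"""End-to-end convenience: raw frames + white reference -> parameter maps."""

from __future__ import annotations

from typing import Sequence

from .calibrate import CalibrationMatrix
from .camera import RgbImage, white_balance
from .imaging import ParameterMaps, derive_saturation, estimate_maps

__all__ = ["process_frames"]


def process_frames(
    frames: Sequence[RgbImage],
    white: RgbImage,
    matrix: CalibrationMatrix,
    ref_reflectance: float = 0.99,
) -> list[ParameterMaps]:
    """White-balance each raw frame, apply the calibration matrix and derive
    total hemoglobin and StO2 planes."""
    maps = []
    for frame in frames:
        calibrated = white_balance(frame, white, ref_reflectance=ref_reflectance)
        maps.append(derive_saturation(estimate_maps(calibrated, matrix)))
    return maps
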