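"""Tissue optical properties from physiological parameters.

Brain tissue is modeled as a homogeneous medium whose absorption comes from
oxygenated and deoxygenated hemoglobin and whose reduced scattering follows a
power law in wavelength,

    mu_s'(lambda) = a * lambda**(-b),

with lambda in nanometers and ``a`` in cm^-1 * nm^b so that mu_s' is in cm^-1.
Hemoglobin content is expressed as a percentage of a whole-blood reference
(150 g/L hemoglobin, 44% hematocrit): ``c_hbt = 100`` means the tissue absorbs
like whole blood. The calibration grid enumerates combinations of scattering
amplitude, scattering power, total hemoglobin and oxygen saturation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WORKING_GRID_NM",
    "SpectralCurve",
    "TissueState",
    "OpticalProperties",
    "GridSpec",
    "reduced_scattering",
    "whole_blood_absorption",
    "absorption_from_state",
    "optical_properties",
    "build_state_grid",
    "load_spectral_curve",
]

#: Working wavelength grid: 400-700 nm at 10 nm spacing (31 samples).
WORKING_GRID_NM = np.arange(400.0, 701.0, 10.0)

#: Hemoglobin molar mass used to convert molar extinction to absorption, g/mol.
HEMOGLOBIN_MOLAR_MASS_G_PER_MOL = 64_500.0

#: Whole-blood hemoglobin mass concentration of the 100% reference, g/L.
WHOLE_BLOOD_HB_G_PER_L = 150.0


class SpectralCurveError(ValueError):
    """Raised for malformed or insufficiently covering spectral tables."""


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled function of wavelength (extinction, illuminant, sensitivity,
    reflectance...).

    Wavelengths must be strictly increasing and match the length of ``values``;
    values must be nonnegative.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectralCurveError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise SpectralCurveError("a spectral curve needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectralCurveError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise SpectralCurveError("values must be finite")
        if np.any(vals < 0):
            raise SpectralCurveError("values must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def resample(self, grid_nm: np.ndarray | None = None) -> "SpectralCurve":
        """Linearly resample onto ``grid_nm`` (default: the working grid).

        Extrapolation is refused: the source samples must cover the target grid.
        """
        grid = WORKING_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
        if grid[0] < self.wavelengths_nm[0] or grid[-1] > self.wavelengths_nm[-1]:
            raise SpectralCurveError(
                f"curve covers {self.wavelengths_nm[0]:g}-{self.wavelengths_nm[-1]:g} nm, "
                f"cannot cover requested {grid[0]:g}-{grid[-1]:g} nm without extrapolation"
            )
        if np.array_equal(grid, self.wavelengths_nm):
            return SpectralCurve(grid.copy(), self.values.copy(), role=self.role)
        vals = np.interp(grid, self.wavelengths_nm, self.values)
        return SpectralCurve(grid, vals, role=self.role)

    def on_working_grid(self) -> bool:
        return self.wavelengths_nm.shape == WORKING_GRID_NM.shape and np.array_equal(
            self.wavelengths_nm, WORKING_GRID_NM
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "value": self.values}
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, role: str = "generic") -> "SpectralCurve":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if not {"wavelength_nm", "value"}.issubset(df.columns):
            raise SpectralCurveError(
                f"{path}: expected columns 'wavelength_nm,value', got {list(df.columns)}"
            )
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), role=role)


def load_spectral_curve(path: str | Path, role: str = "generic") -> SpectralCurve:
    """Load a two-column table and resample it onto the working grid."""
    return SpectralCurve.from_csv(path, role=role).resample()


@dataclass(frozen=True)
class TissueState:
    """One point of the calibration grid.

    Parameters
    ----------
    c_hbo, c_hbr:
        Oxygenated / deoxygenated hemoglobin as % of the whole-blood reference.
    a:
        Scattering amplitude, cm^-1 * nm^b.
    b:
        Scattering power (dimensionless).
    """

    c_hbo: float
    c_hbr: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.c_hbo < 0 or self.c_hbr < 0:
            raise ValueError("hemoglobin concentrations must be nonnegative")
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be positive")
        if self.b <= 0:
            raise ValueError("scattering power b must be positive")

    @property
    def c_hbt(self) -> float:
        """Total hemoglobin, % of the whole-blood reference."""
        return self.c_hbo + self.c_hbr

    @property
    def sto2(self) -> float:
        """Hemoglobin oxygen saturation, % (undefined at c_hbt == 0)."""
        if self.c_hbt == 0:
            raise ValueError("StO2 undefined for c_hbt == 0")
        return 100.0 * self.c_hbo / self.c_hbt


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering spectra on the working grid, cm^-1."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray

    def __post_init__(self) -> None:
        mu_a = np.atleast_1d(np.asarray(self.mu_a, dtype=float))
        mu_s = np.atleast_1d(np.asarray(self.mu_s_prime, dtype=float))
        if mu_a.shape != mu_s.shape:
            raise ValueError("mu_a and mu_s_prime must have equal shapes")
        if np.any(mu_a < 0):
            raise ValueError("mu_a must be nonnegative")
        if np.any(mu_s <= 0):
            raise ValueError("mu_s_prime must be positive at every wavelength")
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_s_prime", mu_s)

    @property
    def albedo(self) -> np.ndarray:
        """Single-scattering albedo mu_s' / (mu_s' + mu_a) per wavelength."""
        return self.mu_s_prime / (self.mu_s_prime + self.mu_a)


#: Typical scattering amplitude of cortical tissue, cm^-1 * nm^b.
TYPICAL_A = 12e4

#: Explicit scattering-power grid values.
DEFAULT_B_VALUES = (1.24, 1.31, 1.38, 1.45, 1.52)


@dataclass(frozen=True)
class GridSpec:
    """Axes of the calibration grid.

    Defaults give 5 amplitudes x 5 powers x 3 total-hemoglobin levels x
    6 saturation levels = 450 states. ``a_scales`` multiply ``a_typical``.
    """

    a_scales: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    c_hbt_levels: tuple[float, ...] = (5.0, 10.0, 20.0)
    sto2_levels: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    a_typical: float = TYPICAL_A

    @property
    def a_values(self) -> tuple[float, ...]:
        return tuple(s * self.a_typical for s in self.a_scales)

    @property
    def n_states(self) -> int:
        return (
            len(self.a_scales)
            * len(self.b_values)
            * len(self.c_hbt_levels)
            * len(self.sto2_levels)
        )

    def to_dict(self) -> dict:
        return {
            "a_scales": list(self.a_scales),
            "b_values": list(self.b_values),
            "c_hbt_levels": list(self.c_hbt_levels),
            "sto2_levels": list(self.sto2_levels),
            "a_typical": self.a_typical,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            a_scales=tuple(d["a_scales"]),
            b_values=tuple(d["b_values"]),
            c_hbt_levels=tuple(d["c_hbt_levels"]),
            sto2_levels=tuple(d["sto2_levels"]),
            a_typical=float(d["a_typical"]),
        )


def reduced_scattering(a: float, b: float, wavelength_nm) -> np.ndarray | float:
    """Power-law reduced scattering coefficient a * lambda**(-b), cm^-1.

    ``wavelength_nm`` may be a scalar or an array (the working grid).
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if a <= 0:
        raise ValueError("scattering amplitude a must be positive")
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    out = a * wl ** (-float(b))
    return float(out) if out.ndim == 0 else out


def _load_extinction_table() -> pd.DataFrame:
    ref = resources.files("oximap.data") / "hemoglobin_extinction_synthetic.csv"
    with ref.open("rb") as fh:
        return pd.read_csv(io.BytesIO(fh.read()), comment="#")


_WHOLE_BLOOD_CACHE: dict[str, SpectralCurve] = {}


def whole_blood_absorption() -> tuple[SpectralCurve, SpectralCurve]:
    """Absorption spectra of fully oxygenated / deoxygenated whole blood, cm^-1.

    The packaged synthetic molar-extinction table (see its header) is converted
    with mu_a = ln(10) * eps * (150 g/L / 64,500 g/mol), i.e. the whole-blood
    reference of the 100% total-hemoglobin state.
    """
    if not _WHOLE_BLOOD_CACHE:
        df = _load_extinction_table()
        molar = WHOLE_BLOOD_HB_G_PER_L / HEMOGLOBIN_MOLAR_MASS_G_PER_MOL  # mol/L
        factor = np.log(10.0) * molar
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        _WHOLE_BLOOD_CACHE["hbo"] = SpectralCurve(
            wl, factor * df["eps_hbo2"].to_numpy(dtype=float), role="mu_a_hbo_whole"
        ).resample()
        _WHOLE_BLOOD_CACHE["hbr"] = SpectralCurve(
            wl, factor * df["eps_hb"].to_numpy(dtype=float), role="mu_a_hbr_whole"
        ).resample()
    return _WHOLE_BLOOD_CACHE["hbo"], _WHOLE_BLOOD_CACHE["hbr"]


def absorption_from_state(
    c_hbo: float,
    c_hbr: float,
    tables: tuple[SpectralCurve, SpectralCurve] | None = None,
) -> SpectralCurve:
    """Tissue absorption spectrum for given hemoglobin fractions (% of whole
    blood): mu_a = (c_hbo/100) * mu_a_HbO_whole + (c_hbr/100) * mu_a_HbR_whole.
    """
    if c_hbo < 0 or c_hbr < 0:
        raise ValueError("hemoglobin concentrations must be nonnegative")
    hbo, hbr = tables if tables is not None else whole_blood_absorption()
    if not (hbo.on_working_grid() and hbr.on_working_grid()):
        raise SpectralCurveError("reference tables must be on the working grid")
    mu_a = (c_hbo / 100.0) * hbo.values + (c_hbr / 100.0) * hbr.values
    return SpectralCurve(WORKING_GRID_NM.copy(), mu_a, role="mu_a")


def optical_properties(state: TissueState) -> OpticalProperties:
    """Absorption and reduced scattering of a tissue state on the working grid."""
    mu_a = absorption_from_state(state.c_hbo, state.c_hbr).values
    mu_s = reduced_scattering(state.a, state.b, WORKING_GRID_NM)
    return OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s)


def build_state_grid(spec: GridSpec | None = None) -> list[TissueState]:
    """Enumerate the calibration grid.

    Nested-loop order (each axis ascending): a, then b, then c_hbt, then sto2.
    For each (c_hbt, sto2) pair, c_hbo = c_hbt*sto2/100 and c_hbr = c_hbt - c_hbo.
    """
    spec = spec if spec is not None else GridSpec()
    for name in ("a_scales", "b_values", "c_hbt_levels", "sto2_levels"):
        if not getattr(spec, name):
            raise ValueError(f"grid axis {name} must be nonempty")
    states: list[TissueState] = []
    for a in sorted(spec.a_values):
        for b in sorted(spec.b_values):
            for c_hbt in sorted(spec.c_hbt_levels):
                for sto2 in sorted(spec.sto2_levels):
                    c_hbo = c_hbt * sto2 / 100.0
                    states.append(
                        TissueState(c_hbo=c_hbo, c_hbr=c_hbt - c_hbo, a=a, b=b)
                    )
    return states
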