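"""Weighted-photon Monte Carlo of total diffuse reflectance.

The medium is a single homogeneous layer (slab, semi-infinite when the
thickness is ``inf``) with isotropic scattering. Photons are launched downward
at the surface; per step the free path is sampled from Beer's law,
``dl = -ln(xi) / (mu_s' + mu_a)``, at each interaction a fraction
``mu_a / (mu_s' + mu_a)`` of the photon weight is deposited and a new
direction is drawn uniformly on the sphere (``cos(theta) = 2*xi - 1``,
``psi = 2*pi*xi``). The total weight escaping through the top surface, divided
by the launched weight, estimates the diffuse reflectance O = I / I0.

Because sampling depends on (mu_a, mu_s') only through the single-scattering
albedo once lengths are measured in mean free paths, the reflectance of a
semi-infinite medium is a function of the albedo alone. ``build_albedo_lut``
exploits this: simulate once on a set of albedo knots, then interpolate.

Plane-parallel geometry only needs the depth ``z`` and the direction cosine
``uz``; the azimuth never influences an escape event and is not tracked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .optics import OpticalProperties, SpectralCurve, TissueState, WORKING_GRID_NM, optical_properties

__all__ = [
    "McsConfig",
    "ReflectanceEstimate",
    "AlbedoLut",
    "simulate_reflectance",
    "simulate_spectrum",
    "build_albedo_lut",
    "DegenerateMediumError",
]


class DegenerateMediumError(ValueError):
    """Raised when mu_s' = 0: no scattering, the random walk is undefined."""


class McsConfigError(ValueError):
    pass


@dataclass(frozen=True)
class McsConfig:
    """Monte Carlo run configuration.

    ``slab_thickness_cm`` may be ``math.inf`` for a semi-infinite medium.
    With ``roulette=True`` photons below ``weight_threshold`` play Russian
    roulette (survival probability ``roulette_survival``, unbiased); with
    ``roulette=False`` they are terminated and their residual weight tallied,
    which keeps the energy balance exact at the cost of a small bias.
    """

    n_photons: int = 100_000
    seed: int = 0
    slab_thickness_cm: float = 10.0
    boundary: str = "matched"  # "matched" | "fresnel"
    n_rel: float = 1.4
    weight_threshold: float = 1e-4
    roulette_survival: float = 0.1
    roulette: bool = True

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise McsConfigError("n_photons must be >= 1")
        if not (self.slab_thickness_cm > 0):
            raise McsConfigError("slab_thickness_cm must be positive")
        if not (0 < self.roulette_survival <= 1):
            raise McsConfigError("roulette_survival must be in (0, 1]")
        if self.boundary not in ("matched", "fresnel"):
            raise McsConfigError("boundary must be 'matched' or 'fresnel'")
        if self.weight_threshold < 0:
            raise McsConfigError("weight_threshold must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "n_photons": self.n_photons,
            "seed": self.seed,
            "slab_thickness_cm": self.slab_thickness_cm,
            "boundary": self.boundary,
            "n_rel": self.n_rel,
            "weight_threshold": self.weight_threshold,
            "roulette_survival": self.roulette_survival,
            "roulette": self.roulette,
        }


@dataclass(frozen=True)
class ReflectanceEstimate:
    """Monte Carlo estimate of total diffuse reflectance at one wavelength.

    The weight ledger (reflected/transmitted/absorbed/residual, in units of
    launched photons) supports energy-conservation checks; with roulette off
    the four tallies sum to ``n_photons`` exactly up to float rounding.
    """

    reflectance: float
    std_error: float
    n_photons: int
    albedo: float
    reflected_weight: float = 0.0
    transmitted_weight: float = 0.0
    absorbed_weight: float = 0.0
    residual_weight: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.reflectance <= 1.0):
            raise ValueError("reflectance must lie in [0, 1]")
        if self.std_error < 0:
            raise ValueError("std_error must be nonnegative")


def _fresnel_reflectance(cos_i: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for internal incidence, tissue->air.

    ``cos_i`` is the magnitude of the direction cosine against the surface
    normal; ``n_rel`` the tissue/ambient refractive-index ratio (> 1).
    Total internal reflection beyond the critical angle.
    """
    cos_i = np.clip(cos_i, 0.0, 1.0)
    sin_i = np.sqrt(1.0 - cos_i**2)
    sin_t = n_rel * sin_i
    out = np.ones_like(cos_i)
    ok = sin_t < 1.0
    cos_t = np.sqrt(1.0 - sin_t[ok] ** 2)
    ci, ct = cos_i[ok], cos_t
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
    out[ok] = 0.5 * (rs**2 + rp**2)
    return out


def _simulate_albedo(
    albedo: float,
    thickness_mfp: float,
    cfg: McsConfig,
    rng: np.random.Generator,
) -> ReflectanceEstimate:
    """Random walk in mean-free-path units; returns reflectance and ledger."""
    n = cfg.n_photons
    z = np.zeros(n)
    uz = np.ones(n)
    w = np.ones(n)
    alive = np.ones(n, dtype=bool)
    refl_w = np.zeros(n)  # per-photon escaped weight, for the standard error

    transmitted = 0.0
    absorbed = 0.0
    residual = 0.0
    fresnel = cfg.boundary == "fresnel"

    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        zi, uzi, wi = z[idx], uz[idx], w[idx]
        step = -np.log(rng.random(idx.size))

        with np.errstate(divide="ignore"):
            dist = np.where(
                uzi < 0,
                zi / -uzi,
                np.where(uzi > 0, (thickness_mfp - zi) / uzi, np.inf),
            )
        hits = step >= dist
        up = hits & (uzi < 0)
        down = hits & (uzi > 0)

        if fresnel:
            # Escape through either interface is filtered by Fresnel reflection;
            # reflected photons restart at the boundary (exponential step is
            # memoryless, so resampling the remainder is exact).
            for sel, at_top in ((up, True), (down, False)):
                j = np.flatnonzero(sel)
                if j.size == 0:
                    continue
                r = _fresnel_reflectance(np.abs(uzi[j]), cfg.n_rel)
                out = rng.random(j.size) >= r
                gidx = idx[j]
                esc = gidx[out]
                if at_top:
                    refl_w[esc] += w[esc]
                else:
                    transmitted += w[esc].sum()
                alive[esc] = False
                stay = gidx[~out]
                z[stay] = 0.0 if at_top else thickness_mfp
                uz[stay] = -uz[stay]
        else:
            esc_top = idx[up]
            refl_w[esc_top] += w[esc_top]
            alive[esc_top] = False
            esc_bot = idx[down]
            transmitted += w[esc_bot].sum()
            alive[esc_bot] = False

        inter = ~hits
        j = idx[inter]
        if j.size:
            z[j] = z[j] + uz[j] * step[inter]
            dep = w[j] * (1.0 - albedo)
            absorbed += dep.sum()
            w[j] = w[j] * albedo
            uz[j] = 2.0 * rng.random(j.size) - 1.0

            low = j[w[j] < cfg.weight_threshold]
            if low.size:
                if cfg.roulette:
                    survive = rng.random(low.size) < cfg.roulette_survival
                    dead = low[~survive]
                    alive[dead] = False
                    w[dead] = 0.0
                    w[low[survive]] /= cfg.roulette_survival
                else:
                    residual += w[low].sum()
                    alive[low] = False
                    w[low] = 0.0

    mean = refl_w.mean()
    se = float(refl_w.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ReflectanceEstimate(
        reflectance=float(min(max(mean, 0.0), 1.0)),
        std_error=se,
        n_photons=n,
        albedo=float(albedo),
        reflected_weight=float(refl_w.sum()),
        transmitted_weight=float(transmitted),
        absorbed_weight=float(absorbed),
        residual_weight=float(residual),
    )


def simulate_reflectance(
    mu_a: float, mu_s_prime: float, cfg: McsConfig | None = None
) -> ReflectanceEstimate:
    """Simulate total diffuse reflectance for one (mu_a, mu_s') pair, cm^-1."""
    cfg = cfg if cfg is not None else McsConfig()
    if mu_s_prime <= 0:
        raise DegenerateMediumError("mu_s_prime must be positive")
    if mu_a < 0:
        raise ValueError("mu_a must be nonnegative")
    mu_t = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_t
    thickness_mfp = cfg.slab_thickness_cm * mu_t
    rng = np.random.default_rng(cfg.seed)
    return _simulate_albedo(albedo, thickness_mfp, cfg, rng)


def simulate_spectrum(
    state: TissueState,
    cfg: McsConfig | None = None,
    lut: "AlbedoLut | None" = None,
) -> SpectralCurve:
    """Diffuse reflectance spectrum of a tissue state on the working grid.

    Without a LUT, one simulation per wavelength with the substream seed
    ``cfg.seed + wavelength index``; with a LUT, per-wavelength albedos are
    interpolated (no fresh randomness).
    """
    cfg = cfg if cfg is not None else McsConfig()
    props = optical_properties(state)
    if lut is not None:
        vals = lut.reflectance(props.albedo)
    else:
        vals = np.empty(WORKING_GRID_NM.size)
        for i in range(WORKING_GRID_NM.size):
            est = simulate_reflectance(
                float(props.mu_a[i]),
                float(props.mu_s_prime[i]),
                replace(cfg, seed=cfg.seed + i),
            )
            vals[i] = est.reflectance
    return SpectralCurve(WORKING_GRID_NM.copy(), vals, role="reflectance")


@dataclass(frozen=True)
class AlbedoLut:
    """Reflectance of the semi-infinite medium tabulated against albedo.

    Knots include the analytic endpoints R(0) = 0 (the first interaction
    absorbs the full weight before any scattering can return it) and
    R(1) = 1 (no absorption; the recurrent walk escapes almost surely).
    Interpolation is monotone cubic (PCHIP) in s = sqrt(1 - albedo), which
    linearizes the steep approach of R to 1.
    """

    albedo_knots: np.ndarray
    reflectance_values: np.ndarray
    std_errors: np.ndarray
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.albedo_knots, dtype=float)
        r = np.asarray(self.reflectance_values, dtype=float)
        se = np.asarray(self.std_errors, dtype=float)
        if a.shape != r.shape or a.shape != se.shape:
            raise ValueError("knot arrays must share shape")
        if not np.all(np.diff(a) > 0):
            raise ValueError("albedo knots must be strictly increasing")
        if a[0] < 0 or a[-1] > 1:
            raise ValueError("albedo knots must lie in [0, 1]")
        object.__setattr__(self, "albedo_knots", a)
        object.__setattr__(self, "reflectance_values", r)
        object.__setattr__(self, "std_errors", se)

    def _interpolator(self) -> PchipInterpolator:
        s = np.sqrt(1.0 - self.albedo_knots)[::-1]
        r = self.reflectance_values[::-1]
        return PchipInterpolator(s, r, extrapolate=False)

    def reflectance(self, albedo) -> np.ndarray | float:
        """Interpolated reflectance at arbitrary albedos in [min knot, 1]."""
        a = np.asarray(albedo, dtype=float)
        if np.any(a < self.albedo_knots[0] - 1e-12) or np.any(a > 1.0 + 1e-12):
            raise ValueError("albedo outside the LUT coverage")
        s = np.sqrt(np.clip(1.0 - a, 0.0, 1.0))
        out = np.clip(self._interpolator()(s), 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "albedo_knots": self.albedo_knots.tolist(),
                    "reflectance_values": self.reflectance_values.tolist(),
                    "std_errors": self.std_errors.tolist(),
                    "n_photons": self.n_photons,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AlbedoLut":
        d = json.loads(Path(path).read_text())
        return cls(
            albedo_knots=np.asarray(d["albedo_knots"], dtype=float),
            reflectance_values=np.asarray(d["reflectance_values"], dtype=float),
            std_errors=np.asarray(d["std_errors"], dtype=float),
            n_photons=int(d["n_photons"]),
            seed=int(d["seed"]),
        )


def build_albedo_lut(
    n_knots: int = 25,
    cfg: McsConfig | None = None,
    max_albedo: float = 0.9995,
) -> AlbedoLut:
    """Simulate reflectance on albedo knots of the semi-infinite medium.

    Knots are uniform in s = sqrt(1 - albedo) between ``max_albedo`` and 0,
    concentrating them where R varies fastest; the analytic endpoints 0 and 1
    are appended. Knot k uses the substream seed ``cfg.seed + k``.
    """
    cfg = cfg if cfg is not None else McsConfig()
    if n_knots < 2:
        raise McsConfigError("n_knots must be >= 2")
    s = np.linspace(math.sqrt(1.0 - max_albedo), 1.0, n_knots)
    knots = np.sort(1.0 - s**2)
    knots = knots[(knots > 0.0) & (knots < 1.0)]

    semi_inf = replace(cfg, slab_thickness_cm=math.inf)
    refl = np.empty(knots.size)
    errs = np.empty(knots.size)
    for k, alb in enumerate(knots):
        rng = np.random.default_rng(cfg.seed + k)
        est = _simulate_albedo(float(alb), math.inf, semi_inf, rng)
        refl[k] = est.reflectance
        errs[k] = est.std_error

    albedos = np.concatenate([[0.0], knots, [1.0]])
    values = np.concatenate([[0.0], refl, [1.0]])
    ses = np.concatenate([[0.0], errs, [0.0]])
    return AlbedoLut(
        albedo_knots=albedos,
        reflectance_values=values,
        std_errors=ses,
        n_photons=cfg.n_photons,
        seed=cfg.seed,
    )
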