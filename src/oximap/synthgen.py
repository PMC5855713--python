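"""Ground-truthed synthetic cortex image sequences.

Emulates the inspired-oxygen (FiO2) protocol of the in vivo experiments the
estimator is meant for: an episode schedule (hyperoxia, normoxia, hypoxia,
anoxia) drives smooth per-pixel trajectories of total hemoglobin, oxygen
saturation and scattering power; the anoxia episode includes a delayed rapid
drop of scattering power emulating anoxic depolarization. Each frame is
rendered through the same physics used for calibration (power-law scattering +
hemoglobin absorption -> albedo LUT reflectance -> camera forward model), so
the whole pipeline can be exercised, with known truth, without animal data.

The spatial layout is deliberately simple: uniform parenchyma crossed by a few
dark "vessel" strips with higher total hemoglobin. Vessels violate the
homogeneous-medium assumption on purpose; accuracy checks should use the
parenchyma mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .camera import CameraModel, RgbImage, default_camera_model, spectrum_to_rgb
from .mcs import AlbedoLut, McsConfig, build_albedo_lut
from .optics import (
    GridSpec,
    SpectralCurve,
    TissueState,
    WORKING_GRID_NM,
    optical_properties,
)

__all__ = [
    "Episode",
    "Scenario",
    "GroundTruth",
    "SyntheticSequence",
    "default_scenario",
    "generate_sequence",
    "write_fixture_bundle",
    "load_fixture_bundle",
    "ScenarioError",
    "FixtureError",
]

#: Raw-count gain of the synthetic 16-bit sensor (counts per unit reflectance-rgb).
SENSOR_GAIN = 30_000.0

#: Reflectance of the synthetic white diffuser.
WHITE_REFLECTANCE = 0.99


class ScenarioError(ValueError):
    pass


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class Episode:
    """One respiratory condition: label, duration and parameter targets."""

    label: str
    duration_s: float
    c_hbt: float
    sto2: float
    b: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ScenarioError("episode duration must be positive")


@dataclass(frozen=True)
class Scenario:
    """Episode schedule plus rendering parameters.

    Parameters approach each episode's targets exponentially with time
    constant ``tau_s``. During an ``anoxia`` episode, ``ad_delay_s`` after its
    onset the scattering-power target switches to ``b_after_ad`` with the
    faster constant ``ad_tau_s`` (the anoxic-depolarization drop). ``noise_sd``
    is the additive Gaussian sigma in raw counts, applied after quantization.
    """

    episodes: tuple[Episode, ...]
    tau_s: float = 10.0
    ad_delay_s: float = 60.0
    b_after_ad: float = 1.26
    ad_tau_s: float = 5.0
    frame_interval_s: float = 2.0
    height: int = 64
    width: int = 64
    a: float = 12e4
    n_vessels: int = 2
    vessel_width_px: int = 4
    vessel_c_hbt: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.episodes:
            raise ScenarioError("scenario needs at least one episode")
        if self.frame_interval_s <= 0 or self.tau_s <= 0:
            raise ScenarioError("frame interval and tau must be positive")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be nonnegative")

    @property
    def total_duration_s(self) -> float:
        return sum(ep.duration_s for ep in self.episodes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scenario":
        d = json.loads(Path(path).read_text())
        episodes = tuple(Episode(**ep) for ep in d.pop("episodes"))
        return cls(episodes=episodes, **d)


def default_scenario(**overrides) -> Scenario:
    """The canonical four-episode protocol (hyperoxia -> normoxia -> hypoxia ->
    anoxia), targets inside the calibration grid."""
    episodes = (
        Episode("hyperoxia", 60.0, c_hbt=9.0, sto2=80.0, b=1.38),
        Episode("normoxia", 60.0, c_hbt=10.0, sto2=55.0, b=1.38),
        Episode("hypoxia", 60.0, c_hbt=12.0, sto2=30.0, b=1.38),
        Episode("anoxia", 120.0, c_hbt=15.0, sto2=5.0, b=1.45),
    )
    return Scenario(episodes=episodes, **overrides)


@dataclass(frozen=True)
class GroundTruth:
    """True per-frame parameter planes co-registered with the emitted frames."""

    times: np.ndarray  # (T,)
    c_hbo: np.ndarray  # (T, H, W)
    c_hbr: np.ndarray
    b: np.ndarray
    parenchyma_mask: np.ndarray  # (H, W) bool, True away from vessels

    @property
    def c_hbt(self) -> np.ndarray:
        return self.c_hbo + self.c_hbr

    @property
    def sto2(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.c_hbo / self.c_hbt


@dataclass(frozen=True)
class SyntheticSequence:
    frames: tuple[RgbImage, ...]
    white: RgbImage
    ground_truth: GroundTruth
    scenario: Scenario


def _trajectories(scn: Scenario, times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-wise parenchyma (c_hbt, sto2, b) following the episode schedule."""
    starts = np.concatenate([[0.0], np.cumsum([ep.duration_s for ep in scn.episodes])])
    c_hbt = np.empty_like(times)
    sto2 = np.empty_like(times)
    b = np.empty_like(times)
    # state initialized at the first episode's targets
    cur = np.array([scn.episodes[0].c_hbt, scn.episodes[0].sto2, scn.episodes[0].b])
    t_prev = 0.0
    for i, t in enumerate(times):
        # integrate in small substeps so trajectories are frame-rate independent
        while t_prev < t:
            dt = min(1.0, t - t_prev)
            ep_idx = min(np.searchsorted(starts, t_prev, side="right") - 1, len(scn.episodes) - 1)
            ep = scn.episodes[ep_idx]
            target = np.array([ep.c_hbt, ep.sto2, ep.b])
            tau = np.array([scn.tau_s, scn.tau_s, scn.tau_s])
            if ep.label == "anoxia" and (t_prev - starts[ep_idx]) >= scn.ad_delay_s:
                target[2] = scn.b_after_ad
                tau[2] = scn.ad_tau_s
            cur = target + (cur - target) * np.exp(-dt / tau)
            t_prev += dt
        c_hbt[i], sto2[i], b[i] = cur
    return c_hbt, sto2, b


def _vessel_mask(scn: Scenario) -> np.ndarray:
    """Boolean (H, W) mask, True on vessel strips (vertical, evenly spaced)."""
    mask = np.zeros((scn.height, scn.width), dtype=bool)
    for k in range(scn.n_vessels):
        x = int((k + 1) * scn.width / (scn.n_vessels + 1))
        mask[:, x : x + scn.vessel_width_px] = True
    return mask


def _render_rgb(c_hbo: float, c_hbr: float, a: float, b: float,
                model: CameraModel, lut: AlbedoLut) -> np.ndarray:
    state = TissueState(c_hbo=c_hbo, c_hbr=c_hbr, a=a, b=b)
    props = optical_properties(state)
    try:
        refl = lut.reflectance(props.albedo)
    except ValueError as exc:
        raise ScenarioError(f"scenario state outside LUT coverage: {exc}") from exc
    curve = SpectralCurve(WORKING_GRID_NM.copy(), np.asarray(refl), role="reflectance")
    return spectrum_to_rgb(curve, model)


def _validate_targets(scn: Scenario, grid: GridSpec) -> None:
    """Episode targets must stay inside the calibration grid's ranges; the
    estimator is meaningless outside them."""
    hbt_lo, hbt_hi = min(grid.c_hbt_levels), max(grid.c_hbt_levels)
    b_lo, b_hi = min(grid.b_values), max(grid.b_values)
    for ep in scn.episodes:
        if not (hbt_lo <= ep.c_hbt <= hbt_hi):
            raise ScenarioError(
                f"episode {ep.label!r}: c_hbt={ep.c_hbt} outside grid range "
                f"[{hbt_lo}, {hbt_hi}]"
            )
        if not (0.0 <= ep.sto2 <= 100.0):
            raise ScenarioError(f"episode {ep.label!r}: sto2={ep.sto2} outside [0, 100]")
        if not (b_lo <= ep.b <= b_hi):
            raise ScenarioError(
                f"episode {ep.label!r}: b={ep.b} outside grid range [{b_lo}, {b_hi}]"
            )
    if not (hbt_lo <= scn.vessel_c_hbt <= hbt_hi):
        raise ScenarioError("vessel_c_hbt outside grid range")
    if any(ep.label == "anoxia" for ep in scn.episodes) and not (
        b_lo <= scn.b_after_ad <= b_hi
    ):
        raise ScenarioError("b_after_ad outside grid range")


def generate_sequence(
    scn: Scenario,
    model: CameraModel | None = None,
    lut: AlbedoLut | None = None,
    grid: GridSpec | None = None,
) -> SyntheticSequence:
    """Render the scenario into raw RGB frames plus ground truth.

    Raw counts are ``SENSOR_GAIN * rgb`` quantized to integers, with seeded
    additive Gaussian noise; the matching white-reference frame encodes the
    99%-reflectance diffuser so that white balancing recovers normalized rgb.
    """
    model = model if model is not None else default_camera_model()
    _validate_targets(scn, grid if grid is not None else GridSpec())
    if lut is None:
        lut = build_albedo_lut(cfg=McsConfig(n_photons=20_000, seed=scn.seed))
    rng = np.random.default_rng(scn.seed)

    n_frames = int(np.floor(scn.total_duration_s / scn.frame_interval_s))
    times = (np.arange(n_frames) + 1) * scn.frame_interval_s
    c_hbt_t, sto2_t, b_t = _trajectories(scn, times)
    vessels = _vessel_mask(scn)

    h, w = scn.height, scn.width
    frames = []
    gt_hbo = np.empty((n_frames, h, w))
    gt_hbr = np.empty((n_frames, h, w))
    gt_b = np.empty((n_frames, h, w))
    for i, t in enumerate(times):
        par_hbo = c_hbt_t[i] * sto2_t[i] / 100.0
        par_hbr = c_hbt_t[i] - par_hbo
        ves_hbo = scn.vessel_c_hbt * sto2_t[i] / 100.0
        ves_hbr = scn.vessel_c_hbt - ves_hbo

        rgb_par = _render_rgb(par_hbo, par_hbr, scn.a, b_t[i], model, lut)
        rgb_ves = _render_rgb(ves_hbo, ves_hbr, scn.a, b_t[i], model, lut)

        plane = np.where(vessels[..., None], rgb_ves, rgb_par)
        counts = np.round(SENSOR_GAIN * plane)
        if scn.noise_sd > 0:
            counts = counts + rng.normal(0.0, scn.noise_sd, size=counts.shape)
        frames.append(
            RgbImage(data=np.clip(counts, 0.0, None), calibration="raw", time_s=float(t))
        )
        gt_hbo[i] = np.where(vessels, ves_hbo, par_hbo)
        gt_hbr[i] = np.where(vessels, ves_hbr, par_hbr)
        gt_b[i] = b_t[i]

    white = RgbImage(
        data=np.full((h, w, 3), np.round(SENSOR_GAIN * WHITE_REFLECTANCE)),
        calibration="raw",
    )
    gt = GroundTruth(
        times=times, c_hbo=gt_hbo, c_hbr=gt_hbr, b=gt_b, parenchyma_mask=~vessels
    )
    return SyntheticSequence(frames=tuple(frames), white=white, ground_truth=gt, scenario=scn)


def _write_tiff(path: Path, image: RgbImage) -> None:
    tifffile.imwrite(path, np.clip(image.data, 0, 65535).astype(np.uint16))


def write_fixture_bundle(
    path: str | Path,
    scenario: Scenario | None = None,
    model: CameraModel | None = None,
    lut: AlbedoLut | None = None,
) -> Path:
    """Emit a small canonical bundle: 12-frame 64x64 sequence, white frame,
    scenario JSON and ground-truth arrays. Fully determined by the scenario
    seed (byte-identical on regeneration)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = default_scenario(frame_interval_s=25.0, noise_sd=0.0, seed=7)
    seq = generate_sequence(scenario, model=model, lut=lut)
    for i, frame in enumerate(seq.frames):
        _write_tiff(out / f"frame_{i:03d}.tiff", frame)
    _write_tiff(out / "white.tiff", seq.white)
    scenario.to_json(out / "scenario.json")
    gt = seq.ground_truth
    np.save(out / "gt_times.npy", gt.times)
    np.save(out / "gt_c_hbo.npy", gt.c_hbo)
    np.save(out / "gt_c_hbr.npy", gt.c_hbr)
    np.save(out / "gt_b.npy", gt.b)
    np.save(out / "gt_parenchyma_mask.npy", gt.parenchyma_mask)
    (out / "manifest.json").write_text(
        json.dumps(
            {"n_frames": len(seq.frames), "white": "white.tiff", "scenario": "scenario.json"},
            indent=1,
            sort_keys=True,
        )
    )
    return out


def load_fixture_bundle(path: str | Path) -> SyntheticSequence:
    """Load a fixture bundle; refuses to proceed without the white reference."""
    p = Path(path)
    manifest = json.loads((p / "manifest.json").read_text())
    white_path = p / manifest["white"]
    if not white_path.exists():
        raise FixtureError(
            "white reference frame missing: calibration-dependent estimation "
            "cannot run without it"
        )
    scenario = Scenario.from_json(p / manifest["scenario"])
    frames = []
    times = np.load(p / "gt_times.npy")
    for i in range(manifest["n_frames"]):
        data = tifffile.imread(p / f"frame_{i:03d}.tiff").astype(float)
        frames.append(RgbImage(data=data, calibration="raw", time_s=float(times[i])))
    white = RgbImage(data=tifffile.imread(white_path).astype(float), calibration="raw")
    gt = GroundTruth(
        times=times,
        c_hbo=np.load(p / "gt_c_hbo.npy"),
        c_hbr=np.load(p / "gt_c_hbr.npy"),
        b=np.load(p / "gt_b.npy"),
        parenchyma_mask=np.load(p / "gt_parenchyma_mask.npy"),
    )
    return SyntheticSequence(frames=tuple(frames), white=white, ground_truth=gt, scenario=scenario)
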