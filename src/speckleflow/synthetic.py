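"""Synthetic raw-frame generator with known ground truth.

Stands in for the hardware: renders interleaved LED/VCSEL frame sequences
whose physics match the assumptions of the processing chain, so every
pipeline stage can be validated against known truth.

* Radial reflectance falloff per wavelength from the diffusion forward
  model at the scene's (mua, musp), times a system gain, plus a dark
  offset and optional Poisson shot noise.
* VCSEL frames additionally carry fully-developed-speckle statistics:
  pixel intensities drawn i.i.d. gamma with shape 1/K_target^2, where
  K_target follows from the speckle-visibility model at the scene's
  Db(t).  Marginal statistics only — no spatial grain correlation — which
  suffices to validate contrast estimators and inversions.
* The 135 Hz camera interleave [VCSEL, LED660, VCSEL, LED740] giving
  ~67 Hz VCSEL and ~34 Hz per-LED rates.
* Arterial / venous cuff-occlusion protocols driving phenomenological
  hemodynamic time courses (ground truth for direction checks; no claim
  of physiological calibration).

Absorption time courses are synthesized from hemoglobin-concentration
ground truth through the same extinction table the unmixing stage uses,
so concentration recovery can be checked to machine precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chromophores import (DEVICE_WAVELENGTHS, ExtinctionTable,
                           default_extinction_table, synthesize_mua)
from .forward_models import (FlowModelParams, OpticalProperties,
                             diffuse_reflectance, speckle_contrast_forward,
                             wavenumber_in_medium)
from .lut_engine import DEFAULT_MUA_GRID, DEFAULT_MUSP_GRID
from .srdrs import ProbeGeometry

logger = logging.getLogger(__name__)

CAMERA_RATE_HZ = 135.0
#: repeating 4-frame channel schedule inferred from the printed per-channel
#: rates (camera/2 for the VCSEL, camera/4 per LED)
SCHEDULE = ("V850", "L660", "V850", "L740")
CHANNEL_WAVELENGTH = {"L660": 660.0, "L740": 740.0, "V850": 850.0}

#: default imaging geometry: 256x256 sensor at 0.05 mm/pixel with the
#: source near the left edge so separations out to 10 mm stay on-chip
DEFAULT_FRAME_SHAPE = (256, 256)
DEFAULT_GEOMETRY = ProbeGeometry(source_px=(128.0, 28.0), pixel_pitch=0.05)

#: effective separation at which the VCSEL speckle contrast is evaluated
#: (midpoint of the 3.1-4.4 mm SPG region of interest)
SPECKLE_RHO_REF = 3.75


@dataclass(frozen=True)
class ProtocolSpec:
    """Cuff-occlusion protocol: ordered (duration s, pressure mmHg) segments."""

    kind: str
    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be > 0")
        if any(p < 0 for _, p in self.segments):
            raise ValueError("cuff pressures must be >= 0")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def pressure_at(self, t: float) -> float:
        acc = 0.0
        for d, p in self.segments:
            acc += d
            if t < acc:
                return p
        return self.segments[-1][1]


def make_protocol(kind: str) -> ProtocolSpec:
    """Standard occlusion protocols.

    arterial: 2 min baseline at 0 mmHg, 2 min full occlusion at 220 mmHg,
    2 min recovery.  venous: 2 min baseline, stepwise occlusion at 20, 40,
    60, 80 and 100 mmHg for 1 min each, 1 min recovery.
    """
    if kind == "arterial":
        return ProtocolSpec("arterial",
                            ((120.0, 0.0), (120.0, 220.0), (120.0, 0.0)))
    if kind == "venous":
        return ProtocolSpec("venous",
                            ((120.0, 0.0), (60.0, 20.0), (60.0, 40.0),
                             (60.0, 60.0), (60.0, 80.0), (60.0, 100.0),
                             (60.0, 0.0)))
    raise ValueError(f"unknown protocol kind {kind!r}; expected "
                     "'arterial' or 'venous'")


@dataclass(frozen=True)
class BaselineScene:
    """Resting-state ground truth the protocols perturb.

    Concentrations in uM; musp per wavelength in mm^-1; Db in mm^2/s.
    Baseline Db of 1e-6 mm^2/s (1e-8 cm^2/s) is a standard resting-tissue
    value in correlation-diffusion flowmetry; a 1 Hz sinusoidal component
    of 20% relative amplitude emulates the cardiac pulse.
    """

    HbO2: float = 50.0
    Hb: float = 25.0
    musp: dict = field(default_factory=lambda: {660.0: 1.2, 740.0: 1.1,
                                                850.0: 1.0})
    Db: float = 1e-6
    pulse_frac: float = 0.2
    pulse_hz: float = 1.0
    n: float = 1.4


@dataclass(frozen=True)
class ResponseModel:
    """Phenomenological pressure -> hemodynamics map (not calibrated).

    venous: total hemoglobin (hence absorption) rises with cuff pressure
    (+25% at 100 mmHg by default, saturation fixed) and flow falls (-65% at
    100 mmHg); arterial: flow collapses to 5% of baseline and oxygenated
    hemoglobin converts to deoxygenated at a fixed rate while occluded.
    Transitions are smoothed with a first-order 2 s relaxation.
    """

    venous_hbt_per_mmHg: float = 0.0025
    venous_db_per_mmHg: float = 0.0065
    venous_db_floor: float = 0.2
    arterial_db_frac: float = 0.05
    arterial_conversion_uM_s: float = 0.15
    smoothing_tau_s: float = 2.0
    occlusion_pressure_mmHg: float = 200.0


@dataclass
class GroundTruthScene:
    """Time-resolved ground truth driving the frame renderer.

    Arrays are sampled on ``t_grid``; properties between samples are
    linearly interpolated.  A fixed seed makes rendered output bitwise
    reproducible.
    """

    t_grid: np.ndarray
    HbO2_t: np.ndarray
    Hb_t: np.ndarray
    Db_t: np.ndarray           # slow envelope; cardiac pulse added on top
    musp: dict
    geometry: ProbeGeometry = DEFAULT_GEOMETRY
    frame_shape: tuple = DEFAULT_FRAME_SHAPE
    gain: float = 6e5
    dark_offset: float = 10.0
    shot_noise: bool = True
    exposure_T: float = 5e-3
    beta: float = 1.0
    pulse_frac: float = 0.2
    pulse_hz: float = 1.0
    n: float = 1.4
    seed: int = 0
    table: ExtinctionTable = field(default_factory=default_extinction_table)
    #: explicit per-wavelength absorption (phantom mode); when set, the
    #: hemoglobin concentration courses are ignored for mua
    mua_override: dict | None = None

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, float)
        if np.any(np.asarray(self.Db_t) < 0):
            raise ValueError("Db_t must be >= 0")

    # -- ground-truth queries ---------------------------------------------

    @property
    def duration(self) -> float:
        return float(self.t_grid[-1])

    def concentrations_at(self, t: float) -> tuple[float, float]:
        hbo2 = float(np.interp(t, self.t_grid, self.HbO2_t))
        hb = float(np.interp(t, self.t_grid, self.Hb_t))
        return hbo2, hb

    def mua_at(self, wavelength: float, t: float) -> float:
        if self.mua_override is not None:
            mua = self.mua_override[wavelength]
        else:
            hbo2, hb = self.concentrations_at(t)
            mua = synthesize_mua(hbo2, hb, self.table, (wavelength,))[0]
        lo, hi = DEFAULT_MUA_GRID[0], DEFAULT_MUA_GRID[-1]
        if not (lo <= mua <= hi):
            warnings.warn(f"mua={mua:.4g} at {wavelength} nm outside LUT "
                          "range; clamped", RuntimeWarning, stacklevel=2)
            mua = float(np.clip(mua, lo, hi))
        return mua

    def props_at(self, wavelength: float, t: float) -> OpticalProperties:
        musp = self.musp[wavelength]
        lo, hi = DEFAULT_MUSP_GRID[0], DEFAULT_MUSP_GRID[-1]
        if not (lo <= musp <= hi):
            warnings.warn(f"musp={musp:.4g} outside LUT range; clamped",
                          RuntimeWarning, stacklevel=2)
            musp = float(np.clip(musp, lo, hi))
        return OpticalProperties(mua=self.mua_at(wavelength, t), musp=musp,
                                 n=self.n, wavelength=wavelength)

    def Db_at(self, t: float) -> float:
        envelope = float(np.interp(t, self.t_grid, self.Db_t))
        pulse = 1.0 + self.pulse_frac * np.sin(2 * np.pi * self.pulse_hz * t)
        return max(envelope * pulse, 0.0)

    def flow_params_at(self, t: float) -> FlowModelParams:
        return FlowModelParams(Db=self.Db_at(t), beta=self.beta,
                               exposure_T=self.exposure_T,
                               k0=wavenumber_in_medium(850.0, self.n))


def constant_scene(baseline: BaselineScene | None = None, duration: float = 10.0,
                   seed: int = 0, pulse: bool = False,
                   **scene_kwargs) -> GroundTruthScene:
    """Scene with time-invariant ground truth.

    The cardiac pulse on Db is off by default so the scene is strictly
    constant; pass ``pulse=True`` to keep the baseline's 1 Hz component.
    """
    baseline = baseline or BaselineScene()
    t = np.array([0.0, duration])
    return GroundTruthScene(
        t_grid=t,
        HbO2_t=np.full(2, baseline.HbO2),
        Hb_t=np.full(2, baseline.Hb),
        Db_t=np.full(2, baseline.Db),
        musp=dict(baseline.musp),
        pulse_frac=baseline.pulse_frac if pulse else 0.0,
        pulse_hz=baseline.pulse_hz,
        n=baseline.n,
        seed=seed,
        **scene_kwargs,
    )


def scene_from_protocol(protocol: ProtocolSpec,
                        baseline: BaselineScene | None = None,
                        response: ResponseModel | None = None,
                        dt: float = 0.05, seed: int = 0,
                        **scene_kwargs) -> GroundTruthScene:
    """Ground-truth time courses for a cuff protocol.

    Piecewise targets per segment are relaxed toward with a first-order
    exponential (``response.smoothing_tau_s``); a zero-pressure protocol
    therefore reproduces the baseline exactly.
    """
    baseline = baseline or BaselineScene()
    response = response or ResponseModel()
    t = np.arange(0.0, protocol.total_duration + dt / 2, dt)
    hbo2 = np.empty_like(t)
    hb = np.empty_like(t)
    db = np.empty_like(t)
    cur_hbo2, cur_hb, cur_db = baseline.HbO2, baseline.Hb, baseline.Db
    alpha = dt / response.smoothing_tau_s
    relax = 1.0 - np.exp(-alpha)
    for i, ti in enumerate(t):
        p = protocol.pressure_at(ti)
        if protocol.kind == "arterial" and p >= response.occlusion_pressure_mmHg:
            # full occlusion: flow collapses, HbO2 -> Hb at a fixed rate
            db_target = baseline.Db * response.arterial_db_frac
            conv = response.arterial_conversion_uM_s * dt
            conv = min(conv, max(cur_hbo2, 0.0))
            cur_hbo2 -= conv
            cur_hb += conv
            hbo2_target, hb_target = cur_hbo2, cur_hb
        elif protocol.kind == "venous" and p > 0:
            factor = 1.0 + response.venous_hbt_per_mmHg * p
            hbo2_target = baseline.HbO2 * factor
            hb_target = baseline.Hb * factor
            db_target = baseline.Db * max(1.0 - response.venous_db_per_mmHg * p,
                                          response.venous_db_floor)
        else:
            hbo2_target, hb_target = baseline.HbO2, baseline.Hb
            db_target = baseline.Db
        cur_hbo2 += (hbo2_target - cur_hbo2) * relax
        cur_hb += (hb_target - cur_hb) * relax
        cur_db += (db_target - cur_db) * relax
        hbo2[i], hb[i], db[i] = cur_hbo2, cur_hb, cur_db

    return GroundTruthScene(
        t_grid=t, HbO2_t=hbo2, Hb_t=hb, Db_t=db, musp=dict(baseline.musp),
        pulse_frac=baseline.pulse_frac, pulse_hz=baseline.pulse_hz,
        n=baseline.n, seed=seed, **scene_kwargs,
    )


#: silicone calibration phantom defaults: optically flat-ish across the
#: three channels, static (Db = 0)
DEFAULT_PHANTOM_PROPS = {660.0: (0.02, 1.5), 740.0: (0.02, 1.4),
                         850.0: (0.02, 1.3)}


def phantom_scene(props_by_wavelength: dict | None = None,
                  duration: float = 4.0, seed: int = 100,
                  n: float = 1.4, **scene_kwargs) -> GroundTruthScene:
    """Static calibration-phantom scene with explicit (mua, musp).

    ``props_by_wavelength`` maps wavelength -> (mua, musp); the phantom is
    static (Db = 0), so VCSEL frames carry fully developed speckle.
    """
    props = props_by_wavelength or DEFAULT_PHANTOM_PROPS
    t = np.array([0.0, duration])
    return GroundTruthScene(
        t_grid=t,
        HbO2_t=np.zeros(2), Hb_t=np.zeros(2), Db_t=np.zeros(2),
        musp={wl: ms for wl, (_, ms) in props.items()},
        mua_override={wl: ma for wl, (ma, _) in props.items()},
        pulse_frac=0.0, n=n, seed=seed, **scene_kwargs,
    )


def phantom_optical_properties(scene: GroundTruthScene) -> dict:
    """Channel -> OpticalProperties map for a phantom scene."""
    return {ch: scene.props_at(wl, 0.0)
            for ch, wl in CHANNEL_WAVELENGTH.items()}


# --------------------------------------------------------------------------
# Frame rendering
# --------------------------------------------------------------------------

def _frame_rng(scene: GroundTruthScene, channel: str, t: float) -> np.random.Generator:
    code = {"L660": 1, "L740": 2, "V850": 3}[channel]
    return np.random.default_rng([scene.seed & 0x7FFFFFFF, code,
                                  int(round(t * 1e6)) & 0x7FFFFFFF])


def render_frame(scene: GroundTruthScene, channel: str, t: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one raw camera frame (float64 counts).

    LED channels: pixel mean = gain * R(rho) + dark offset with optional
    Poisson shot noise.  VCSEL: speckle first — gamma-distributed pixel
    intensities with shape 1/K_target^2 about the same radial mean — then
    dark offset and shot noise.  With shot noise off, LED frames hold the
    exact (unquantized) means.
    """
    if channel not in CHANNEL_WAVELENGTH:
        raise ValueError(f"unknown channel {channel!r}; expected one of "
                         f"{sorted(CHANNEL_WAVELENGTH)}")
    if not (0.0 <= t <= scene.duration):
        raise ValueError(f"t={t} outside scene support [0, {scene.duration}]")
    if rng is None:
        rng = _frame_rng(scene, channel, t)
    wl = CHANNEL_WAVELENGTH[channel]
    props = scene.props_at(wl, t)
    rho = scene.geometry.rho_map(scene.frame_shape)
    rho = np.clip(rho, 0.25 * scene.geometry.pixel_pitch, None)  # avoid rho=0 at source pixel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        signal = scene.gain * diffuse_reflectance(rho, props)

    if channel == "V850":
        k_target = speckle_contrast_forward(scene.flow_params_at(t),
                                            SPECKLE_RHO_REF, props)
        shape = 1.0 / k_target**2
        signal = rng.gamma(shape, signal / shape)
    mean = signal + scene.dark_offset
    if scene.shot_noise:
        return rng.poisson(mean).astype(float)
    return mean


def render_dark_frame(scene: GroundTruthScene,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Dark frame: offset plus shot noise only."""
    if rng is None:
        rng = np.random.default_rng([scene.seed & 0x7FFFFFFF, 99])
    mean = np.full(scene.frame_shape, scene.dark_offset)
    if scene.shot_noise:
        return rng.poisson(mean).astype(float)
    return mean


@dataclass
class FrameSequence:
    """Rendered frames with their channel schedule and timestamps."""

    frames: np.ndarray          # (n_frames, H, W)
    channels: list[str]
    timestamps: np.ndarray      # s
    geometry: ProbeGeometry
    exposure_T: float
    seed: int

    def __len__(self) -> int:
        return len(self.channels)


def render_sequence(scene: GroundTruthScene, duration: float | None = None,
                    camera_rate: float = CAMERA_RATE_HZ,
                    start_t: float = 0.0) -> FrameSequence:
    """Render the interleaved sequence [V850, L660, V850, L740] repeating.

    At 135 Hz this gives the VCSEL an effective 67.5 Hz and each LED
    33.75 Hz.  Deterministic for a fixed scene seed.
    """
    if duration is None:
        duration = scene.duration - start_t
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_frames = int(round(duration * camera_rate))
    rng = np.random.default_rng([scene.seed & 0x7FFFFFFF, 7,
                                 int(round(start_t * 1e6)) & 0x7FFFFFFF])
    frames = np.empty((n_frames, *scene.frame_shape))
    channels: list[str] = []
    ts = start_t + np.arange(n_frames) / camera_rate
    for i in range(n_frames):
        ch = SCHEDULE[i % len(SCHEDULE)]
        channels.append(ch)
        frames[i] = render_frame(scene, ch, float(ts[i]), rng=rng)
    return FrameSequence(frames=frames, channels=channels, timestamps=ts,
                         geometry=scene.geometry, exposure_T=scene.exposure_T,
                         seed=scene.seed)


def render_bursts(scene: GroundTruthScene, burst_s: float = 0.4,
                  every_s: float = 15.0,
                  camera_rate: float = CAMERA_RATE_HZ) -> FrameSequence:
    """Render short full-rate bursts spaced through a long scene.

    Long occlusion protocols run for minutes; rendering every frame at
    135 Hz is unnecessary to recover the slow hemodynamic trends, so this
    samples the scene with ``burst_s``-long interleaved bursts every
    ``every_s`` seconds, keeping true timestamps.  The processing chain
    treats the result like any other (gappy) sequence.
    """
    if burst_s <= 0 or every_s <= burst_s:
        raise ValueError("need 0 < burst_s < every_s")
    frames = []
    channels: list[str] = []
    ts = []
    t0 = every_s
    while t0 + burst_s <= scene.duration:
        seq = render_sequence(scene, duration=burst_s, start_t=t0,
                              camera_rate=camera_rate)
        frames.append(seq.frames)
        channels.extend(seq.channels)
        ts.append(seq.timestamps)
        t0 += every_s
    return FrameSequence(frames=np.concatenate(frames), channels=channels,
                         timestamps=np.concatenate(ts),
                         geometry=scene.geometry, exposure_T=scene.exposure_T,
                         seed=scene.seed)


# --------------------------------------------------------------------------
# Disk round trip (the same format the pipeline reads)
# --------------------------------------------------------------------------

def save_sequence(seq: FrameSequence, tiff_path, sidecar_path=None,
                  ground_truth_csv: str | None = None) -> None:
    """Write a multi-page TIFF plus JSON sidecar metadata."""
    import tifffile

    tiff_path = str(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path + ".json"
    tifffile.imwrite(tiff_path, np.asarray(np.round(seq.frames), dtype=np.uint16))
    meta = {
        "schema_version": 1,
        "channels": seq.channels,
        "timestamps_s": [float(x) for x in seq.timestamps],
        "geometry": {
            "source_px": list(seq.geometry.source_px),
            "pixel_pitch_mm": seq.geometry.pixel_pitch,
            "rho_min_mm": seq.geometry.rho_min,
            "rho_max_mm": seq.geometry.rho_max,
            "bin_width_mm": seq.geometry.bin_width,
        },
        "exposure_s": seq.exposure_T,
        "seed": seq.seed,
        "ground_truth_csv": ground_truth_csv,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def load_sequence(tiff_path, sidecar_path=None) -> FrameSequence:
    """Read a frame stack written by save_sequence (or real acquisition)."""
    import tifffile

    tiff_path = str(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != 1:
        raise ValueError(f"unsupported sidecar schema_version "
                         f"{meta.get('schema_version')!r}")
    g = meta["geometry"]
    geometry = ProbeGeometry(
        source_px=tuple(g["source_px"]), pixel_pitch=g["pixel_pitch_mm"],
        rho_min=g["rho_min_mm"], rho_max=g["rho_max_mm"],
        bin_width=g["bin_width_mm"],
    )
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameSequence(
        frames=frames, channels=list(meta["channels"]),
        timestamps=np.asarray(meta["timestamps_s"], float),
        geometry=geometry, exposure_T=float(meta["exposure_s"]),
        seed=int(meta["seed"]),
    )
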