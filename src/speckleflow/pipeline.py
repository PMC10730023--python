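"""End-to-end orchestration: raw interleaved frames -> hemodynamic tables.

Stages: demultiplex the channel-tagged frame stream; average frames in
short windows and form radial reflectance profiles per channel; calibrate
against the phantom measurement; invert to optical properties on the LUT;
unmix absorption into hemoglobin concentrations and StO2; compute speckle
contrast maps and the SPG (1/K^2) trace on the VCSEL stream; and invert
contrast to the Brownian diffusion coefficient Db using the concurrent
850 nm properties.

Outputs: ``timeseries.csv`` (epoch-aligned hemodynamics + flow),
``properties.csv`` (per-channel inversion records), ``spg_trace.csv``
(full-rate SPG) and ``report.json`` (config hash, seed, versions, flags).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .chromophores import (DEVICE_WAVELENGTHS, ExtinctionTable,
                           default_extinction_table, hemodynamic_series)
from .flow import corrected_flow_trace
from .forward_models import FlowModelParams, OpticalProperties, wavenumber_in_medium
from .lsi import (correct_window_bias, flat_field, roi_mask,
                  speckle_contrast_map, spg_trace)
from .lut_engine import ReflectanceLUT, build_lut, load_lut
from .srdrs import (CalibrationReference, ProbeGeometry, RadialProfile,
                    calibrate_profile, invert_properties, radial_profile,
                    scale_factor)
from .synthetic import CHANNEL_WAVELENGTH, FrameSequence, load_sequence

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Configuration schema
# --------------------------------------------------------------------------

class ThresholdConfig(BaseModel):
    """Per-channel R^2 acceptance thresholds for the LUT inversion."""

    led: float = 0.98
    vcsel_phantom: float = 0.94
    vcsel_in_vivo: float = 0.98
    context: str = "in_vivo"   # "phantom" | "in_vivo"

    def for_wavelength(self, wavelength: float) -> float:
        if wavelength in (660.0, 740.0):
            return self.led
        return self.vcsel_phantom if self.context == "phantom" else self.vcsel_in_vivo


class FlowConfig(BaseModel):
    beta: float = 1.0
    exposure_T: float = 5e-3
    wavelength_nm: float = 850.0
    alpha: float = 1.0
    rho_ref_mm: float = 3.75
    staleness_s: float = 5.0


class LUTConfig(BaseModel):
    n_mua: int = 81
    n_musp: int = 65
    mua_range: tuple[float, float] = (0.0, 0.4)
    musp_range: tuple[float, float] = (0.3, 3.5)


class PipelineConfig(BaseModel):
    """Single structured configuration for a pipeline run."""

    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    lut: LUTConfig = Field(default_factory=LUTConfig)
    r2_log_space: bool = True
    srdrs_window_s: float = 2.0
    lsi_window: int = 7
    roi_rho_mm: tuple[float, float] = (3.1, 4.4)
    bias_correct_K: bool = True
    n_tissue: float = 1.4
    vcsel_presmooth: bool = False   # 3-bin moving mean on the VCSEL profile
    extinction_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def extinction_table(self) -> ExtinctionTable:
        if self.extinction_csv:
            return ExtinctionTable.from_csv(self.extinction_csv)
        return default_extinction_table()


# --------------------------------------------------------------------------
# Demultiplexing
# --------------------------------------------------------------------------

class DemuxError(ValueError):
    """Frame stream carries an unknown channel tag."""


def demux(seq: FrameSequence) -> dict[str, dict]:
    """Split an interleaved sequence into per-channel streams.

    Returns a dict channel -> {"frames", "timestamps", "rate_hz"} with
    timestamps preserved and the effective rate reported as
    count / spanned duration.  Unknown channel tags raise DemuxError
    naming the offending frame index.
    """
    known = set(CHANNEL_WAVELENGTH)
    for i, ch in enumerate(seq.channels):
        if ch not in known:
            raise DemuxError(f"frame {i}: unknown channel tag {ch!r}")
    streams: dict[str, dict] = {}
    if len(seq) == 0:
        logger.warning("demux: empty frame sequence")
    duration = None
    if len(seq) >= 2:
        # spanned duration including the final frame period
        dt = np.median(np.diff(seq.timestamps))
        duration = (seq.timestamps[-1] - seq.timestamps[0]) + dt
    for ch in sorted(known):
        idx = [i for i, c in enumerate(seq.channels) if c == ch]
        ts = seq.timestamps[idx] if len(seq) else np.array([])
        frames = seq.frames[idx] if len(seq) else np.empty((0,))
        rate = len(idx) / duration if duration else float("nan")
        streams[ch] = {"frames": frames, "timestamps": ts, "rate_hz": rate}
    return streams


# --------------------------------------------------------------------------
# Calibration input
# --------------------------------------------------------------------------

@dataclass
class CalibrationInput:
    """Phantom frame sequence + dark frame + known phantom properties."""

    phantom_seq: FrameSequence
    dark_frame: np.ndarray
    phantom_props: dict[str, OpticalProperties]

    @classmethod
    def from_json(cls, path) -> "CalibrationInput":
        """Load from a JSON descriptor referencing TIFF stacks.

        Schema: {"phantom_tiff": ..., "dark_tiff": ...,
                 "props": {"660": {"mua": ..., "musp": ...}, ...},
                 "n": 1.43}
        """
        path = Path(path)
        with open(path) as fh:
            meta = json.load(fh)
        base = path.parent
        seq = load_sequence(base / meta["phantom_tiff"])
        import tifffile
        dark_stack = tifffile.imread(base / meta["dark_tiff"]).astype(float)
        dark = dark_stack.mean(axis=0) if dark_stack.ndim == 3 else dark_stack
        n = float(meta.get("n", 1.43))
        props = {}
        for ch, wl in CHANNEL_WAVELENGTH.items():
            rec = meta["props"][str(int(wl))]
            props[ch] = OpticalProperties(mua=float(rec["mua"]),
                                          musp=float(rec["musp"]), n=n,
                                          wavelength=wl)
        return cls(phantom_seq=seq, dark_frame=dark, phantom_props=props)

    def to_json(self, out_dir, stem: str = "calibration") -> Path:
        """Write phantom stack, dark frame and descriptor JSON to a directory."""
        import tifffile

        from .synthetic import save_sequence

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        phantom_tiff = f"{stem}_phantom.tif"
        dark_tiff = f"{stem}_dark.tif"
        save_sequence(self.phantom_seq, out_dir / phantom_tiff)
        tifffile.imwrite(out_dir / dark_tiff,
                         np.round(self.dark_frame).astype(np.uint16))
        any_props = next(iter(self.phantom_props.values()))
        meta = {
            "phantom_tiff": phantom_tiff,
            "dark_tiff": dark_tiff,
            "n": any_props.n,
            "props": {str(int(p.wavelength)): {"mua": p.mua, "musp": p.musp}
                      for p in self.phantom_props.values()},
        }
        path = out_dir / f"{stem}.json"
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)
        return path


def calibration_from_scene(scene, duration: float = 2.0) -> CalibrationInput:
    """Render a phantom scene into a CalibrationInput.

    The dark frame is the exact offset when the scene is noiseless, else
    the mean of 16 rendered dark frames.
    """
    from .synthetic import (phantom_optical_properties, render_dark_frame,
                            render_sequence)

    seq = render_sequence(scene, duration=duration)
    if scene.shot_noise:
        rng = np.random.default_rng([scene.seed & 0x7FFFFFFF, 98])
        dark = np.mean([render_dark_frame(scene, rng) for _ in range(16)],
                       axis=0)
    else:
        dark = np.full(scene.frame_shape, float(scene.dark_offset))
    return CalibrationInput(phantom_seq=seq, dark_frame=dark,
                            phantom_props=phantom_optical_properties(scene))


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def _window_average(frames: np.ndarray, ts: np.ndarray, window_s: float,
                    presmooth: bool = False):
    """Average frames in non-overlapping time windows.

    Yields (window-centre time, mean frame).  Windows are anchored at the
    stream's first timestamp; partial trailing windows are kept.
    """
    if len(ts) == 0:
        return
    t0 = ts[0]
    idx = np.floor((ts - t0) / window_s).astype(int)
    for k in np.unique(idx):
        sel = idx == k
        yield float(ts[sel].mean()), frames[sel].mean(axis=0)


def _presmooth_profile(profile: RadialProfile) -> RadialProfile:
    """3-bin moving mean on a radial profile (VCSEL speckle suppression)."""
    v = profile.mean_intensity
    sm = np.convolve(np.pad(v, 1, mode="edge"), np.ones(3) / 3, mode="valid")
    return RadialProfile(rho_centers=profile.rho_centers, mean_intensity=sm,
                         pixel_counts=profile.pixel_counts,
                         channel=profile.channel)


@dataclass
class PipelineResult:
    """In-memory pipeline outputs."""

    timeseries: pd.DataFrame
    properties: pd.DataFrame
    spg: pd.DataFrame
    report: dict


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def run_pipeline(input_seq, calibration, config: PipelineConfig | None = None,
                 out_dir=None, lut: ReflectanceLUT | None = None
                 ) -> PipelineResult:
    """Run the full processing chain.

    Parameters
    ----------
    input_seq : FrameSequence or path
        Interleaved frame stack (multi-page TIFF + JSON sidecar).
    calibration : CalibrationInput or path
        Phantom measurement with known properties, plus a dark frame.
    config : PipelineConfig, optional
    out_dir : path, optional
        Where to write timeseries.csv, properties.csv, spg_trace.csv and
        report.json; omit for in-memory results only.
    lut : ReflectanceLUT, optional
        Prebuilt table; by default one is built on the measured rho grid.
    """
    config = config or PipelineConfig()
    warnings_log: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                # I/O problems propagate as input errors; everything else
                # is labelled with the failing stage
                if exc is not None and not isinstance(exc, (StageError, OSError)):
                    raise StageError(f"stage '{name}' failed: {exc}") from exc
                return False

        return _Ctx()

    with _stage("load"):
        if not isinstance(input_seq, FrameSequence):
            input_seq = load_sequence(input_seq)
        if not isinstance(calibration, CalibrationInput):
            calibration = CalibrationInput.from_json(calibration)
    geometry = input_seq.geometry

    with _stage("demux"):
        streams = demux(input_seq)
        cal_streams = demux(calibration.phantom_seq)

    with _stage("calibration"):
        dark = calibration.dark_frame
        cal_profiles: dict[str, RadialProfile] = {}
        for ch in CHANNEL_WAVELENGTH:
            if len(cal_streams[ch]["timestamps"]) == 0:
                raise StageError(f"stage 'calibration' failed: no {ch} "
                                 "frames in the calibration stack")
            mean_frame = cal_streams[ch]["frames"].mean(axis=0)
            prof = radial_profile(mean_frame, geometry, dark, channel=ch)
            if ch == "V850" and config.vcsel_presmooth:
                prof = _presmooth_profile(prof)
            cal_profiles[ch] = prof
        rho_centers = cal_profiles["V850"].rho_centers
        if lut is None:
            lc = config.lut
            lut = build_lut(
                mua_grid=np.linspace(*lc.mua_range, lc.n_mua),
                musp_grid=np.linspace(*lc.musp_range, lc.n_musp),
                rho_grid=rho_centers,
                n=config.n_tissue,
            )
        calref = CalibrationReference(phantom_props=calibration.phantom_props,
                                      measured_profile=cal_profiles)
        scale = {ch: scale_factor(lut, calref, ch) for ch in CHANNEL_WAVELENGTH}

    with _stage("srdrs"):
        prop_records = []
        for ch, wl in CHANNEL_WAVELENGTH.items():
            thr = config.thresholds.for_wavelength(wl)
            stream = streams[ch]
            if len(stream["timestamps"]) == 0:
                warnings_log.append(f"srdrs: channel {ch} has no frames")
                continue
            for t_mid, mean_frame in _window_average(
                    stream["frames"], stream["timestamps"],
                    config.srdrs_window_s):
                prof = radial_profile(mean_frame, geometry, dark, channel=ch)
                if ch == "V850" and config.vcsel_presmooth:
                    prof = _presmooth_profile(prof)
                if not (prof.rho_centers.shape == rho_centers.shape and
                        np.allclose(prof.rho_centers, rho_centers)):
                    raise StageError("stage 'srdrs' failed: sample and "
                                     "calibration rho grids differ")
                curve = calibrate_profile(prof, scale[ch])
                res = invert_properties(curve, lut, thr,
                                        log_space=config.r2_log_space,
                                        n=config.n_tissue, wavelength=wl)
                if res.fallback_flag:
                    warnings_log.append(
                        f"srdrs: {ch} t={t_mid:.2f}s fell back to best "
                        f"single node (best R^2={res.best_r2:.4f})")
                prop_records.append({
                    "t": t_mid, "channel": ch, "wavelength_nm": wl,
                    "mua": res.props.mua, "musp": res.props.musp,
                    "n_candidates": res.n_candidates_averaged,
                    "best_r2": res.best_r2, "fallback": res.fallback_flag,
                })
        properties = pd.DataFrame(prop_records)
        if properties.empty:
            raise StageError("stage 'srdrs' failed: no property estimates")

    with _stage("unmix"):
        mua_series = {}
        for wl in DEVICE_WAVELENGTHS:
            sub = properties[properties.wavelength_nm == wl]
            mua_series[wl] = (sub.t.to_numpy(), sub.mua.to_numpy())
        hemo = hemodynamic_series(mua_series, config.extinction_table())

    with _stage("lsi"):
        v = streams["V850"]
        mask = roi_mask(geometry, input_seq.frames.shape[1:],
                        *config.roi_rho_mm)
        # flat-field: remove the radial mean gradient so windowed contrast
        # reflects speckle alone
        flat = flat_field(v["frames"] - dark[None])
        flat = np.clip(flat, np.percentile(flat[mask], 1) * 1e-3, None)
        maps = [speckle_contrast_map((f - dark) / flat, config.lsi_window,
                                     timestamp=t)
                for f, t in zip(v["frames"], v["timestamps"])]
        spg = spg_trace(maps, mask)
        n_flagged = int(spg.flags.sum())
        if n_flagged:
            warnings_log.append(f"lsi: {n_flagged} frames with zero ROI "
                                "contrast flagged")

    with _stage("flow"):
        sub = properties[properties.wavelength_nm == 850.0]
        props_list = [OpticalProperties(mua=r.mua, musp=r.musp,
                                        n=config.n_tissue, wavelength=850.0)
                      for r in sub.itertuples()]
        template = FlowModelParams(
            Db=0.0, beta=config.flow.beta, exposure_T=config.flow.exposure_T,
            k0=wavenumber_in_medium(config.flow.wavelength_nm, config.n_tissue),
            alpha=config.flow.alpha)
        K_for_flow = (correct_window_bias(spg.K_roi, config.lsi_window)
                      if config.bias_correct_K else spg.K_roi)
        ctrace = corrected_flow_trace(spg.t, K_for_flow, sub.t.to_numpy(),
                                      props_list, template,
                                      rho_ref=config.flow.rho_ref_mm,
                                      staleness_s=config.flow.staleness_s)
        n_nc = int((~ctrace.convergence_flag).sum())
        if n_nc:
            warnings_log.append(f"flow: {n_nc} samples did not converge "
                                "or lacked fresh properties")

    with _stage("assemble"):
        spg_df = pd.DataFrame({
            "t": spg.t, "spg": spg.spg, "K_roi": spg.K_roi,
            "roi_pixel_count": spg.roi_pixel_count,
            "Db": ctrace.Db, "flow_converged": ctrace.convergence_flag,
            "masked_frame_flag": spg.flags,
        })
        # epoch-align flow onto the hemodynamic grid by window averaging
        epoch = []
        half = config.srdrs_window_s / 2
        for t0 in hemo.t:
            sel = (spg.t >= t0 - half) & (spg.t < t0 + half)
            epoch.append({
                "spg": float(np.nanmean(spg.spg[sel])) if sel.any() else np.nan,
                "Db": float(np.nanmean(ctrace.Db[sel])) if sel.any() else np.nan,
            })
        ts = hemo.copy()
        for wl in DEVICE_WAVELENGTHS:
            sub = properties[properties.wavelength_nm == wl]
            tag = str(int(wl))
            ts[f"mua_{tag}"] = np.interp(ts.t, sub.t, sub.mua)
            ts[f"musp_{tag}"] = np.interp(ts.t, sub.t, sub.musp)
        ts["spg"] = [e["spg"] for e in epoch]
        ts["Db"] = [e["Db"] for e in epoch]

        report = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "config": config.model_dump(mode="json"),
            "config_hash": config.config_hash(),
            "seed": input_seq.seed,
            "n_frames": len(input_seq),
            "channel_rates_hz": {ch: streams[ch]["rate_hz"]
                                 for ch in CHANNEL_WAVELENGTH},
            "lut_model_id": lut.model_id,
            "n_fallback_inversions": int(properties.fallback.sum()),
            "warnings": warnings_log,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ts.to_csv(out_dir / "timeseries.csv", index=False)
        properties.to_csv(out_dir / "properties.csv", index=False)
        spg_df.to_csv(out_dir / "spg_trace.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)

    return PipelineResult(timeseries=ts, properties=properties, spg=spg_df,
                          report=report)


def segment_means(t, values, protocol, skip_s: float = 10.0) -> list[float]:
    """Per-protocol-segment means of a time series.

    The first ``skip_s`` seconds of each segment are dropped so the
    exponential transition after each cuff-pressure change does not
    contaminate the segment average.  Segments with no samples give NaN.
    """
    t = np.asarray(t, float)
    values = np.asarray(values, float)
    out = []
    start = 0.0
    for dur, _ in protocol.segments:
        sel = (t >= start + skip_s) & (t < start + dur)
        out.append(float(np.nanmean(values[sel])) if sel.any() else np.nan)
        start += dur
    return out


# --------------------------------------------------------------------------
# Repeatability
# --------------------------------------------------------------------------

def cov_report(repeated_measurements: dict) -> pd.DataFrame:
    """Coefficient of variation per quantity over repeated measurements.

    COV = 100 * sample standard deviation / mean (%).  Quantities with a
    zero mean are flagged undefined.  Requires >= 2 repeats each.
    """
    rows = []
    for name, values in repeated_measurements.items():
        v = np.asarray(values, float)
        if v.size < 2:
            raise ValueError(f"{name}: need >= 2 repeats, got {v.size}")
        mean = v.mean()
        if mean == 0:
            rows.append({"quantity": name, "cov_pct": np.nan,
                         "undefined_flag": True})
        else:
            rows.append({"quantity": name,
                         "cov_pct": 100.0 * v.std(ddof=1) / mean,
                         "undefined_flag": False})
    return pd.DataFrame(rows)
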