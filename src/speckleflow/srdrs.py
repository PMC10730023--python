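"""Spatially resolved diffuse reflectance: profiles, calibration, inversion.

The camera sees the sample around a point source; binning dark-subtracted
pixel intensities by distance from the source yields a radial reflectance
profile over source-detector separations 3-10 mm.  A calibration phantom of
known optical properties converts raw counts to absolute reflectance via a
per-separation scale factor (theoretical phantom curve / measured phantom
profile), which cancels the unknown system response.  Calibrated curves are
then matched against the lookup table: every (mua, musp) node whose
goodness of fit exceeds a per-channel R^2 threshold (0.98 for the LEDs;
0.94 phantom / 0.98 in vivo for the 850 nm laser) is retained and the
candidates' properties are averaged — a deliberately conservative estimator
when several nodes fit comparably well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward_models import OpticalProperties
from .lut_engine import ReflectanceLUT

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """ROI/annulus does not intersect the frame."""


class CalibrationError(ValueError):
    """Calibration measurement unusable (e.g. zero-intensity bin)."""


class AlignmentError(ValueError):
    """Radial grids of two profiles do not match."""


# --------------------------------------------------------------------------
# Geometry and profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeGeometry:
    """Imaging geometry: source position and pixel scale.

    source_px is the (row, col) pixel coordinate of the source spot;
    pixel_pitch the physical pixel size in mm/pixel.  rho bounds delimit
    the usable source-detector separations (mm); bins are half-open
    [lo, hi) with width bin_width, centre-of-pixel distance convention.
    """

    source_px: tuple[float, float]
    pixel_pitch: float
    rho_min: float = 3.0
    rho_max: float = 10.0
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if not (0 < self.rho_min < self.rho_max):
            raise ValueError("need 0 < rho_min < rho_max")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    def bin_edges(self) -> np.ndarray:
        n = int(round((self.rho_max - self.rho_min) / self.bin_width))
        return self.rho_min + self.bin_width * np.arange(n + 1)

    def rho_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel distance (mm) from the source, centre-of-pixel."""
        rows = np.arange(shape[0])[:, None] - self.source_px[0]
        cols = np.arange(shape[1])[None, :] - self.source_px[1]
        return self.pixel_pitch * np.hypot(rows, cols)


@dataclass
class RadialProfile:
    """Dark-subtracted mean intensity vs source-detector separation."""

    rho_centers: np.ndarray
    mean_intensity: np.ndarray
    pixel_counts: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.rho_centers = np.asarray(self.rho_centers, float)
        self.mean_intensity = np.asarray(self.mean_intensity, float)
        self.pixel_counts = np.asarray(self.pixel_counts)
        if np.any(np.diff(self.rho_centers) <= 0):
            raise ValueError("rho_centers must be strictly ascending")
        if np.any(self.mean_intensity < 0):
            raise ValueError("mean_intensity must be >= 0 after clamping")


def radial_profile(frame, geometry: ProbeGeometry, dark_frame=None,
                   channel: str = "") -> RadialProfile:
    """Bin dark-subtracted pixel values by distance from the source.

    Negative values after dark subtraction are clamped to zero; bins with
    no pixels are dropped.  Raises GeometryError when the [rho_min, rho_max]
    annulus misses the frame entirely.
    """
    frame = np.asarray(frame, dtype=float)
    if dark_frame is not None:
        dark_frame = np.asarray(dark_frame, dtype=float)
        if dark_frame.shape != frame.shape:
            raise ValueError("frame and dark_frame must share dimensions")
        frame = frame - dark_frame
    frame = np.clip(frame, 0.0, None)

    rho = geometry.rho_map(frame.shape)
    edges = geometry.bin_edges()
    sel = (rho >= edges[0]) & (rho < edges[-1])
    if not sel.any():
        raise GeometryError(
            f"annulus [{geometry.rho_min}, {geometry.rho_max}] mm lies "
            f"outside a {frame.shape} frame at pitch {geometry.pixel_pitch}"
        )
    idx = np.digitize(rho[sel], edges) - 1  # half-open [lo, hi) bins
    counts = np.bincount(idx, minlength=edges.size - 1)
    sums = np.bincount(idx, weights=frame[sel], minlength=edges.size - 1)
    rho_sums = np.bincount(idx, weights=rho[sel], minlength=edges.size - 1)
    keep = counts > 0
    # effective bin coordinate = mean pixel distance in the bin (not the
    # geometric centre): removes the first-order binning bias from pixel
    # discreteness and partial annuli, identically for sample and phantom
    centers = np.zeros(edges.size - 1)
    centers[keep] = rho_sums[keep] / counts[keep]
    return RadialProfile(
        rho_centers=centers[keep],
        mean_intensity=sums[keep] / counts[keep],
        pixel_counts=counts[keep],
        channel=channel,
    )


@dataclass
class CalibrationReference:
    """Phantom measurement with known optical properties, per channel."""

    phantom_props: dict[str, OpticalProperties]
    measured_profile: dict[str, RadialProfile]


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def scale_factor(lut: ReflectanceLUT, calibration: CalibrationReference,
                 channel: str) -> np.ndarray:
    """Per-separation scale vector: theoretical phantom curve / measured.

    The phantom's known properties are snapped to the nearest LUT node (a
    warning is logged when the snap exceeds half a grid step).  Raises
    CalibrationError when any retained bin of the measured phantom profile
    is zero.
    """
    props = calibration.phantom_props[channel]
    profile = calibration.measured_profile[channel]
    i, j = lut.node_index(props.mua, props.musp)
    d_mua = abs(lut.mua_grid[i] - props.mua)
    d_musp = abs(lut.musp_grid[j] - props.musp)
    half_step_mua = 0.5 * np.min(np.diff(lut.mua_grid))
    half_step_musp = 0.5 * np.min(np.diff(lut.musp_grid))
    if d_mua > half_step_mua or d_musp > half_step_musp:
        logger.warning(
            "calibration phantom (mua=%.4g, musp=%.4g) snapped to LUT node "
            "(%.4g, %.4g): off-node by more than half a grid step",
            props.mua, props.musp, lut.mua_grid[i], lut.musp_grid[j])
    theoretical = _curve_on(lut, i, j, profile.rho_centers)
    zero = profile.mean_intensity == 0
    if zero.any():
        bins = profile.rho_centers[zero]
        raise CalibrationError(
            f"zero measured phantom intensity in bin(s) at rho = {bins} mm"
        )
    return theoretical / profile.mean_intensity


def _curve_on(lut: ReflectanceLUT, i: int, j: int,
              rho_centers: np.ndarray) -> np.ndarray:
    """LUT node curve evaluated on rho_centers (exact at grid, else linear)."""
    curve = lut.curve_at_node(i, j)
    if rho_centers.shape == lut.rho_grid.shape and np.allclose(
            rho_centers, lut.rho_grid):
        return curve
    if rho_centers.min() < lut.rho_grid.min() - 1e-9 or \
            rho_centers.max() > lut.rho_grid.max() + 1e-9:
        raise AlignmentError("profile rho range exceeds the LUT rho grid")
    return np.interp(rho_centers, lut.rho_grid, curve)


def calibrate_profile(sample_profile: RadialProfile,
                      scale_vector: np.ndarray) -> np.ndarray:
    """Absolute reflectance: elementwise sample profile x scale vector."""
    scale_vector = np.asarray(scale_vector, float)
    if scale_vector.shape != sample_profile.mean_intensity.shape:
        raise AlignmentError(
            f"scale vector length {scale_vector.size} != profile length "
            f"{sample_profile.mean_intensity.size}"
        )
    return sample_profile.mean_intensity * scale_vector


# --------------------------------------------------------------------------
# Goodness of fit and inversion
# --------------------------------------------------------------------------

class UndefinedR2Error(ValueError):
    """Theoretical curve has zero variance; R^2 undefined."""


def r_squared(calibrated_curve, theoretical_curve, log_space: bool = True):
    """Coefficient of determination between measured and theoretical curves.

    R^2 = 1 - SS_res / SS_tot with SS_res the squared residuals between the
    curves and SS_tot the theoretical curve's variance about its own mean.
    Computed on log-transformed reflectance by default: R(rho) spans decades
    over 3-10 mm and a linear-space R^2 would be dominated by the shortest
    separations.  R^2 <= 1 with equality iff the curves are identical.

    Points where the measured curve is non-positive cannot be
    log-transformed and are excluded (>= 3 points must remain).
    """
    y_meas = np.asarray(calibrated_curve, float)
    y_th = np.asarray(theoretical_curve, float)
    if y_meas.shape != y_th.shape or y_meas.ndim != 1:
        raise ValueError("curves must be 1-D and equal length")
    if log_space:
        ok = (y_meas > 0) & (y_th > 0)
        if ok.sum() < 3:
            raise ValueError("need >= 3 positive points for log-space R^2")
        y_meas = np.log(y_meas[ok])
        y_th = np.log(y_th[ok])
    elif y_meas.size < 3:
        raise ValueError("need >= 3 points")
    ss_tot = np.sum((y_th - y_th.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedR2Error("theoretical curve has zero variance")
    ss_res = np.sum((y_meas - y_th) ** 2)
    return float(1.0 - ss_res / ss_tot)


@dataclass
class InversionResult:
    """Optical properties recovered from one calibrated curve."""

    props: OpticalProperties
    n_candidates_averaged: int
    best_r2: float
    threshold_used: float
    fallback_flag: bool = False

    def __post_init__(self) -> None:
        if not self.fallback_flag:
            if self.n_candidates_averaged < 1:
                raise ValueError("non-fallback result needs >= 1 candidate")
            if self.best_r2 < self.threshold_used:
                raise ValueError("non-fallback best_r2 below threshold")


def invert_properties(calibrated_curve, lut: ReflectanceLUT,
                      threshold: float, log_space: bool = True,
                      n: float = 1.4, wavelength: float = 0.0,
                      best_margin_factor: float | None = 2.0
                      ) -> InversionResult:
    """Recover (mua, musp) by R^2-thresholded averaging over LUT nodes.

    All grid nodes whose theoretical curve fits the calibrated curve with
    R^2 > threshold are retained and their (mua, musp) values averaged
    arithmetically.  When no node passes, the single best-R^2 node is
    returned with ``fallback_flag`` set.

    The fixed per-channel threshold is a quality floor; on top of it,
    candidates must fit within ``best_margin_factor`` times the best
    node's misfit (R^2 >= 1 - k*(1 - best_r2), k = 2 by default).  The
    floor alone admits a long (mua, musp) trade-off ridge whose arithmetic
    mean is badly biased — absolute radial reflectance constrains the pair
    only weakly at the 0.98 level — while the misfit band scales the
    candidate set with the measurement noise: a noiseless curve generated
    at a grid node is recovered exactly, and noisy curves still average
    several comparably good fits.  Pass ``best_margin_factor=None`` for
    floor-only acceptance.
    """
    y = np.asarray(calibrated_curve, float)
    if lut.n_nodes == 0:
        raise ValueError("empty LUT")
    if y.shape != lut.rho_grid.shape:
        raise AlignmentError("calibrated curve must live on the LUT rho grid")

    curves = lut.curves_flat()
    if log_space:
        ok = y > 0
        if ok.sum() < 3:
            raise ValueError("need >= 3 positive points for log-space R^2")
        ly = np.log(y[ok])
        with np.errstate(divide="ignore"):
            lc = np.log(curves[:, ok])
        valid = np.all(np.isfinite(lc), axis=1)
        mean_c = np.where(valid, np.nanmean(np.where(np.isfinite(lc), lc, np.nan), axis=1), 0.0)
        ss_tot = np.nansum((np.where(np.isfinite(lc), lc, 0.0) - mean_c[:, None]) ** 2, axis=1)
        ss_res = np.sum((np.where(np.isfinite(lc), lc, np.inf) - ly[None, :]) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(valid & (ss_tot > 0), 1.0 - ss_res / ss_tot, -np.inf)
    else:
        mean_c = curves.mean(axis=1)
        ss_tot = np.sum((curves - mean_c[:, None]) ** 2, axis=1)
        ss_res = np.sum((curves - y[None, :]) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, -np.inf)

    node_props = lut.node_properties()
    best = int(np.argmax(r2))
    best_r2 = float(r2[best])
    passing = r2 > threshold
    if best_margin_factor is not None:
        band = 1.0 - best_margin_factor * (1.0 - best_r2)
        passing &= r2 >= band
    if passing.any():
        mua, musp = node_props[passing].mean(axis=0)
        return InversionResult(
            props=OpticalProperties(mua=float(mua), musp=float(musp), n=n,
                                    wavelength=wavelength),
            n_candidates_averaged=int(passing.sum()),
            best_r2=best_r2,
            threshold_used=threshold,
        )
    mua, musp = node_props[best]
    logger.warning("no LUT node passed R^2 > %.3f (best %.4f); "
                   "falling back to the single best node", threshold, best_r2)
    return InversionResult(
        props=OpticalProperties(mua=float(mua), musp=float(musp), n=n,
                                wavelength=wavelength),
        n_candidates_averaged=1,
        best_r2=best_r2,
        threshold_used=threshold,
        fallback_flag=True,
    )
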