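"""Lookup table of theoretical diffuse-reflectance curves over (mua, musp).

The inversion step matches a measured, calibrated radial reflectance curve
against precomputed theoretical curves R(rho) on a grid of absorption and
reduced-scattering values (mua in [0, 0.4] mm^-1, musp in [0.3, 3.5] mm^-1
by default, source-detector separations 3-10 mm).  The LUT is built from a
pluggable forward model — the closed-form diffusion solution by default, so
an externally computed transport table can be dropped in — and persisted as
a self-describing HDF5 container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .forward_models import OpticalProperties, diffuse_reflectance

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: default grids: ranges are the device's stated property coverage; the
#: resolution (81 x 65 nodes) keeps inversion quantization error well below
#: typical device repeatability
DEFAULT_MUA_GRID = np.linspace(0.0, 0.4, 81)
DEFAULT_MUSP_GRID = np.linspace(0.3, 3.5, 65)
DEFAULT_RHO_GRID = np.linspace(3.0, 10.0, 71)


class LUTFormatError(ValueError):
    """Raised when a persisted LUT file is corrupt or schema-incompatible."""


def diffusion_forward_model(rho_grid: np.ndarray, mua: float, musp: float,
                            n: float = 1.4) -> np.ndarray:
    """Default forward model: diffusion-approximation R(rho) curve.

    At the mua = 0 grid edge the diffusion solution degrades (mueff = 0);
    the curve is still returned (and finite) but build_lut flags the cell.
    """
    props = OpticalProperties(mua=mua, musp=musp, n=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.asarray(diffuse_reflectance(rho_grid, props))


@dataclass
class ReflectanceLUT:
    """Grid of theoretical reflectance curves.

    curves[i, j, :] is R(rho_grid) at (mua_grid[i], musp_grid[j]).
    ``flags`` marks cells where the forward model is outside its validity
    regime (mua = 0 edge, or musp < 10*mua).
    """

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    rho_grid: np.ndarray
    curves: np.ndarray
    model_id: str
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mua_grid = np.asarray(self.mua_grid, dtype=float)
        self.musp_grid = np.asarray(self.musp_grid, dtype=float)
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        for name, g in (("mua_grid", self.mua_grid),
                        ("musp_grid", self.musp_grid),
                        ("rho_grid", self.rho_grid)):
            if g.ndim != 1 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be 1-D strictly ascending")
        expected = (self.mua_grid.size, self.musp_grid.size, self.rho_grid.size)
        if self.curves.shape != expected:
            raise ValueError(
                f"curves shape {self.curves.shape} != grid shape {expected}"
            )
        if self.flags is None:
            self.flags = np.zeros(expected[:2], dtype=bool)

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.mua_grid.size * self.musp_grid.size

    def node_index(self, mua: float, musp: float) -> tuple[int, int]:
        """Nearest grid node to (mua, musp)."""
        i = int(np.argmin(np.abs(self.mua_grid - mua)))
        j = int(np.argmin(np.abs(self.musp_grid - musp)))
        return i, j

    def curve_at_node(self, i: int, j: int) -> np.ndarray:
        return self.curves[i, j]

    def node_properties(self) -> np.ndarray:
        """(n_nodes, 2) array of (mua, musp) in row-major node order."""
        mm, ss = np.meshgrid(self.mua_grid, self.musp_grid, indexing="ij")
        return np.column_stack([mm.ravel(), ss.ravel()])

    def curves_flat(self) -> np.ndarray:
        """(n_nodes, n_rho) view of the curves in row-major node order."""
        return self.curves.reshape(self.n_nodes, self.rho_grid.size)

    def interpolate(self, mua: float, musp: float) -> np.ndarray:
        """Curve at an off-node property pair, bilinear in log-reflectance.

        Reflectance is close to log-linear in (mua, musp), so
        interpolating the log curves roughly quarters the mid-cell error
        of direct bilinear interpolation.
        """
        from scipy.interpolate import RegularGridInterpolator

        with np.errstate(divide="ignore"):
            log_curves = np.log(self.curves)
        itp = RegularGridInterpolator(
            (self.mua_grid, self.musp_grid), log_curves,
            bounds_error=True,
        )
        return np.exp(np.asarray(itp((mua, musp))))


def build_lut(mua_grid=None, musp_grid=None, rho_grid=None,
              forward_model=None, model_id: str | None = None,
              n: float = 1.4) -> ReflectanceLUT:
    """Build a ReflectanceLUT by evaluating a forward model on the grid.

    Parameters
    ----------
    mua_grid, musp_grid, rho_grid : arrays, optional
        Strictly ascending grids; defaults cover mua 0-0.4 mm^-1 (81),
        musp 0.3-3.5 mm^-1 (65) and rho 3-10 mm (71).
    forward_model : callable(rho_grid, mua, musp, n) -> curve, optional
        Defaults to the diffusion-approximation model.
    model_id : str, optional
        Provenance tag stored with the table.
    n : float
        Refractive index passed to the forward model.

    Deterministic: identical inputs give a bit-identical LUT.
    """
    mua_grid = DEFAULT_MUA_GRID if mua_grid is None else np.asarray(mua_grid, float)
    musp_grid = DEFAULT_MUSP_GRID if musp_grid is None else np.asarray(musp_grid, float)
    rho_grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, float)
    if forward_model is None:
        forward_model = diffusion_forward_model
        if model_id is None:
            model_id = f"diffusion-dipole-n{n:g}"
    if model_id is None:
        model_id = getattr(forward_model, "__name__", "custom")

    curves = np.empty((mua_grid.size, musp_grid.size, rho_grid.size))
    flags = np.zeros((mua_grid.size, musp_grid.size), dtype=bool)
    for i, mua in enumerate(mua_grid):
        for j, musp in enumerate(musp_grid):
            curves[i, j] = forward_model(rho_grid, mua, musp, n)
            if mua == 0.0 or musp < 10.0 * mua:
                flags[i, j] = True
    if flags.any():
        logger.info("build_lut: %d/%d cells flagged outside the forward "
                    "model's comfortable validity regime",
                    int(flags.sum()), flags.size)
    return ReflectanceLUT(mua_grid, musp_grid, rho_grid, curves, model_id, flags)


def save_lut(lut: ReflectanceLUT, path) -> None:
    """Persist a LUT losslessly to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mua_grid", data=lut.mua_grid)
        f.create_dataset("musp_grid", data=lut.musp_grid)
        f.create_dataset("rho_grid", data=lut.rho_grid)
        f.create_dataset("curves", data=lut.curves)
        f.create_dataset("flags", data=lut.flags)
        f.attrs["model_id"] = lut.model_id
        f.attrs["schema_version"] = SCHEMA_VERSION


def load_lut(path, expected_model_id: str | None = None) -> ReflectanceLUT:
    """Load a persisted LUT; round trip with save_lut is bitwise lossless.

    Raises LUTFormatError on corrupt/truncated files or schema mismatch.
    Logs a warning when ``expected_model_id`` is given and differs from the
    file's provenance tag.
    """
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise LUTFormatError(
                    f"LUT schema version {version!r} != expected {SCHEMA_VERSION}"
                )
            missing = {"mua_grid", "musp_grid", "rho_grid", "curves"} - set(f.keys())
            if missing:
                raise LUTFormatError(f"LUT file missing datasets: {sorted(missing)}")
            lut = ReflectanceLUT(
                mua_grid=f["mua_grid"][...],
                musp_grid=f["musp_grid"][...],
                rho_grid=f["rho_grid"][...],
                curves=f["curves"][...],
                model_id=str(f.attrs["model_id"]),
                flags=f["flags"][...] if "flags" in f else None,
            )
    except OSError as exc:
        raise LUTFormatError(
            f"cannot read LUT file {path!r} (truncated or not HDF5; "
            f"expected schema version {SCHEMA_VERSION}): {exc}"
        ) from exc
    if expected_model_id is not None and lut.model_id != expected_model_id:
        logger.warning("LUT model_id %r differs from configured %r",
                       lut.model_id, expected_model_id)
    return lut
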