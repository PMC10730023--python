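"""Closed-form light-transport models for a semi-infinite turbid medium.

Three pieces of physics used throughout the pipeline:

* steady-state diffuse reflectance ``R(rho)`` for a point source on a
  semi-infinite homogeneous medium, in the diffusion approximation with an
  extrapolated boundary (two-dipole image-source construction);
* the normalized field autocorrelation ``g1(rho, tau)`` of multiply
  scattered coherent light when the scatterers undergo Brownian motion with
  diffusion coefficient ``Db``, obtained from the correlation-diffusion
  equation by substituting a dynamic absorption
  ``mua(tau) = mua + 2 * alpha * musp * k0**2 * Db * tau``
  into the steady-state Green's function and normalizing at ``tau = 0``;
* the exposure-integrated speckle visibility linking ``g1`` to the spatial
  speckle contrast ``K`` measured by a camera with finite exposure ``T``:

  ``K**2 = (2 * beta / T) * int_0^T (1 - tau/T) * g1(rho, tau)**2 dtau``.

All lengths are in millimetres, times in seconds.  The diffusion solution is
accurate when ``musp >> mua`` and ``rho`` exceeds a transport mean free path;
a warning is emitted outside that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1.  Non-negative.
    musp : float
        Reduced scattering coefficient, mm^-1.  Strictly positive.
    n : float
        Tissue refractive index (1.0-2.0).  Default 1.4, a standard value
        for soft tissue; silicone calibration phantoms use ~1.43.
    wavelength : float
        Nominal wavelength in nm; carried as a tag, the transport model
        itself is wavelength-agnostic.
    """

    mua: float
    musp: float
    n: float = 1.4
    wavelength: float = 850.0

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.musp <= 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if not (1.0 <= self.n <= 2.0):
            raise ValueError(f"refractive index must lie in [1, 2], got {self.n}")

    @property
    def mutp(self) -> float:
        """Transport attenuation mua + musp, mm^-1."""
        return self.mua + self.musp

    @property
    def mueff(self) -> float:
        """Effective attenuation sqrt(3 * mua * (mua + musp)), mm^-1."""
        return float(np.sqrt(3.0 * self.mua * self.mutp))


@dataclass(frozen=True)
class FlowModelParams:
    """Parameters of the speckle-visibility flow model.

    ``Db`` is the Brownian diffusion coefficient of the moving scatterers
    (mm^2/s) — the blood-flow index.  ``beta`` is the coherence factor
    bounding the maximum contrast, ``exposure_T`` the camera exposure (s),
    ``k0`` the optical wavenumber in the medium (mm^-1) and ``alpha`` the
    dynamic-scatterer fraction.  ``alpha`` is fixed at 1 by default and
    absorbed into ``Db`` (the product alpha*Db is what the data constrain).
    """

    Db: float
    beta: float = 1.0
    exposure_T: float = 5e-3
    k0: float = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.Db < 0:
            raise ValueError(f"Db must be >= 0, got {self.Db}")
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if self.exposure_T <= 0:
            raise ValueError(f"exposure_T must be > 0, got {self.exposure_T}")
        if self.k0 <= 0:
            raise ValueError(f"k0 must be > 0, got {self.k0}")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


def wavenumber_in_medium(wavelength_nm: float, n: float = 1.4) -> float:
    """Optical wavenumber k0 = 2*pi*n/lambda in mm^-1."""
    lambda_mm = wavelength_nm * 1e-6
    return 2.0 * np.pi * n / lambda_mm


# --------------------------------------------------------------------------
# Steady-state diffuse reflectance
# --------------------------------------------------------------------------

def _boundary_A(n: float) -> float:
    """Internal-reflection factor A = (1 + r_d) / (1 - r_d).

    Uses the Groenhuis polynomial approximation for the effective diffuse
    reflection coefficient r_d of the tissue/air interface.
    """
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def _reflectance_dipole(rho: np.ndarray, mua: float, musp: float, n: float,
                        mueff: float | np.ndarray | None = None) -> np.ndarray:
    """Two-dipole diffuse reflectance, vectorized over rho (and mueff).

    Isotropic point source at depth z0 = 1/(mua+musp), negative image at
    z0 + 2*zb above the extrapolated boundary zb = 2*A*D.
    """
    mutp = mua + musp
    z0 = 1.0 / mutp
    D = 1.0 / (3.0 * mutp)
    zb = 2.0 * _boundary_A(n) * D
    if mueff is None:
        mueff = np.sqrt(3.0 * mua * mutp)
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return (term1 + term2) / (4.0 * np.pi)


def diffuse_reflectance(rho, props: OpticalProperties):
    """Steady-state diffuse reflectance R(rho) per unit area (mm^-2).

    Parameters
    ----------
    rho : float or array
        Source-detector separation, mm.  Strictly positive.
    props : OpticalProperties

    Returns
    -------
    float or ndarray
        Reflectance per unit area.  Strictly positive; strictly decreasing
        in ``rho`` beyond one transport mean free path and strictly
        decreasing in ``mua`` at fixed ``rho``.

    Warns when ``musp < 10 * mua`` (diffusion regime questionable).
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0):
        raise ValueError("rho must be strictly positive")
    if props.musp < 10.0 * props.mua and props.mua > 0:
        warnings.warn(
            f"musp/mua = {props.musp / props.mua:.1f} < 10: diffusion "
            "approximation may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    out = _reflectance_dipole(rho_arr, props.mua, props.musp, props.n)
    return out if out.ndim else float(out)


def asymptotic_decay_slope(props: OpticalProperties, n_points: int = 41) -> float:
    """Fitted far-field slope of ln(rho^2 * R(rho)).

    In the asymptotic regime the radial reflectance decays as
    ``exp(-mueff*rho)/rho^2`` with mueff = sqrt(3*mua*(mua+musp)), so the
    fitted slope converges to ``-mueff``.  The pre-exponential factors
    contribute relative corrections of order 1/(rho*mueff); the fit window
    rho*mueff in [30, 36] keeps them below the percent level across the
    whole lookup-table property range.
    """
    if props.mua <= 0:
        raise ValueError("asymptotic slope undefined for mua = 0")
    mueff = props.mueff
    rho = np.linspace(30.0 / mueff, 36.0 / mueff, n_points)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        refl = diffuse_reflectance(rho, props)
    return float(np.polyfit(rho, np.log(rho**2 * refl), 1)[0])


# --------------------------------------------------------------------------
# Field autocorrelation under Brownian dynamics
# --------------------------------------------------------------------------

def field_autocorrelation_g1(rho, tau, props: OpticalProperties,
                             flow: FlowModelParams):
    """Normalized field autocorrelation g1(rho, tau).

    The correlation-diffusion equation for Brownian scatterers has the same
    form as the steady-state photon-diffusion equation with absorption
    replaced by ``mua + 2*alpha*musp*k0**2*Db*tau``; g1 is the ratio of the
    semi-infinite Green's function at the dynamic absorption to its static
    (tau = 0) value.

    Satisfies g1(rho, 0) = 1, 0 < g1 <= 1, non-increasing in tau and Db.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    mua_dyn = props.mua + 2.0 * flow.alpha * props.musp * flow.k0**2 * flow.Db * tau_arr
    # dynamic absorption alters mueff only; source depth and boundary are
    # set by the static transport coefficient
    mueff_dyn = np.sqrt(3.0 * mua_dyn * (mua_dyn + props.musp))
    num = _reflectance_dipole(np.asarray(rho, float), props.mua, props.musp,
                              props.n, mueff=mueff_dyn)
    den = _reflectance_dipole(np.asarray(rho, float), props.mua, props.musp,
                              props.n)
    out = num / den
    return out if np.ndim(out) else float(out)


# --------------------------------------------------------------------------
# Exposure-integrated speckle contrast
# --------------------------------------------------------------------------

#: absolute tolerance on K^2 in the visibility quadrature
QUAD_ATOL_K2 = 1e-9
#: integration is cut off once g1^2 falls below this
G1SQ_CUTOFF = 1e-12


class QuadratureError(RuntimeError):
    """Raised when the speckle-visibility quadrature fails to converge."""


def visibility_integral(g1_func, T: float, beta: float = 1.0) -> float:
    """K from the speckle-visibility integral for an arbitrary g1(tau).

    Evaluates ``K^2 = (2*beta/T) * int_0^T (1 - tau/T) * g1(tau)**2 dtau``
    by adaptive quadrature.  Exposed separately so analytically known
    kernels (e.g. a single-exponential g1) can be checked directly.
    """
    if T <= 0:
        raise ValueError("exposure time must be > 0")

    # cut the integration where g1^2 is negligible to keep the adaptive
    # rule from wasting subdivisions on a flat tail
    upper = T
    if g1_func(T) ** 2 < G1SQ_CUTOFF:
        lo, hi = 0.0, T
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g1_func(mid) ** 2 < G1SQ_CUTOFF:
                hi = mid
            else:
                lo = mid
        upper = hi

    def integrand(tau: float) -> float:
        return (1.0 - tau / T) * g1_func(tau) ** 2

    val, err = integrate.quad(integrand, 0.0, upper, epsabs=QUAD_ATOL_K2 * T / (2 * beta),
                              epsrel=1e-10, limit=200)
    if err > 1e-6 * max(val, 1e-30) + QUAD_ATOL_K2:
        raise QuadratureError(
            f"visibility quadrature did not converge: value={val:.3e}, "
            f"error estimate={err:.3e}, upper limit={upper:.3e}s"
        )
    k2 = (2.0 * beta / T) * val
    return float(np.sqrt(max(k2, 0.0)))


def speckle_contrast_forward(flow: FlowModelParams, rho: float,
                             props: OpticalProperties) -> float:
    """Predicted speckle contrast K for Brownian flow ``flow.Db``.

    Returns K in (0, sqrt(beta)]; K -> sqrt(beta) as T -> 0 or Db -> 0,
    and K is strictly decreasing in Db at fixed exposure.
    """
    if flow.Db == 0.0:
        return float(np.sqrt(flow.beta))

    def g1(tau: float) -> float:
        return field_autocorrelation_g1(rho, tau, props, flow)

    return visibility_integral(g1, flow.exposure_T, flow.beta)
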