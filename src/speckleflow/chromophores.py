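"""Hemoglobin unmixing: absorption at three wavelengths -> [HbO2], [Hb], StO2.

Scatter-corrected absorption coefficients at 660, 740 and 850 nm are
decomposed over the two-chromophore basis {HbO2, Hb}:

    mua(lambda) = ln(10) * (eps_HbO2(lambda)*[HbO2] + eps_Hb(lambda)*[Hb])

with molar (base-10) extinction coefficients eps in mm^-1 uM^-1 and
concentrations in uM.  The 3x2 system is solved by linear least squares;
total hemoglobin [HbT] = [HbO2] + [Hb] and tissue oxygen saturation
StO2 = 100*[HbO2]/[HbT] follow.  Water and lipid are deliberately excluded
from the basis.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LN10 = float(np.log(10.0))
DEVICE_WAVELENGTHS = (660.0, 740.0, 850.0)

#: [HbT] below this (uM) leaves StO2 undefined
HBT_MIN_FOR_STO2 = 0.1


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients per wavelength.

    eps_* are base-10 molar extinctions in mm^-1 uM^-1 (the ln(10) factor
    is applied explicitly in the forward relation).  source_tag records the
    compilation the numbers came from.
    """

    wavelengths: tuple[float, ...]
    eps_HbO2: tuple[float, ...]
    eps_Hb: tuple[float, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not (len(self.wavelengths) == len(self.eps_HbO2) == len(self.eps_Hb)):
            raise ValueError("wavelengths and extinction columns must align")
        if any(e <= 0 for e in self.eps_HbO2 + self.eps_Hb):
            raise ValueError("extinction coefficients must be strictly positive")

    def matrix(self, wavelengths=DEVICE_WAVELENGTHS) -> np.ndarray:
        """(n_lambda, 2) matrix [eps_HbO2, eps_Hb] at the given wavelengths."""
        rows = []
        for wl in wavelengths:
            try:
                k = self.wavelengths.index(float(wl))
            except ValueError as exc:
                raise KeyError(f"wavelength {wl} nm not in extinction table") from exc
            rows.append((self.eps_HbO2[k], self.eps_Hb[k]))
        return np.asarray(rows, dtype=float)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ExtinctionTable":
        df = pd.read_csv(path_or_buf, comment="#")
        tag = str(df["source_tag"].iloc[0]) if "source_tag" in df else ""
        return cls(
            wavelengths=tuple(float(w) for w in df["wavelength_nm"]),
            eps_HbO2=tuple(float(e) for e in df["eps_HbO2"]),
            eps_Hb=tuple(float(e) for e in df["eps_Hb"]),
            source_tag=tag,
        )


def default_extinction_table() -> ExtinctionTable:
    """Hemoglobin extinction table shipped with the package.

    Values from the standard OMLC/Prahl compilation, converted to
    mm^-1 uM^-1 (base-10 molar extinction).
    """
    ref = importlib.resources.files("speckleflow.data") / "extinction_hemoglobin.csv"
    with ref.open("r") as fh:
        return ExtinctionTable.from_csv(fh)


def synthesize_mua(HbO2: float, Hb: float, table: ExtinctionTable,
                   wavelengths=DEVICE_WAVELENGTHS) -> np.ndarray:
    """Forward model: absorption (mm^-1) from concentrations (uM)."""
    E = table.matrix(wavelengths)
    return LN10 * (E @ np.array([HbO2, Hb]))


@dataclass
class HemodynamicState:
    """Hemoglobin concentrations (uM) and tissue oxygen saturation (%).

    StO2 is None (undefined) when HbT <= 0.1 uM.  Negative concentrations
    from noisy fits are reported as-is with ``negative_flag`` set rather
    than clipped.
    """

    HbO2: float
    Hb: float
    HbT: float = field(init=False)
    StO2: float | None = field(init=False)
    negative_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        self.HbT = self.HbO2 + self.Hb
        self.negative_flag = self.HbO2 < 0 or self.Hb < 0
        if self.HbT > HBT_MIN_FOR_STO2:
            self.StO2 = 100.0 * self.HbO2 / self.HbT
        else:
            self.StO2 = None


def unmix(mua_by_wavelength, table: ExtinctionTable,
          wavelengths=DEVICE_WAVELENGTHS, nonneg: bool = False
          ) -> HemodynamicState:
    """Least-squares chromophore concentrations from mua at >= 2 wavelengths.

    Parameters
    ----------
    mua_by_wavelength : mapping or array
        Absorption (mm^-1) keyed/ordered by ``wavelengths``.
    table : ExtinctionTable
    nonneg : bool
        Solve with a non-negativity constraint (off by default; negative
        solutions are flagged, not clipped).
    """
    if isinstance(mua_by_wavelength, dict):
        missing = [w for w in wavelengths if w not in mua_by_wavelength]
        if missing:
            raise ValueError(f"missing absorption at wavelengths: {missing}")
        mua = np.array([mua_by_wavelength[w] for w in wavelengths], float)
    else:
        mua = np.asarray(mua_by_wavelength, float)
        if mua.size != len(wavelengths):
            raise ValueError("mua vector length must match wavelengths")
    E = LN10 * table.matrix(wavelengths)
    if np.linalg.matrix_rank(E) < 2:
        raise ValueError("extinction matrix is rank-deficient; cannot unmix")
    if nonneg:
        from scipy.optimize import nnls
        c, _ = nnls(E, mua)
    else:
        c, *_ = np.linalg.lstsq(E, mua, rcond=None)
    return HemodynamicState(HbO2=float(c[0]), Hb=float(c[1]))


def hemodynamic_series(mua_series: dict[float, tuple[np.ndarray, np.ndarray]],
                       table: ExtinctionTable,
                       wavelengths=DEVICE_WAVELENGTHS) -> pd.DataFrame:
    """Align per-wavelength absorption time series and unmix each epoch.

    Parameters
    ----------
    mua_series : dict wavelength -> (t, mua)
        Per-channel absorption estimates with their timestamps.

    The slowest channel defines the epoch grid; the other channels
    contribute their temporally nearest samples.  Returns a DataFrame with
    columns t, HbO2_uM, Hb_uM, HbT_uM, StO2_pct, negative_flag.
    """
    missing = [w for w in wavelengths if w not in mua_series or
               len(mua_series[w][0]) == 0]
    if missing:
        raise ValueError(f"channels missing from absorption record: {missing}")
    # slowest channel = fewest samples over the common span
    master_wl = min(wavelengths, key=lambda w: len(mua_series[w][0]))
    t_master = np.asarray(mua_series[master_wl][0], float)
    rows = []
    for t0 in t_master:
        mua = {}
        for w in wavelengths:
            tw, vw = mua_series[w]
            tw = np.asarray(tw, float)
            k = int(np.argmin(np.abs(tw - t0)))
            mua[w] = float(np.asarray(vw, float)[k])
        st = unmix(mua, table, wavelengths)
        rows.append({"t": t0, "HbO2_uM": st.HbO2, "Hb_uM": st.Hb,
                     "HbT_uM": st.HbT,
                     "StO2_pct": np.nan if st.StO2 is None else st.StO2,
                     "negative_flag": st.negative_flag})
    return pd.DataFrame(rows)
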