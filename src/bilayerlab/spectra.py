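"""Laurdan generalized polarization, headgroup protonation, and zeta potential.

Laurdan's emission spectrum red-shifts with water penetration at the
membrane's polar/apolar interface; the generalized polarization

    GP = (I440 - I490) / (I440 + I490)

condenses this shift into a single number between -1 (fully water-exposed)
and +1 (no polar relaxation).  Lipid headgroup protonation follows the
monoprotic Henderson-Hasselbalch isotherm f(pH) = 1 / (1 + 10^(pH - pKa)),
and the zeta potential of a liposome is obtained from its electrophoretic
mobility through the Helmholtz-Smoluchowski relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.constants import epsilon_0

__all__ = [
    "EmissionSpectrum",
    "GPResult",
    "PKaFit",
    "MobilityMeasurement",
    "TitrationModel",
    "gp",
    "delta_gp",
    "protonation_fraction",
    "fit_pka",
    "zeta_from_mobility",
]

GP_BLUE_NM = 440.0  # gel-like / dehydrated band
GP_RED_NM = 490.0   # relaxed, water-exposed band


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission spectrum sampled on an increasing nm grid."""

    wavelength: np.ndarray
    intensity: np.ndarray
    label: str | float | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or it.shape != wl.shape:
            raise ValueError("wavelength and intensity must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if wl[0] > GP_BLUE_NM or wl[-1] < GP_RED_NM:
            raise ValueError("spectrum must cover both 440 and 490 nm")


@dataclass(frozen=True)
class GPResult:
    I440: float
    I490: float
    GP: float


@dataclass
class PKaFit:
    """Least-squares estimate of the apparent pKa of the protonation isotherm."""

    pKa: float
    residual: float
    covariance: float

    @property
    def stderr(self) -> float:
        return float(np.sqrt(self.covariance)) if self.covariance >= 0 else float("nan")

    def summary(self) -> str:
        return (
            "Protonation isotherm fit (monoprotic Henderson-Hasselbalch)\n"
            f"  pKa      = {self.pKa:.4f} +/- {self.stderr:.4f}\n"
            f"  residual = {self.residual:.6g} (sum of squares)"
        )


@dataclass(frozen=True)
class MobilityMeasurement:
    """Electrophoretic mobility with the medium properties needed for zeta.

    Defaults correspond to water at 25 C (viscosity 8.9e-4 Pa s, relative
    permittivity 78.4); override for other solvents or temperatures.
    """

    mobility: float                    # m^2 V^-1 s^-1
    viscosity: float = 8.9e-4          # Pa s
    relative_permittivity: float = 78.4
    temperature: float = 25.0          # C, bookkeeping only

    def __post_init__(self):
        if self.viscosity <= 0 or self.relative_permittivity <= 0:
            raise ValueError("viscosity and permittivity must be positive")


# ---------------------------------------------------------------------------


def gp(spectrum: EmissionSpectrum, window_nm: float = 0.0) -> GPResult:
    """Generalized polarization from a spectrum.

    I440 and I490 are taken by linear interpolation at exactly 440 and
    490 nm; ``window_nm > 0`` instead averages the spectrum over +/- that
    window around each band (both conventions appear in practice).
    """
    wl, it = spectrum.wavelength, spectrum.intensity

    def extract(center: float) -> float:
        if window_nm > 0:
            mask = np.abs(wl - center) <= window_nm
            if not mask.any():
                raise ValueError(f"no samples within {window_nm} nm of {center} nm")
            return float(it[mask].mean())
        return float(np.interp(center, wl, it))

    i440 = extract(GP_BLUE_NM)
    i490 = extract(GP_RED_NM)
    total = i440 + i490
    if total <= 0:
        raise ValueError("GP undefined: I440 + I490 <= 0")
    return GPResult(I440=i440, I490=i490, GP=(i440 - i490) / total)


def delta_gp(
    series: list[tuple[float, GPResult]], reference_pH: float = 8.0
) -> list[tuple[float, float]]:
    """GP change relative to the series point nearest ``reference_pH``.

    The reference must lie within 0.2 pH of an actual point; its own
    delta-GP is exactly 0.
    """
    if not series:
        raise ValueError("empty GP series")
    ph = np.array([p for p, _ in series])
    i_ref = int(np.argmin(np.abs(ph - reference_pH)))
    if abs(ph[i_ref] - reference_pH) > 0.2:
        raise ValueError(f"no point within 0.2 pH of reference {reference_pH}")
    gp_ref = series[i_ref][1].GP
    return [(p, res.GP - gp_ref) for p, res in series]


def protonation_fraction(pH: float | np.ndarray, pKa: float) -> float | np.ndarray:
    """Protonated fraction of a monoprotic site: 1 / (1 + 10^(pH - pKa))."""
    f = 1.0 / (1.0 + np.power(10.0, np.asarray(pH, dtype=float) - pKa))
    return f if f.ndim else float(f)


class TitrationModel:
    """One-parameter fit of the protonation isotherm to (pH, fraction) points."""

    def __init__(self, points: list[tuple[float, float]] | np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError("need at least 4 (pH, fraction) points")
        self.pH = pts[:, 0]
        self.fraction = pts[:, 1]
        if np.ptp(self.fraction) < 1e-12:
            raise ValueError("degenerate titration data: all fractions equal")

    def fit(self, init: float = 4.0) -> PKaFit:
        if not (0.0 < init < 14.0):
            raise ValueError("initial pKa must lie in (0, 14)")

        def resid(x):
            return protonation_fraction(self.pH, x[0]) - self.fraction

        sol = optimize.least_squares(resid, x0=[init], bounds=([0.0], [14.0]))
        rss = float(2.0 * sol.cost)
        dof = max(len(self.pH) - 1, 1)
        jtj = float(np.sum(sol.jac**2))
        cov = (rss / dof) / jtj if jtj > 0 else float("inf")
        return PKaFit(pKa=float(sol.x[0]), residual=rss, covariance=cov)


def fit_pka(points: list[tuple[float, float]] | np.ndarray, init: float = 4.0) -> PKaFit:
    """Functional wrapper around :meth:`TitrationModel.fit`."""
    return TitrationModel(points).fit(init)


def zeta_from_mobility(m: MobilityMeasurement) -> float:
    """Zeta potential (mV) via Helmholtz-Smoluchowski:

    zeta = mu * eta / (eps0 * eps_r)

    Valid for particles much larger than the Debye length (thin double
    layer), as for ~100 nm extruded liposomes in aqueous buffer.
    """
    zeta_volts = m.mobility * m.viscosity / (epsilon_0 * m.relative_permittivity)
    return zeta_volts * 1e3
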