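"""Lamellar small-angle X-ray scattering model for lipid vesicle suspensions.

The scattered intensity of a dilute suspension of large vesicles, whose
bilayer thickness is small compared to the vesicle radius, factorises into a
transverse bilayer form factor and an interlamellar structure factor,

    I(q) = kappa * (2 pi A / q^2) * P_t(q) * [u + (1 - u) * S_MCT(q)]

where ``kappa`` is an instrumental scaling factor, ``A`` the basal-plane
area (only the product ``kappa * 2 pi A`` is identifiable and it is fitted as
one compound scale), ``P_t(q)`` the squared Fourier amplitude of the bilayer
electron-density contrast modelled as three symmetric strips (methyl trough,
methylene, headgroup), ``u`` the fraction of positionally uncorrelated
bilayers, and ``S_MCT(q)`` the structure factor of a stack of ``N`` bilayers
at repeat distance ``d`` fluctuating according to the modified Caille theory
with disorder parameter ``eta``.

The canonical momentum-transfer unit throughout is nm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = [
    "SAXSCurve",
    "StepProfileParams",
    "MCTParams",
    "LamellarModelParams",
    "FitResult",
    "DensityProfile",
    "LamellarSAXSModel",
    "convert_units",
    "form_amplitude",
    "s_mct",
    "intensity_model",
    "fit_curve",
    "density_profile",
    "d_from_peak",
    "find_peaks",
]

EULER_GAMMA = float(np.euler_gamma)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SAXSCurve:
    """A 1-D scattering curve (q, I, optional sigma).

    ``unit_in`` declares the unit of ``q`` as provided; :func:`convert_units`
    maps the curve onto the canonical nm^-1 scale.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    unit_in: str = "nm^-1"

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if q.ndim != 1 or I.shape != q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.sigma is not None and self.sigma.shape != q.shape:
            raise ValueError("sigma must match q in shape")
        if not np.all(np.isfinite(q)) or not np.all(np.isfinite(I)):
            raise ValueError("q and I must be finite")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.unit_in not in ("nm^-1", "A^-1"):
            raise ValueError(f"unknown q unit {self.unit_in!r}; use 'nm^-1' or 'A^-1'")


@dataclass(frozen=True)
class StepProfileParams:
    """Three-strip electron density profile of a symmetric bilayer.

    Half-widths (nm, from the bilayer midplane): ``z_m`` bounds the terminal
    methyl trough, ``z_c`` the hydrocarbon (methylene) region, ``z_h`` the
    outer edge of the polar headgroup strip.  Densities are electron-density
    contrasts relative to the aqueous solvent (e/nm^3); the hydrocarbon
    contrast ``rho_c`` is normally negative.
    """

    z_m: float
    z_c: float
    z_h: float
    rho_m: float
    rho_c: float
    rho_h: float

    def __post_init__(self):
        if not (0.0 < self.z_m < self.z_c < self.z_h):
            raise ValueError("strip boundaries must satisfy 0 < z_m < z_c < z_h")
        for rho in (self.rho_m, self.rho_c, self.rho_h):
            if not np.isfinite(rho):
                raise ValueError("densities must be finite")
        if self.rho_c > 0:
            warnings.warn(
                "rho_c > 0: hydrocarbon contrast relative to water is normally negative",
                stacklevel=3,
            )


@dataclass(frozen=True)
class MCTParams:
    """Modified Caille theory stack: N bilayers at repeat d with disorder eta."""

    N: int
    d: float
    eta: float

    def __post_init__(self):
        if int(self.N) != self.N or self.N < 1:
            raise ValueError("N must be an integer >= 1")
        object.__setattr__(self, "N", int(self.N))
        if self.d <= 0:
            raise ValueError("repeat distance d must be positive")
        if self.eta < 0:
            raise ValueError("Caille parameter eta must be >= 0")


@dataclass(frozen=True)
class LamellarModelParams:
    """Full parameter set of the lamellar intensity model.

    ``kappa`` and ``area`` enter only through the compound scale
    ``kappa * 2 pi * area``; they are reported jointly.
    """

    kappa: float
    area: float
    profile: StepProfileParams
    mct: MCTParams
    u: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("compound scale kappa*2*pi*area must be positive")
        if not (0.0 <= self.u <= 1.0):
            raise ValueError("u must lie in [0, 1]")

    @property
    def scale(self) -> float:
        return self.kappa * 2.0 * np.pi * self.area


@dataclass
class FitResult:
    """Outcome of a lamellar model fit (parameters, chi2, covariance)."""

    params: LamellarModelParams
    chi2: float
    n_iter: int
    converged: bool
    covariance: np.ndarray | None = None
    param_names: tuple[str, ...] = ()
    _model: "LamellarSAXSModel | None" = field(default=None, repr=False)

    def predict(self, q: np.ndarray | None = None) -> np.ndarray:
        if q is None:
            if self._model is None:
                raise ValueError("no default q grid; pass q explicitly")
            q = self._model.curve.q
        return intensity_model(np.asarray(q, dtype=float), self.params)

    def profile(self, z_grid: np.ndarray | None = None, smooth_sigma: float = 0.0) -> "DensityProfile":
        if z_grid is None:
            z_max = 1.5 * self.params.profile.z_h
            z_grid = np.linspace(-z_max, z_max, 801)
        return density_profile(self.params.profile, z_grid, smooth_sigma)

    def summary(self) -> str:
        p = self.params
        err = {}
        if self.covariance is not None and len(self.param_names):
            se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
            err = dict(zip(self.param_names, se))

        def row(name, value, unit=""):
            e = err.get(name)
            es = f" +/- {e:.4g}" if e is not None else ""
            return f"  {name:<12} {value:>12.5g}{es}  {unit}"

        lines = [
            "Lamellar SAXS model fit",
            "=" * 46,
            row("scale", p.scale, "(kappa*2piA, a.u.)"),
            row("z_m", p.profile.z_m, "nm"),
            row("z_c", p.profile.z_c, "nm"),
            row("z_h", p.profile.z_h, "nm"),
            row("rho_m", p.profile.rho_m, "e/nm^3 (rel.)"),
            row("rho_c", p.profile.rho_c, "e/nm^3 (rel.)"),
            row("rho_h", p.profile.rho_h, "e/nm^3 (rel.)"),
            row("d", p.mct.d, "nm"),
            row("eta", p.mct.eta, ""),
            row("u", p.u, ""),
            f"  {'N':<12} {p.mct.N:>12d}  bilayers",
            "-" * 46,
            f"  chi2 = {self.chi2:.6g}   iterations = {self.n_iter}   converged = {self.converged}",
        ]
        return "\n".join(lines)


@dataclass
class DensityProfile:
    """Relative electron density versus distance from the bilayer midplane."""

    z: np.ndarray
    rho: np.ndarray
    D_HH: float | None

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.z, self.rho)
        ax.set_xlabel("z (nm)")
        ax.set_ylabel(r"$\Delta\rho$ (rel.)")
        if self.D_HH is not None:
            ax.axvline(self.D_HH / 2, ls="--", lw=0.8)
            ax.axvline(-self.D_HH / 2, ls="--", lw=0.8)
        return ax


# ---------------------------------------------------------------------------
# model evaluation


def convert_units(curve: SAXSCurve) -> SAXSCurve:
    """Return the curve with q on the canonical nm^-1 scale (idempotent)."""
    if curve.unit_in == "nm^-1":
        return curve
    # 1 A^-1 = 10 nm^-1
    return SAXSCurve(q=curve.q * 10.0, I=curve.I, sigma=curve.sigma, unit_in="nm^-1")


def form_amplitude(q: np.ndarray | float, p: StepProfileParams) -> np.ndarray | float:
    """Fourier amplitude F(q) of the symmetric three-strip density profile.

    F(q) = (2/q) [rho_m sin(q z_m) + rho_c (sin(q z_c) - sin(q z_m))
                  + rho_h (sin(q z_h) - sin(q z_c))]

    The transverse form factor is P_t(q) = F(q)^2.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    s_m = np.sin(q * p.z_m)
    s_c = np.sin(q * p.z_c)
    s_h = np.sin(q * p.z_h)
    out = (2.0 / q) * (p.rho_m * s_m + p.rho_c * (s_c - s_m) + p.rho_h * (s_h - s_c))
    return out if out.ndim else float(out)


def s_mct(q: np.ndarray | float, p: MCTParams) -> np.ndarray | float:
    """Modified Caille theory structure factor of an N-bilayer stack.

    S(q) = N + 2 sum_{k=1}^{N-1} (N-k) cos(k q d)
               * exp(-(d/2pi)^2 q^2 eta gamma_E) * (pi k)^(-(d/2pi)^2 q^2 eta)

    with gamma_E the Euler-Mascheroni constant.  For N = 1 the stack carries
    no interference and S = 1 identically.
    """
    q = np.asarray(q, dtype=float)
    if p.N == 1:
        out = np.ones_like(q)
        return out if out.ndim else 1.0
    alpha = (p.d / (2.0 * np.pi)) ** 2 * q**2 * p.eta  # Caille exponent
    out = np.full_like(q, float(p.N))
    damp = np.exp(-alpha * EULER_GAMMA)
    for k in range(1, p.N):
        out = out + 2.0 * (p.N - k) * np.cos(k * q * p.d) * damp * (np.pi * k) ** (-alpha)
    return out if out.ndim else float(out)


def intensity_model(q_grid: np.ndarray, params: LamellarModelParams) -> np.ndarray:
    """Model intensity kappa*(2piA/q^2)*P_t(q)*[u + (1-u)*S_MCT(q)]."""
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q grid must be strictly positive")
    F = form_amplitude(q, params.profile)
    Pt = F * F
    S = s_mct(q, params.mct)
    return params.scale / q**2 * Pt * (params.u + (1.0 - params.u) * S)


def d_from_peak(q_peak: float) -> float:
    """Lamellar repeat distance d = 2 pi / q_peak (nm for q in nm^-1)."""
    if q_peak <= 0:
        raise ValueError("q_peak must be positive")
    return 2.0 * np.pi / q_peak


def find_peaks(curve: SAXSCurve, prominence: float = 0.05) -> list[float]:
    """Peak positions of the Lorentz-corrected intensity I*q^2.

    ``prominence`` is relative to the dynamic range of I*q^2.  Peaks are
    refined to sub-grid precision by parabolic interpolation on log(I*q^2).
    """
    curve = convert_units(curve)
    y = curve.I * curve.q**2
    span = float(np.ptp(y))
    if span <= 0:
        return []
    idx, _ = signal.find_peaks(y, prominence=prominence * span)
    out = []
    for i in idx:
        if 0 < i < len(y) - 1 and np.all(y[i - 1 : i + 2] > 0):
            # parabolic vertex through the three log-ordinates
            la, lb, lc = np.log(y[i - 1 : i + 2])
            denom = la - 2 * lb + lc
            shift = 0.5 * (la - lc) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            q_ref = np.interp(i + shift, np.arange(len(y)), curve.q)
            out.append(float(q_ref))
        else:
            out.append(float(curve.q[i]))
    return out


def density_profile(
    p: StepProfileParams, z_grid: np.ndarray, smooth_sigma: float = 0.0
) -> DensityProfile:
    """Piecewise-constant density contrast on z_grid, mirrored about z = 0.

    ``smooth_sigma`` (nm) applies a Gaussian kernel for display.  D_HH is the
    separation of the two headgroup maxima; it is None for a flat profile.
    """
    z = np.asarray(z_grid, dtype=float)
    if not np.allclose(z, -z[::-1], atol=1e-9):
        raise ValueError("z_grid must be symmetric about 0")
    az = np.abs(z)
    rho = np.where(
        az < p.z_m, p.rho_m, np.where(az < p.z_c, p.rho_c, np.where(az < p.z_h, p.rho_h, 0.0))
    ).astype(float)
    if smooth_sigma > 0:
        dz = z[1] - z[0]
        rho = ndimage.gaussian_filter1d(rho, smooth_sigma / dz, mode="nearest")
    if np.ptp(rho) == 0:
        return DensityProfile(z=z, rho=rho, D_HH=None)
    pos = z > 0
    i_max = np.argmax(rho[pos])
    z_peak = z[pos][i_max]
    return DensityProfile(z=z, rho=rho, D_HH=float(2.0 * z_peak))


# ---------------------------------------------------------------------------
# fitting

_FREE_PARAMS = ("scale", "z_m", "z_c", "z_h", "rho_m", "rho_c", "rho_h", "d", "eta", "u")

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "scale": (1e-12, 1e12),
    "z_m": (0.01, 3.0),
    "z_c": (0.05, 4.0),
    "z_h": (0.1, 5.0),
    "rho_m": (-1000.0, 1000.0),
    "rho_c": (-1000.0, 1000.0),
    "rho_h": (-1000.0, 1000.0),
    "d": (1.0, 100.0),
    "eta": (0.0, 2.0),
    "u": (0.0, 1.0),
}


def _params_to_vector(params: LamellarModelParams) -> dict[str, float]:
    return {
        "scale": params.scale,
        "z_m": params.profile.z_m,
        "z_c": params.profile.z_c,
        "z_h": params.profile.z_h,
        "rho_m": params.profile.rho_m,
        "rho_c": params.profile.rho_c,
        "rho_h": params.profile.rho_h,
        "d": params.mct.d,
        "eta": params.mct.eta,
        "u": params.u,
    }


def _vector_to_params(v: Mapping[str, float], N: int) -> LamellarModelParams:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = StepProfileParams(
            z_m=v["z_m"], z_c=v["z_c"], z_h=v["z_h"],
            rho_m=v["rho_m"], rho_c=v["rho_c"], rho_h=v["rho_h"],
        )
    return LamellarModelParams(
        kappa=v["scale"] / (2.0 * np.pi),
        area=1.0,
        profile=profile,
        mct=MCTParams(N=N, d=v["d"], eta=v["eta"]),
        u=v["u"],
    )


class LamellarSAXSModel:
    """Weighted least-squares fitter for the lamellar intensity model.

    Parameters
    ----------
    curve
        Observed scattering curve; converted to canonical nm^-1 units.
        Residuals are weighted by ``sigma`` when present, else by
        ``sqrt(I_obs)`` (Poisson-like weighting); only relative weights
        matter.

    The number of correlated bilayers N is an integer searched exhaustively
    over ``n_range``; all remaining parameters are refined by bounded
    trust-region least squares with multi-start jitter around the supplied
    initial guess.
    """

    def __init__(self, curve: SAXSCurve):
        self.curve = convert_units(curve)
        if self.curve.sigma is not None:
            w = np.asarray(self.curve.sigma, dtype=float)
            if np.any(w <= 0):
                raise ValueError("sigma weights must be positive")
        else:
            w = np.sqrt(np.clip(self.curve.I, 1e-30, None))
        self._weights = w

    @classmethod
    def from_file(cls, path, unit_in: str = "nm^-1") -> "LamellarSAXSModel":
        from .io import read_saxs_curve

        return cls(read_saxs_curve(path, unit_in=unit_in))

    # -- objective ---------------------------------------------------------

    def _residuals(self, x: np.ndarray, free: Sequence[str], fixed: Mapping[str, float], N: int):
        v = dict(fixed)
        v.update(zip(free, x))
        # enforce strip ordering softly: invalid geometry -> huge residual
        if not (0 < v["z_m"] < v["z_c"] < v["z_h"]):
            return np.full(len(self.curve.q), 1e8)
        if v["scale"] <= 0 or v["d"] <= 0 or v["eta"] < 0 or not (0 <= v["u"] <= 1):
            return np.full(len(self.curve.q), 1e8)
        params = _vector_to_params(v, N)
        model = intensity_model(self.curve.q, params)
        res = (self.curve.I - model) / self._weights
        if not np.all(np.isfinite(res)):
            return np.full(len(self.curve.q), 1e8)
        return res

    def fit(
        self,
        init: LamellarModelParams,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        fix: Iterable[str] = (),
        n_range: tuple[int, int] = (1, 5),
        n_starts: int = 8,
        seed: int = 0,
    ) -> FitResult:
        """Fit the model; returns a :class:`FitResult`.

        ``fix`` names parameters held at their ``init`` value (e.g. ``{"u"}``).
        ``n_range`` is the inclusive integer range searched for N.
        """
        fix = set(fix)
        unknown = fix - set(_FREE_PARAMS) - {"N"}
        if unknown:
            raise ValueError(f"unknown parameter names in fix: {sorted(unknown)}")
        v0 = _params_to_vector(init)
        free = [name for name in _FREE_PARAMS if name not in fix]
        fixed = {name: v0[name] for name in fix if name != "N"}
        bnds = dict(_DEFAULT_BOUNDS)
        if bounds:
            bnds.update(bounds)
        lo = np.array([bnds[n][0] for n in free])
        hi = np.array([bnds[n][1] for n in free])
        x0 = np.array([v0[n] for n in free])
        for n, xi in zip(free, x0):
            if not (bnds[n][0] <= xi <= bnds[n][1]):
                raise ValueError(f"init for {n} outside bounds")

        rng = np.random.default_rng(seed)
        n_values = (
            [init.mct.N]
            if "N" in fix
            else list(range(n_range[0], n_range[1] + 1))
        )

        best = None
        total_nfev = 0
        for N in n_values:
            starts = [x0]
            for _ in range(max(0, n_starts - 1)):
                jit = x0 * (1.0 + rng.uniform(-0.2, 0.2, size=x0.shape))
                starts.append(np.clip(jit, lo, hi))
            for x_start in starts:
                try:
                    sol = optimize.least_squares(
                        self._residuals,
                        x_start,
                        args=(free, fixed, N),
                        bounds=(lo, hi),
                        method="trf",
                        x_scale="jac",
                        max_nfev=2000,
                    )
                except Exception:
                    continue
                total_nfev += sol.nfev
                chi2 = float(2.0 * sol.cost)
                if best is None or chi2 < best[0]:
                    best = (chi2, sol, N)

        if best is None:
            raise RuntimeError("lamellar fit failed: no optimiser run produced finite residuals")

        chi2, sol, N = best
        v = dict(fixed)
        v.update(zip(free, sol.x))
        params = _vector_to_params(v, N)

        # covariance from the Jacobian at the optimum (sigma-weighted residuals)
        cov = None
        try:
            J = sol.jac
            dof = max(len(self.curve.q) - len(free), 1)
            s2 = chi2 / dof
            cov = s2 * np.linalg.pinv(J.T @ J)
        except Exception:
            cov = None

        # honest convergence: optimiser success AND chi2 meaningfully below
        # the no-model floor (variance of the weighted data)
        y_w = self.curve.I / self._weights
        floor = float(np.sum((y_w - y_w.mean()) ** 2))
        converged = bool(sol.status > 0 and chi2 < 0.5 * floor)

        return FitResult(
            params=params,
            chi2=chi2,
            n_iter=int(total_nfev),
            converged=converged,
            covariance=cov,
            param_names=tuple(free),
            _model=self,
        )


def fit_curve(
    curve: SAXSCurve,
    init: LamellarModelParams,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fix: Iterable[str] = (),
    n_range: tuple[int, int] = (1, 5),
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Functional wrapper around :meth:`LamellarSAXSModel.fit`."""
    return LamellarSAXSModel(curve).fit(
        init, bounds=bounds, fix=fix, n_range=n_range, n_starts=n_starts, seed=seed
    )
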