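"""Synthetic fixtures with known ground truth for every analysis stage.

Each generator is deterministic given its seed and emulates the statistical
structure its analysis assumes, not the instrument physics:

* GUV micrographs: a bright ring on a dark background, optionally carrying
  angular protrusion sectors that break point symmetry (no phase-contrast
  optics, no polydispersity).
* SAXS curves: the lamellar intensity model evaluated on a q grid with
  optional relative Gaussian noise.
* Laurdan spectra: two Gaussian emission bands near 440 and 490 nm.
* Headgroup trajectories: per-lipid two-state (flipped-out / flipped-in)
  first-order Markov chains driving the O-P bond orientation; the true state
  sequence is returned next to the coordinates so recovery tests are
  self-contained.
* Titrations: the monoprotic protonation isotherm plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .guv import GrayImage
from .saxs import LamellarModelParams, SAXSCurve, intensity_model
from .spectra import EmissionSpectrum, protonation_fraction
from .trajectory import HeadgroupTrajectory

__all__ = [
    "GUVImageSpec",
    "SAXSSimSpec",
    "SpectrumSimSpec",
    "FlipTrajectorySpec",
    "TitrationSimSpec",
    "gen_guv_image",
    "gen_saxs_curve",
    "gen_spectrum",
    "gen_flip_trajectory",
    "gen_titration",
]


# ---------------------------------------------------------------------------
# GUV images


@dataclass(frozen=True)
class GUVImageSpec:
    """Synthetic phase-contrast vesicle image.

    ``protrusions`` is a list of (angular_position_deg, angular_span_deg,
    radial_fraction, contrast) sectors added over the outer
    ``radial_fraction`` of the radius on one side of the vesicle only.
    An integer-pixel ``center`` makes the noise-free image exactly
    point-symmetric (the pixel grid mirrors onto itself).
    """

    width: int = 512
    height: int = 512
    center: tuple[float, float] | None = None
    radius: float = 150.0
    ring_contrast: float = 0.8
    ring_width: float = 2.0
    background: float = 0.1
    noise_sigma: float = 0.0
    protrusions: tuple[tuple[float, float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.center is None:
            object.__setattr__(self, "center", (self.width // 2, self.height // 2))
        object.__setattr__(self, "protrusions", tuple(tuple(p) for p in self.protrusions))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.ring_contrast <= 1:
            raise ValueError("ring_contrast must lie in [0, 1]")
        for pos, span, rf, contrast in self.protrusions:
            if not (0 < rf <= 1):
                raise ValueError("protrusion radial_fraction must lie in (0, 1]")
            if not (0 <= contrast <= 1):
                raise ValueError("protrusion contrast must lie in [0, 1]")
            if span <= 0:
                raise ValueError("protrusion angular span must be positive")
        cx, cy = self.center
        margin = self.radius + 3 * self.ring_width
        if (cx - margin < 0 or cy - margin < 0
                or cx + margin > self.width - 1 or cy + margin > self.height - 1):
            raise ValueError(
                "vesicle circle (plus ring width) extends outside the image frame"
            )
        if self.radius >= min(self.width, self.height) / 2:
            raise ValueError("radius must be smaller than half the frame")


def gen_guv_image(spec: GUVImageSpec) -> GrayImage:
    """Render the vesicle image on the [0, 1] intensity scale."""
    y, x = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    cx, cy = spec.center
    dx, dy = x - cx, y - cy
    rho = np.hypot(dx, dy)
    img = np.full((spec.height, spec.width), spec.background)
    img += spec.ring_contrast * np.exp(-0.5 * ((rho - spec.radius) / spec.ring_width) ** 2)
    if spec.protrusions:
        ang = np.degrees(np.arctan2(dy, dx)) % 360.0
        for pos, span, rf, contrast in spec.protrusions:
            in_sector = ((ang - pos) % 360.0) <= span
            in_annulus = (rho >= (1.0 - rf) * spec.radius) & (rho <= spec.radius)
            img[in_sector & in_annulus] += contrast
    img = np.clip(img, 0.0, 1.0)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(img + rng.normal(0.0, spec.noise_sigma, img.shape), 0.0, 1.0)
    return GrayImage(pixels=img)


# ---------------------------------------------------------------------------
# SAXS curves


@dataclass(frozen=True)
class SAXSSimSpec:
    """Lamellar model curve on ``q_grid`` (nm^-1) with optional noise.

    ``noise_model`` is ``"none"`` or ``("gaussian_relative", fraction)``:
    multiplicative Gaussian noise of the given relative amplitude, with the
    sigma column recording the applied scale.
    """

    model: LamellarModelParams
    q_grid: np.ndarray
    noise_model: str | tuple[str, float] = "none"
    seed: int = 0

    def __post_init__(self):
        q = np.asarray(self.q_grid, dtype=float)
        object.__setattr__(self, "q_grid", q)
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q_grid must be strictly increasing and positive")
        if self.noise_model != "none":
            kind, frac = self.noise_model
            if kind != "gaussian_relative" or frac <= 0:
                raise ValueError("noise_model must be 'none' or ('gaussian_relative', f>0)")


def gen_saxs_curve(spec: SAXSSimSpec) -> SAXSCurve:
    I = intensity_model(spec.q_grid, spec.model)
    if spec.noise_model == "none":
        return SAXSCurve(q=spec.q_grid, I=I, sigma=None, unit_in="nm^-1")
    _, frac = spec.noise_model
    rng = np.random.default_rng(spec.seed)
    sigma = frac * I
    I_noisy = I + sigma * rng.standard_normal(I.shape)
    return SAXSCurve(q=spec.q_grid, I=I_noisy, sigma=sigma, unit_in="nm^-1")


# ---------------------------------------------------------------------------
# emission spectra


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Two-Gaussian Laurdan-like emission spectrum on a nm grid (370-600)."""

    band_centers: tuple[float, float] = (440.0, 490.0)
    band_widths: tuple[float, float] = (25.0, 25.0)
    band_amplitudes: tuple[float, float] = (1.0, 1.0)
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(370.0, 600.5, 1.0)
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        wl = np.asarray(self.wavelength_grid, dtype=float)
        object.__setattr__(self, "wavelength_grid", wl)
        if any(a < 0 for a in self.band_amplitudes):
            raise ValueError("band amplitudes must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def gen_spectrum(spec: SpectrumSimSpec) -> EmissionSpectrum:
    wl = spec.wavelength_grid
    it = np.zeros_like(wl)
    for c, w, a in zip(spec.band_centers, spec.band_widths, spec.band_amplitudes):
        it = it + a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        it = it + rng.normal(0.0, spec.noise_sigma, it.shape)
    return EmissionSpectrum(wavelength=wl, intensity=it)


# ---------------------------------------------------------------------------
# headgroup flip trajectories


@dataclass(frozen=True)
class FlipTrajectorySpec:
    """Two-state Markov flip dynamics driving O-P bond orientations.

    Per frame, an out-state lipid flips in with probability ``p_in`` and an
    in-state lipid flips out with probability ``p_out`` (stationary
    flipped-in fraction p_in / (p_in + p_out)).  In the out state both
    O11->P and O12->P bonds point along +z with z-magnitude ``z_offset``
    (nm); in the in state along -z.  ``angular_noise`` (deg) tilts each bond
    independently.  All lipids sit in the upper leaflet of the box.
    """

    n_lipids: int = 64
    n_frames: int = 200
    p_in: float = 0.1
    p_out: float = 0.1
    z_offset: float = 0.15
    angular_noise: float = 5.0
    box: tuple[float, float, float] = (6.4, 6.4, 10.0)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_in <= 1 and 0 <= self.p_out <= 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.z_offset <= 0:
            raise ValueError("z_offset must be positive")
        if self.n_lipids < 1 or self.n_frames < 1:
            raise ValueError("need at least one lipid and one frame")


def _tilted_bonds(rng, n, z_offset, sign, angular_noise):
    """Bond vectors of length z_offset along sign*z, tilted by Gaussian noise."""
    alpha = np.abs(rng.normal(0.0, np.deg2rad(angular_noise), n)) if angular_noise > 0 else np.zeros(n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return z_offset * np.column_stack(
        [np.sin(alpha) * np.cos(phi), np.sin(alpha) * np.sin(phi), sign * np.cos(alpha)]
    )


def gen_flip_trajectory(spec: FlipTrajectorySpec) -> tuple[HeadgroupTrajectory, np.ndarray]:
    """Returns (trajectory, true_states); states are 0 = out, 1 = in."""
    rng = np.random.default_rng(spec.seed)
    n_l, n_f = spec.n_lipids, spec.n_frames
    lx, ly, lz = spec.box

    # initial states from the stationary distribution (all-out if unreachable)
    if spec.p_in + spec.p_out > 0:
        f_in = spec.p_in / (spec.p_in + spec.p_out)
    else:
        f_in = 0.0
    states = np.zeros((n_f, n_l), dtype=int)
    states[0] = (rng.random(n_l) < f_in).astype(int)
    for t in range(1, n_f):
        u = rng.random(n_l)
        prev = states[t - 1]
        flip_to_in = (prev == 0) & (u < spec.p_in)
        flip_to_out = (prev == 1) & (u < spec.p_out)
        states[t] = np.where(flip_to_in, 1, np.where(flip_to_out, 0, prev))

    # lipids on an xy grid in the upper leaflet
    n_side = int(np.ceil(np.sqrt(n_l)))
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    xy = np.column_stack([gx.ravel(), gy.ravel()])[:n_l].astype(float)
    xy[:, 0] *= lx / n_side
    xy[:, 1] *= ly / n_side
    p_z = 0.75 * lz

    coords = np.empty((n_f, n_l, 3, 3))
    sign = np.where(states == 0, 1.0, -1.0)  # out -> bond along +z
    for t in range(n_f):
        P = np.column_stack([xy[:, 0], xy[:, 1], np.full(n_l, p_z)])
        b1 = _tilted_bonds(rng, n_l, spec.z_offset, sign[t], spec.angular_noise)
        b2 = _tilted_bonds(rng, n_l, spec.z_offset, sign[t], spec.angular_noise)
        coords[t, :, 0, :] = P
        coords[t, :, 1, :] = P - b1  # O11 such that O11->P = b1
        coords[t, :, 2, :] = P - b2
    traj = HeadgroupTrajectory(
        atom_labels=("P", "O11", "O12"),
        coords=coords,
        box=np.tile(np.array(spec.box, dtype=float), (n_f, 1)),
        leaflet=np.ones(n_l, dtype=int),
    )
    return traj, states


# ---------------------------------------------------------------------------
# titrations


@dataclass(frozen=True)
class TitrationSimSpec:
    """Protonation isotherm samples: f(pH) = 1/(1+10^(pH-pKa)) + noise."""

    pKa_true: float = 3.5
    pH_grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 7.25, 0.25))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        ph = np.asarray(self.pH_grid, dtype=float)
        object.__setattr__(self, "pH_grid", ph)
        if np.any(ph < 0) or np.any(ph > 14):
            raise ValueError("pH grid must lie within [0, 14]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def gen_titration(spec: TitrationSimSpec) -> np.ndarray:
    """(n, 2) array of (pH, protonated fraction), fractions clipped to [0, 1]."""
    f = protonation_fraction(spec.pH_grid, spec.pKa_true)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sigma, f.shape)
    return np.column_stack([spec.pH_grid, np.clip(f, 0.0, 1.0)])
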