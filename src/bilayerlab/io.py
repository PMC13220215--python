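"""Readers and writers for the plain-text and image formats the analyses use.

* Grayscale images: TIFF/PNG, 8- or 16-bit or float, mapped onto [0, 1].
* Scattering curves and spectra: whitespace/comma-delimited ASCII columns
  with ``#`` comments (``q I [sigma]`` / ``wavelength intensity``).
* Headgroup trajectories: a frame-block text layout --

      # bilayerlab trajectory v1
      frame 0
      box Lx Ly Lz
      <lipid_id> <atom_label> <x> <y> <z>
      ...
      frame 1
      ...

  with coordinates in nm; every lipid carries the same labelled atoms in
  every frame.  Standard MD formats can be converted through MDAnalysis
  (:func:`trajectory_from_mdanalysis`).
"""

from __future__ import annotations

import numpy as np

from .guv import GrayImage
from .saxs import SAXSCurve
from .spectra import EmissionSpectrum
from .trajectory import HeadgroupTrajectory

__all__ = [
    "read_image",
    "write_image",
    "read_saxs_curve",
    "write_saxs_curve",
    "read_spectrum",
    "write_trajectory",
    "read_trajectory",
    "trajectory_from_mdanalysis",
]


def read_image(path, pixel_size: float | None = None) -> GrayImage:
    """Load a TIFF/PNG image as a [0, 1] grayscale raster."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse colour channels
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max() <= 1.0:
        scale = 1.0
    elif arr.max() > 255:
        scale = 65535.0
    else:
        scale = 255.0
    return GrayImage(pixels=arr / scale, pixel_size=pixel_size)


def write_image(path, image: GrayImage) -> None:
    """Write a [0, 1] image as 16-bit TIFF or 8-bit PNG by extension."""
    path = str(path)
    px = np.clip(image.pixels, 0.0, 1.0)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, (px * 65535).astype(np.uint16))
    else:
        from PIL import Image

        Image.fromarray((px * 255).astype(np.uint8)).save(path)


def _load_columns(path) -> np.ndarray:
    return np.loadtxt(path, comments="#", delimiter=None)


def read_saxs_curve(path, unit_in: str = "nm^-1") -> SAXSCurve:
    """Read a 2- or 3-column ASCII curve (q, I, optional sigma)."""
    data = np.atleast_2d(_load_columns(path))
    if data.shape[1] < 2:
        raise ValueError("expected at least two columns: q I [sigma]")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(q=data[:, 0], I=data[:, 1], sigma=sigma, unit_in=unit_in)


def write_saxs_curve(path, curve: SAXSCurve) -> None:
    cols = [curve.q, curve.I]
    header = f"q ({curve.unit_in}) I"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header)


def read_spectrum(path, label=None) -> EmissionSpectrum:
    """Read a 2-column ASCII emission spectrum (wavelength nm, intensity)."""
    data = np.atleast_2d(_load_columns(path))
    if data.shape[1] < 2:
        raise ValueError("expected two columns: wavelength intensity")
    return EmissionSpectrum(wavelength=data[:, 0], intensity=data[:, 1], label=label)


# ---------------------------------------------------------------------------
# trajectory text format


def write_trajectory(path, traj: HeadgroupTrajectory) -> None:
    with open(path, "w") as fh:
        fh.write("# bilayerlab trajectory v1\n")
        fh.write("# columns: lipid_id atom_label x y z (nm)\n")
        for t in range(traj.n_frames):
            fh.write(f"frame {t}\n")
            fh.write("box {:.6f} {:.6f} {:.6f}\n".format(*traj.box[t]))
            for l in range(traj.n_lipids):
                for a, lbl in enumerate(traj.atom_labels):
                    x, y, z = traj.coords[t, l, a]
                    fh.write(f"{l} {lbl} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(path, leaflet: np.ndarray | None = None) -> HeadgroupTrajectory:
    frames: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "frame":
                current = {"box": None, "atoms": {}}
                frames.append(current)
            elif parts[0] == "box":
                if current is None:
                    raise ValueError("box line before any frame line")
                current["box"] = tuple(float(v) for v in parts[1:4])
            else:
                if current is None or current["box"] is None:
                    raise ValueError("atom line before frame/box lines")
                lid = int(parts[0])
                lbl = parts[1]
                xyz = tuple(float(v) for v in parts[2:5])
                current["atoms"].setdefault(lid, {})[lbl] = xyz
    if not frames:
        raise ValueError("no frames in trajectory file")
    lipid_ids = sorted(frames[0]["atoms"])
    labels = tuple(frames[0]["atoms"][lipid_ids[0]])
    coords = np.empty((len(frames), len(lipid_ids), len(labels), 3))
    box = np.empty((len(frames), 3))
    for t, fr in enumerate(frames):
        box[t] = fr["box"]
        for li, lid in enumerate(lipid_ids):
            atoms = fr["atoms"][lid]
            for ai, lbl in enumerate(labels):
                coords[t, li, ai] = atoms[lbl]
    return HeadgroupTrajectory(atom_labels=labels, coords=coords, box=box, leaflet=leaflet)


def trajectory_from_mdanalysis(
    universe, label_selections: dict[str, str], lipid_selection: str = "all",
    leaflet: np.ndarray | None = None,
) -> HeadgroupTrajectory:
    """Build a labelled headgroup trajectory from an MDAnalysis Universe.

    ``label_selections`` maps each atom label (e.g. "P", "O11") to an
    MDAnalysis selection string resolving to exactly one atom per lipid
    residue of ``lipid_selection``.  MDAnalysis coordinates (Angstrom) are
    converted to nm.
    """
    lipids = universe.select_atoms(lipid_selection).residues
    labels = tuple(label_selections)
    groups = {}
    for lbl, sel in label_selections.items():
        ag = lipids.atoms.select_atoms(sel)
        if len(ag) != len(lipids):
            raise ValueError(f"selection for {lbl!r} must match one atom per lipid")
        groups[lbl] = ag
    n_frames = len(universe.trajectory)
    coords = np.empty((n_frames, len(lipids), len(labels), 3))
    box = np.empty((n_frames, 3))
    for t, _ in enumerate(universe.trajectory):
        box[t] = universe.dimensions[:3] / 10.0
        for ai, lbl in enumerate(labels):
            coords[t, :, ai, :] = groups[lbl].positions / 10.0
    return HeadgroupTrajectory(atom_labels=labels, coords=coords, box=box, leaflet=leaflet)
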