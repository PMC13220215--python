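"""Headgroup flip-state classification and bilayer observables from MD frames.

A phosphoglycerolipid's phosphate can orient its phosphorus either toward the
solvent ("flipped-out") or toward the hydrophobic core ("flipped-in").  The
orientation is read from the two ester-oxygen-to-phosphorus bonds: for each
bond the signed cosine of its angle to the bilayer normal (z axis) is

    cos(theta) = (P_z - O_z) / |P - O|

(+1 for a bond parallel to +z, -1 antiparallel).  A lipid-frame is
flipped-out when both O11-P and O12-P cosines are positive, flipped-in when
both are negative, and unclassified for mixed signs.

The module also computes the standard bilayer observables used alongside the
flip analysis: z-displacement occurrence histograms, intramolecular acyl
chain-pair distances, geometric hydrogen-bond counts, number-density
profiles, area/volume per lipid and head-to-head thickness, deuterium order
parameters S_CD, and medoid (representative) conformations by pairwise RMSD.

All coordinates are in nm; periodic boundaries are honoured by the
minimum-image convention in every interatomic distance.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import numpy as np
from MDAnalysis.analysis.rms import rmsd as _mda_rmsd

__all__ = [
    "HeadgroupTrajectory",
    "FlipState",
    "FlipPopulations",
    "HBondCriteria",
    "BilayerMetrics",
    "bond_cos_z",
    "classify_flip",
    "flip_cosines",
    "flip_populations",
    "headgroup_zdisp_hist",
    "chain_pair_distance_profile",
    "count_hbonds",
    "density_profile",
    "bilayer_metrics",
    "order_parameter_scd",
    "representative_conformation",
]


class FlipState(enum.Enum):
    FLIPPED_OUT = "flipped_out"
    FLIPPED_IN = "flipped_in"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HeadgroupTrajectory:
    """Labelled per-lipid atom coordinates over frames, with box dimensions.

    ``coords`` has shape (n_frames, n_lipids, n_atoms, 3) in nm, with
    ``atom_labels`` naming the atom slots consistently across lipids and
    frames (e.g. "P", "O11", "O12", "C1A".."C9A", "C1B".."C9B").
    ``leaflet`` optionally tags each lipid +1 (upper) or -1 (lower); when
    absent, leaflets are assigned per frame from the lipid mean z relative
    to the bilayer midplane.
    """

    atom_labels: tuple[str, ...]
    coords: np.ndarray
    box: np.ndarray
    leaflet: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        box = np.asarray(self.box, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        if coords.ndim != 4 or coords.shape[3] != 3:
            raise ValueError("coords must have shape (n_frames, n_lipids, n_atoms, 3)")
        if coords.shape[2] != len(self.atom_labels):
            raise ValueError("atom_labels must match the atom axis of coords")
        if box.shape != (coords.shape[0], 3) or np.any(box <= 0):
            raise ValueError("box must be (n_frames, 3) and positive")
        if self.leaflet is not None:
            lf = np.asarray(self.leaflet)
            object.__setattr__(self, "leaflet", lf)
            if lf.shape != (coords.shape[1],):
                raise ValueError("leaflet must be one tag per lipid")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.coords.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.atom_labels.index(label)
        except ValueError:
            raise KeyError(f"atom label {label!r} not present in trajectory") from None

    def atom(self, label: str) -> np.ndarray:
        """Coordinates of one labelled atom: shape (n_frames, n_lipids, 3)."""
        return self.coords[:, :, self.index(label), :]


@dataclass
class FlipPopulations:
    """Per-frame and trajectory-mean flip-state fractions with binomial SE."""

    fraction_out: np.ndarray
    fraction_in: np.ndarray
    fraction_unclassified: np.ndarray
    mean_out: float
    mean_in: float
    mean_unclassified: float
    se_out: float
    se_in: float


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: distance and angle cutoffs.

    ``angle_convention`` selects which angle the cutoff applies to:
    "HDA" (hydrogen-donor-acceptor, the common trajectory-analysis choice)
    or "DHA" (donor-hydrogen-acceptor, cutoff then means angle >= 180-cutoff
    from linearity and is interpreted as deviation from 180 degrees).
    """

    distance_cutoff: float = 0.35  # nm, donor-acceptor
    angle_cutoff: float = 35.0     # degrees
    angle_convention: str = "HDA"

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_convention not in ("HDA", "DHA"):
            raise ValueError("angle_convention must be 'HDA' or 'DHA'")


@dataclass(frozen=True)
class BilayerMetrics:
    A_L: float   # area per lipid, nm^2
    V_L: float   # volume per lipid, nm^3
    D_HH: float  # head-to-head thickness, nm


# ---------------------------------------------------------------------------
# flip-state classification


def bond_cos_z(P, O) -> float:
    """Signed cosine of the O->P bond angle to the z axis.

    Magnitude |OP_z| / |OP|, sign taken from the z component: +1 when the
    bond points exactly along +z, -1 along -z, 0 in the xy plane.
    """
    v = np.asarray(P, dtype=float) - np.asarray(O, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm == 0):
        raise ValueError("zero-length O-P bond")
    out = v[..., 2] / norm
    return float(out) if np.ndim(out) == 0 else out


def classify_flip(cos1: float, cos2: float) -> FlipState:
    """Flip state from the two bond cosines (O11-P, O12-P)."""
    for c in (cos1, cos2):
        if not -1.0 <= c <= 1.0:
            raise ValueError("cosines must lie in [-1, 1]")
    if cos1 > 0 and cos2 > 0:
        return FlipState.FLIPPED_OUT
    if cos1 < 0 and cos2 < 0:
        return FlipState.FLIPPED_IN
    return FlipState.UNCLASSIFIED


def flip_cosines(
    traj: HeadgroupTrajectory,
    p_label: str = "P",
    o_labels: tuple[str, str] = ("O11", "O12"),
) -> tuple[np.ndarray, np.ndarray]:
    """Bond cosines for every lipid-frame: two (n_frames, n_lipids) arrays."""
    P = traj.atom(p_label)
    return tuple(bond_cos_z(P, traj.atom(o)) for o in o_labels)


def _leaflet_mask(traj: HeadgroupTrajectory, leaflet: str) -> np.ndarray:
    """Boolean (n_frames, n_lipids) mask selecting the requested leaflet."""
    if leaflet not in ("upper", "lower", "both"):
        raise ValueError("leaflet must be 'upper', 'lower' or 'both'")
    if leaflet == "both":
        return np.ones(traj.coords.shape[:2], dtype=bool)
    if traj.leaflet is not None:
        per_lipid = traj.leaflet > 0 if leaflet == "upper" else traj.leaflet < 0
        return np.broadcast_to(per_lipid, traj.coords.shape[:2]).copy()
    # derive per frame: lipid mean z vs bilayer midplane (mean z of all atoms)
    lipid_z = traj.coords[..., 2].mean(axis=2)            # (n_frames, n_lipids)
    midplane = lipid_z.mean(axis=1, keepdims=True)
    return lipid_z >= midplane if leaflet == "upper" else lipid_z < midplane


def flip_populations(
    traj: HeadgroupTrajectory,
    leaflet: str = "upper",
    p_label: str = "P",
    o_labels: tuple[str, str] = ("O11", "O12"),
) -> FlipPopulations:
    """Flip-state fractions over the selected leaflet, per frame and overall.

    The standard error on the mean fractions is binomial,
    sqrt(p (1-p) / n_obs) with n_obs the total selected lipid-frames.
    """
    c1, c2 = flip_cosines(traj, p_label, o_labels)
    mask = _leaflet_mask(traj, leaflet)
    if not mask.any():
        raise ValueError(f"no lipids selected in leaflet {leaflet!r}")
    out = (c1 > 0) & (c2 > 0) & mask
    inn = (c1 < 0) & (c2 < 0) & mask
    n_sel = mask.sum(axis=1).astype(float)            # per frame
    with np.errstate(invalid="ignore"):
        f_out = out.sum(axis=1) / n_sel
        f_in = inn.sum(axis=1) / n_sel
    f_un = 1.0 - f_out - f_in
    n_tot = float(mask.sum())
    p_out, p_in = float(out.sum() / n_tot), float(inn.sum() / n_tot)
    return FlipPopulations(
        fraction_out=f_out,
        fraction_in=f_in,
        fraction_unclassified=f_un,
        mean_out=p_out,
        mean_in=p_in,
        mean_unclassified=1.0 - p_out - p_in,
        se_out=float(np.sqrt(p_out * (1 - p_out) / n_tot)),
        se_in=float(np.sqrt(p_in * (1 - p_in) / n_tot)),
    )


def headgroup_zdisp_hist(
    traj: HeadgroupTrajectory,
    bins: int | np.ndarray = 50,
    leaflet: str = "both",
    p_label: str = "P",
    o_labels: tuple[str, str] = ("O11", "O12"),
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D occurrence histogram of (P-O11, P-O12) z displacements.

    Returns (counts, edges1, edges2); counts sum to the number of selected
    lipid-frames, or to 1 with ``normalize=True``.
    """
    P = traj.atom(p_label)
    dz1 = P[..., 2] - traj.atom(o_labels[0])[..., 2]
    dz2 = P[..., 2] - traj.atom(o_labels[1])[..., 2]
    mask = _leaflet_mask(traj, leaflet)
    H, e1, e2 = np.histogram2d(dz1[mask].ravel(), dz2[mask].ravel(), bins=bins)
    if normalize:
        H = H / H.sum()
    return H, e1, e2


# ---------------------------------------------------------------------------
# distances and hydrogen bonds


def minimum_image(dvec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in an orthorhombic box."""
    return dvec - box * np.round(dvec / box)


def _chain_labels(traj: HeadgroupTrajectory) -> tuple[list[str], list[str]]:
    pat = re.compile(r"^C(\d+)([AB])$")
    chains: dict[str, list[tuple[int, str]]] = {"A": [], "B": []}
    for lbl in traj.atom_labels:
        m = pat.match(lbl)
        if m:
            chains[m.group(2)].append((int(m.group(1)), lbl))
    a = [lbl for _, lbl in sorted(chains["A"])]
    b = [lbl for _, lbl in sorted(chains["B"])]
    return a, b


def chain_pair_distance_profile(
    traj: HeadgroupTrajectory,
    chain_a: list[str] | None = None,
    chain_b: list[str] | None = None,
) -> np.ndarray:
    """Mean distance between same-index carbons of a lipid's two acyl chains.

    Chains default to labels matching ``C<n>A`` / ``C<n>B`` sorted by index.
    Distances use the minimum-image convention; the result has one entry per
    carbon index, averaged over lipids and frames.
    """
    if chain_a is None or chain_b is None:
        chain_a, chain_b = _chain_labels(traj)
    if len(chain_a) != len(chain_b):
        raise ValueError("the two chains must have equal length")
    if not chain_a:
        raise ValueError("no chain atoms found")
    out = np.empty(len(chain_a))
    box = traj.box[:, None, :]                       # broadcast over lipids
    for n, (la, lb) in enumerate(zip(chain_a, chain_b)):
        d = minimum_image(traj.atom(la) - traj.atom(lb), box)
        out[n] = np.linalg.norm(d, axis=-1).mean()
    return out


def count_hbonds(
    traj: HeadgroupTrajectory,
    donors: list[tuple[str, str]],
    acceptors: list[str],
    criteria: HBondCriteria = HBondCriteria(),
) -> np.ndarray:
    """Per-frame geometric hydrogen-bond counts.

    ``donors`` are (donor, hydrogen) label pairs; ``acceptors`` are acceptor
    labels.  A bond is counted when the minimum-image donor-acceptor
    distance is within ``distance_cutoff`` and the angle criterion holds
    (default: hydrogen-donor-acceptor angle <= 35 degrees, i.e. the
    acceptor sits nearly along the O-H direction).  Donor/acceptor pairs
    range over all lipid pairs; an atom never bonds to its own donor.
    """
    for d_lbl, h_lbl in donors:
        traj.index(d_lbl), traj.index(h_lbl)  # raises on missing H / donor
    counts = np.zeros(traj.n_frames, dtype=int)
    deg = np.degrees
    for f in range(traj.n_frames):
        box = traj.box[f]
        for d_lbl, h_lbl in donors:
            D = traj.coords[f, :, traj.index(d_lbl), :]   # (n_lipids, 3)
            Hc = traj.coords[f, :, traj.index(h_lbl), :]
            for a_lbl in acceptors:
                A = traj.coords[f, :, traj.index(a_lbl), :]
                da = minimum_image(D[:, None, :] - A[None, :, :], box)
                dist = np.linalg.norm(da, axis=-1)        # (n_don, n_acc)
                same = (a_lbl == d_lbl) | (a_lbl == h_lbl)
                if same:
                    np.fill_diagonal(dist, np.inf)
                close = dist <= criteria.distance_cutoff
                if not close.any():
                    continue
                ii, jj = np.nonzero(close)
                dh = minimum_image(Hc[ii] - D[ii], box)
                if criteria.angle_convention == "HDA":
                    # angle at donor between D->H and D->A
                    v2 = -da[ii, jj]
                    cosang = np.sum(dh * v2, axis=-1) / (
                        np.linalg.norm(dh, axis=-1) * np.linalg.norm(v2, axis=-1)
                    )
                    ok = deg(np.arccos(np.clip(cosang, -1, 1))) <= criteria.angle_cutoff
                else:
                    # deviation from linearity of D-H...A at the hydrogen
                    ha = minimum_image(A[jj] - Hc[ii], box)
                    cosang = np.sum((-dh) * ha, axis=-1) / (
                        np.linalg.norm(dh, axis=-1) * np.linalg.norm(ha, axis=-1)
                    )
                    ang = deg(np.arccos(np.clip(cosang, -1, 1)))
                    ok = (180.0 - ang) <= criteria.angle_cutoff
                counts[f] += int(ok.sum())
    return counts


# ---------------------------------------------------------------------------
# profiles and bilayer metrics


def density_profile(
    traj: HeadgroupTrajectory,
    group: list[str],
    n_bins: int = 100,
    z_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-averaged number density of ``group`` atoms vs z, peak-normalised.

    z is measured per frame from the bilayer midplane (the mean z of all
    lipid atoms).  Returns (z_centers, density) with max(density) = 1.
    """
    if not group:
        raise ValueError("empty atom group")
    idx = [traj.index(lbl) for lbl in group]
    mid = traj.coords[..., 2].mean(axis=(1, 2))            # (n_frames,)
    z = (traj.coords[:, :, idx, 2] - mid[:, None, None]).ravel()
    if z_range is None:
        pad = 0.05 * max(np.ptp(z), 1e-9)
        z_range = (z.min() - pad, z.max() + pad)
    counts, edges = np.histogram(z, bins=n_bins, range=z_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts.astype(float)
    if dens.max() > 0:
        dens = dens / dens.max()
    return centers, dens


def bilayer_metrics(
    traj: HeadgroupTrajectory,
    n_lipids: int | None = None,
    n_waters: int = 0,
    water_volume: float = 0.03017,
    head_label: str = "P",
    n_bins: int = 100,
) -> BilayerMetrics:
    """Area per lipid, volume per lipid and head-to-head thickness.

    A_L = <Lx Ly> / (n_lipids / 2) assumes an equal split over two leaflets;
    V_L subtracts the water volume (``water_volume`` nm^3 per molecule,
    default the standard partial volume at ambient conditions) from the mean
    box volume; D_HH is the separation of the two peaks of the
    ``head_label`` number-density profile.
    """
    if n_lipids is None:
        n_lipids = traj.n_lipids
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    area = float(np.mean(traj.box[:, 0] * traj.box[:, 1]))
    A_L = area / (n_lipids / 2.0)
    vol = float(np.mean(np.prod(traj.box, axis=1)))
    V_L = (vol - n_waters * water_volume) / n_lipids
    z, dens = density_profile(traj, [head_label], n_bins=n_bins)
    upper = z > 0
    lower = z < 0
    if not (upper.any() and lower.any() and dens[upper].max() > 0 and dens[lower].max() > 0):
        raise ValueError("headgroup density does not straddle the midplane")
    z_up = z[upper][np.argmax(dens[upper])]
    z_lo = z[lower][np.argmax(dens[lower])]
    return BilayerMetrics(A_L=A_L, V_L=V_L, D_HH=float(z_up - z_lo))


def order_parameter_scd(bond_vectors: list[np.ndarray] | dict) -> np.ndarray:
    """Deuterium order parameter per carbon: S_CD = <(3 cos^2 theta_z - 1)/2>.

    ``bond_vectors`` groups C-H (or C-D) bond unit vectors by carbon index:
    a list (or dict keyed by index) of (n, 3) arrays.  Values lie in
    [-0.5, 1]: 1 for bonds along z, -0.5 for bonds in the xy plane, 0 for
    an isotropic distribution.
    """
    if isinstance(bond_vectors, dict):
        bond_vectors = [bond_vectors[k] for k in sorted(bond_vectors)]
    out = np.empty(len(bond_vectors))
    for n, vecs in enumerate(bond_vectors):
        v = np.asarray(vecs, dtype=float)
        if v.size == 0:
            raise ValueError(f"empty bond-vector group at carbon index {n}")
        cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
        out[n] = np.mean(1.5 * cos2 - 0.5)
    return out


# ---------------------------------------------------------------------------
# representative conformations


def representative_conformation(
    conformations: list[np.ndarray] | np.ndarray,
    assignments: np.ndarray | list[int] | None = None,
) -> int:
    """Index of the medoid of the most populated conformational cluster.

    The medoid minimises the mean pairwise RMSD (after optimal rigid-body
    superposition) to all other members of its cluster; ties break toward
    the lowest index.  ``assignments`` defaults to a single cluster.
    """
    confs = [np.asarray(c, dtype=float) for c in conformations]
    if not confs:
        raise ValueError("no conformations supplied")
    shapes = {c.shape for c in confs}
    if len(shapes) != 1:
        raise ValueError("conformations must be atom-matched (equal shapes)")
    if assignments is None:
        assignments = np.zeros(len(confs), dtype=int)
    labels = np.asarray(assignments)
    if labels.shape != (len(confs),):
        raise ValueError("one cluster label per conformation required")
    values, counts = np.unique(labels, return_counts=True)
    top = values[np.argmax(counts)]  # np.unique sorts: ties pick lowest label
    members = np.nonzero(labels == top)[0]
    if len(members) == 1:
        return int(members[0])
    n = len(members)
    dmat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = _mda_rmsd(confs[members[a]], confs[members[b]],
                          center=True, superposition=True)
            dmat[a, b] = dmat[b, a] = d
    mean_d = dmat.sum(axis=1) / (n - 1)
    return int(members[np.argmin(mean_d)])
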