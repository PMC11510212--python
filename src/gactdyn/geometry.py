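"""Superposition, fluctuation, dihedral and helix-kink geometry.

Angles are reported in degrees wrapped to (-180, 180], averaged with
circular statistics (arithmetic means are wrong near the +/-180 boundary,
e.g. for a phi angle near -157 deg).  Helix-kink geometry follows the
bend / wobble / face-shift decomposition used for proline-kinked
transmembrane helices: bend is the angle between the pre- and post-kink
helix axes, wobble the direction of the bend around the pre-axis measured
from the kink residue's radial direction, and face shift the change in
helical phase across the kink relative to an extrapolation of the
pre-segment twist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import FrameSeries, GactdynError, Selection, Topology

__all__ = [
    "DegenerateFitError",
    "InsufficientFramesError",
    "UndefinedDihedralError",
    "UndefinedMeanError",
    "MissingAtomError",
    "SuperpositionResult",
    "FluctuationProfile",
    "DihedralSeries",
    "HelixAxis",
    "HelixKinkSeries",
    "wrap_angle",
    "circular_mean",
    "circular_sd",
    "circular_difference",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "dihedral",
    "backbone_dihedral_series",
    "sidechain_chi_series",
    "fit_helix_axis",
    "prokink_angles",
]


class DegenerateFitError(GactdynError):
    pass


class InsufficientFramesError(GactdynError):
    pass


class UndefinedDihedralError(GactdynError):
    pass


class UndefinedMeanError(GactdynError):
    pass


class MissingAtomError(GactdynError):
    pass


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def wrap_angle(a):
    """Wrap degrees to (-180, 180]."""
    w = np.mod(a, 360.0)
    return np.where(w > 180.0, w - 360.0, w) if np.ndim(a) else (w - 360.0 if w > 180.0 else w)


def circular_mean(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Circular mean of angles in degrees.

    Returns (mean in (-180, 180], resultant length in [0, 1]).  A resultant
    below 1e-12 (perfectly spread angles) raises :class:`UndefinedMeanError`.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise UndefinedMeanError("circular mean of an empty set")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    r = float(np.hypot(s, c))
    if r < 1e-12:
        raise UndefinedMeanError("resultant length ~ 0; circular mean undefined")
    return float(wrap_angle(np.rad2deg(np.arctan2(s, c)))), r


def circular_sd(angles_deg: Sequence[float]) -> float:
    """Circular standard deviation in degrees, sqrt(-2 ln R)."""
    _, r = circular_mean(angles_deg)
    return float(np.rad2deg(np.sqrt(max(0.0, -2.0 * np.log(max(r, 1e-300))))))


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed smallest difference a - b in (-180, 180]."""
    return float(wrap_angle(a_deg - b_deg))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # applied as x @ R.T + t
    rmsd: float               # A, over the fitted selection

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_fit_points(x: np.ndarray, label: str) -> None:
    if x.shape[0] < 3:
        raise DegenerateFitError(f"{label}: need >= 3 atoms for a rigid fit")
    c = x - x.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-8) < 2:
        raise DegenerateFitError(f"{label}: points are collinear")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: Selection | None = None
) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    When ``selection`` is given both inputs are full-topology coordinate
    arrays and the fit (and reported RMSD) uses only the selected atoms;
    otherwise the arrays are fitted as given.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        m = mobile[selection.index_array]
        r = reference[selection.index_array]
    else:
        m, r = mobile, reference
    if m.shape != r.shape:
        raise ValueError("mobile/reference selection shapes differ")
    _check_fit_points(m, "mobile")
    _check_fit_points(r, "reference")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    H = (m - mc).T @ (r - rc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = m @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_series(
    frames: FrameSeries, reference: np.ndarray, selection: Selection
) -> np.ndarray:
    """Per-frame Calpha (or any selection) RMSD after independent superposition."""
    out = np.empty(frames.n_frames)
    for k in range(frames.n_frames):
        out[k] = kabsch_superpose(frames.coordinates[k], reference, selection).rmsd
    return out


@dataclass
class FluctuationProfile:
    rmsf: dict[int, float]            # residue_index -> RMSF (A)
    window: tuple[float, float]       # (t_start, t_end) ns

    def __getitem__(self, residue_index: int) -> float:
        return self.rmsf[residue_index]


def rmsf(
    frames: FrameSeries, selection: Selection, fit_selection: Selection | None = None
) -> FluctuationProfile:
    """Root-mean-square fluctuation about the trajectory-mean structure.

    Frames are superposed on ``fit_selection`` (default: the analysis
    selection) to their mean structure, with the mean recomputed and the fit
    repeated once (two-pass).  RMSF_i = sqrt(<|r_i - <r_i>|^2>), aggregated
    per residue by averaging over the selected atoms of that residue.
    """
    if frames.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    fit_selection = fit_selection or selection
    coords = frames.coordinates.copy()
    for _pass in range(2):
        ref = coords.mean(axis=0)
        for k in range(coords.shape[0]):
            sup = kabsch_superpose(coords[k], ref, fit_selection)
            coords[k] = sup.apply(coords[k])
    mean = coords.mean(axis=0)
    dev = coords - mean
    per_atom = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    by_res: dict[int, list[float]] = {}
    for i in selection.atom_indices:
        by_res.setdefault(frames.topology.atoms[i].residue_index, []).append(per_atom[i])
    profile = {r: float(np.mean(v)) for r, v in sorted(by_res.items())}
    return FluctuationProfile(profile, (float(frames.times[0]), float(frames.times[-1])))


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC sign convention (cis 0, trans 180)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise UndefinedDihedralError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedDihedralError("collinear triplet; dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return float(wrap_angle(np.rad2deg(np.arctan2(y, x))))


def _dihedral_batch(P: np.ndarray) -> np.ndarray:
    """Vectorized dihedral over frames; P has shape (n_frames, 4, 3)."""
    b1 = P[:, 1] - P[:, 0]
    b2 = P[:, 2] - P[:, 1]
    b3 = P[:, 3] - P[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=1)
    return wrap_angle(np.rad2deg(np.arctan2(y, x)))


@dataclass
class DihedralSeries:
    residue_index: int
    angle_kind: Literal["phi", "psi", "chi1", "chi2"]
    angles: np.ndarray                     # per-frame, degrees in (-180, 180]
    circ_mean: float
    circ_sd: float
    half_split: tuple[float, float, bool]  # (mean 1st half, mean 2nd half, transition)


_DEFAULT_TRANSITION_DEG = 30.0


def _series_stats(angles: np.ndarray, transition_threshold: float) -> tuple[float, float, tuple]:
    mean, _ = circular_mean(angles)
    sd = circular_sd(angles)
    half = len(angles) // 2
    if half >= 1 and len(angles) - half >= 1:
        m1, _ = circular_mean(angles[:half])
        m2, _ = circular_mean(angles[half:])
        flag = abs(circular_difference(m1, m2)) > transition_threshold
        split = (m1, m2, flag)
    else:
        split = (mean, mean, False)
    return mean, sd, split


def _atom_in_residue(topology: Topology, residue_index: int, name: str) -> int:
    for i, a in enumerate(topology.atoms):
        if a.residue_index == residue_index and a.name == name:
            return i
    raise MissingAtomError(
        f"residue {topology.residues[residue_index].name}"
        f"{topology.residues[residue_index].author_number} has no atom {name!r}"
    )


def backbone_dihedral_series(
    frames: FrameSeries,
    residue_index: int,
    kind: Literal["phi", "psi"],
    transition_threshold: float = _DEFAULT_TRANSITION_DEG,
) -> DihedralSeries:
    """Per-frame phi (C_{i-1}, N, CA, C) or psi (N, CA, C, N_{i+1}) series."""
    top = frames.topology
    if kind == "phi":
        if residue_index == 0:
            raise MissingAtomError("phi undefined at the N-terminus (no preceding C)")
        idx = [
            _atom_in_residue(top, residue_index - 1, "C"),
            _atom_in_residue(top, residue_index, "N"),
            _atom_in_residue(top, residue_index, "CA"),
            _atom_in_residue(top, residue_index, "C"),
        ]
    elif kind == "psi":
        if residue_index >= top.n_residues - 1:
            raise MissingAtomError("psi undefined at the C-terminus (no following N)")
        idx = [
            _atom_in_residue(top, residue_index, "N"),
            _atom_in_residue(top, residue_index, "CA"),
            _atom_in_residue(top, residue_index, "C"),
            _atom_in_residue(top, residue_index + 1, "N"),
        ]
    else:
        raise ValueError(f"kind must be phi or psi, got {kind!r}")
    angles = _dihedral_batch(frames.coordinates[:, idx, :])
    mean, sd, split = _series_stats(angles, transition_threshold)
    return DihedralSeries(residue_index, kind, angles, mean, sd, split)


#: chi1 is N-CA-CB-X, chi2 is CA-CB-Y-Z; fourth/extension atoms per residue
_CHI1_X = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}
_CHI2 = {
    "ARG": ("CG", "CD"), "ASN": ("CG", "OD1"), "ASP": ("CG", "OD1"),
    "GLN": ("CG", "CD"), "GLU": ("CG", "CD"), "HIS": ("CG", "ND1"),
    "ILE": ("CG1", "CD1"), "LEU": ("CG", "CD1"), "LYS": ("CG", "CD"),
    "MET": ("CG", "SD"), "PHE": ("CG", "CD1"), "PRO": ("CG", "CD"),
    "TRP": ("CG", "CD1"), "TYR": ("CG", "CD1"),
}


def sidechain_chi_series(
    frames: FrameSeries,
    residue_index: int,
    kind: Literal["chi1", "chi2"],
    transition_threshold: float = _DEFAULT_TRANSITION_DEG,
) -> DihedralSeries:
    """Per-frame side-chain chi1/chi2 series for the standard amino acids."""
    top = frames.topology
    resname = top.residues[residue_index].name
    if kind == "chi1":
        if resname not in _CHI1_X:
            raise MissingAtomError(f"{resname} has no chi1 angle")
        names = ["N", "CA", "CB", _CHI1_X[resname]]
    elif kind == "chi2":
        if resname not in _CHI2:
            raise MissingAtomError(f"{resname} has no chi2 angle")
        g, d = _CHI2[resname]
        names = ["CA", "CB", g, d]
    else:
        raise ValueError(f"kind must be chi1 or chi2, got {kind!r}")
    idx = [_atom_in_residue(top, residue_index, nm) for nm in names]
    angles = _dihedral_batch(frames.coordinates[:, idx, :])
    mean, sd, split = _series_stats(angles, transition_threshold)
    return DihedralSeries(residue_index, kind, angles, mean, sd, split)


# ---------------------------------------------------------------------------
# helix axis and Prokink kink angles
# ---------------------------------------------------------------------------

@dataclass
class HelixAxis:
    point: np.ndarray      # a point on the axis (A)
    direction: np.ndarray  # unit vector, oriented N -> C


def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Axis of a helical Calpha trace.

    Direction: the least-squares rotation superposing residues 1..n-1 onto
    residues 2..n is the helix screw operation; its rotation axis is the
    helix axis (exactly so for an ideal helix, and a least-squares estimate
    under noise).  Orientation follows the N -> C chain direction.  Axis
    point: algebraic (Kasa) circle-fit centre of the points projected on
    the plane normal to the direction, lifted to the centroid's axial
    position.  Exact on ideal helices for >= 4 residues.
    """
    P = np.asarray(ca_coords, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
        raise DegenerateFitError("helix axis fit needs >= 4 Calpha points")
    a, b = P[:-1], P[1:]
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    if np.linalg.matrix_rank(ac, tol=1e-9) < 2:
        raise DegenerateFitError("degenerate helix geometry (collinear points)")
    U, _S, Vt = np.linalg.svd(ac.T @ bc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    # rotation axis = eigenvector of R with eigenvalue 1
    w, v = np.linalg.eig(R)
    u = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    nu = np.linalg.norm(u)
    if nu < 1e-12 or abs(np.min(np.abs(w - 1.0))) > 1e-3:
        raise DegenerateFitError("no stable screw axis (degenerate rotation)")
    u = u / nu
    chain = P[-1] - P[0]
    if np.dot(u, chain) < 0:
        u = -u
    # circle fit in the plane normal to u
    e1 = _perp_unit(u)
    e2 = np.cross(u, e1)
    xy = np.column_stack([P @ e1, P @ e2])
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.sum(xy ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center2d = sol[:2]
    axial = float(np.mean(P @ u))
    point = center2d[0] * e1 + center2d[1] * e2 + axial * u
    return HelixAxis(point=point, direction=u)


def _perp_unit(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = trial - np.dot(trial, u) * u
    return v / np.linalg.norm(v)


@dataclass
class HelixKinkSeries:
    bend: np.ndarray            # deg, >= 0
    wobble: np.ndarray          # deg, (-180, 180]
    face_shift: np.ndarray      # deg, (-180, 180]
    wobble_reliable: np.ndarray  # bool; False whenever bend < bend_floor
    bend_floor: float
    avg_bend: float = field(init=False)
    avg_wobble: float = field(init=False)
    avg_face_shift: float = field(init=False)

    def __post_init__(self) -> None:
        self.avg_bend = float(np.mean(self.bend))
        self.avg_wobble = circular_mean(self.wobble)[0]
        self.avg_face_shift = circular_mean(self.face_shift)[0]


def _signed_angle(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    return float(np.rad2deg(np.arctan2(np.dot(about, np.cross(a, b)), np.dot(a, b))))


def _kink_one_frame(
    coords: np.ndarray,
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    kink_ca: int,
    pre_residue_numbers: np.ndarray,
    post_residue_numbers: np.ndarray,
    kink_number: float,
) -> tuple[float, float, float]:
    ax_pre = fit_helix_axis(coords[pre_idx])
    ax_post = fit_helix_axis(coords[post_idx])
    u1, u2 = ax_pre.direction, ax_post.direction
    bend = float(np.rad2deg(np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))))

    ca = coords[kink_ca]
    rho = ca - ax_pre.point
    rho = rho - np.dot(rho, u1) * u1
    w = u2 - np.dot(u2, u1) * u1
    if np.linalg.norm(rho) < 1e-9 or np.linalg.norm(w) < 1e-9:
        wobble = 0.0
    else:
        wobble = _signed_angle(rho / np.linalg.norm(rho), w / np.linalg.norm(w), u1)

    # reference frame about the pre-axis anchored at the kink radial direction
    e1 = rho / np.linalg.norm(rho) if np.linalg.norm(rho) > 1e-9 else _perp_unit(u1)
    e2 = np.cross(u1, e1)

    def phases(idx: np.ndarray, axis: HelixAxis, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
        rel = coords[idx] - axis.point
        rel = rel - np.outer(rel @ axis.direction, axis.direction)
        return np.rad2deg(np.arctan2(rel @ f2, rel @ f1))

    pre_phase = phases(pre_idx, ax_pre, e1, e2)
    # per-residue twist of the pre-segment from unwrapped phases
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(pre_phase)))
    twist = float(np.polyfit(pre_residue_numbers, unwrapped, 1)[0])

    # transport the reference frame onto the post axis (minimal rotation)
    axis_v = np.cross(u1, u2)
    n = np.linalg.norm(axis_v)
    if n > 1e-12:
        K = np.array([[0, -axis_v[2], axis_v[1]],
                      [axis_v[2], 0, -axis_v[0]],
                      [-axis_v[1], axis_v[0], 0]]) / n
        th = np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    else:
        R = np.eye(3)
    f1, f2 = R @ e1, R @ e2
    obs = phases(post_idx, ax_post, f1, f2)
    predicted = (post_residue_numbers - kink_number) * twist
    face_shift, _ = circular_mean(wrap_angle(obs - predicted))
    return bend, wobble, face_shift


def prokink_angles(
    frames: FrameSeries,
    kink_residue: int,
    pre_range: tuple[int, int],
    post_range: tuple[int, int],
    bend_floor: float = 5.0,
) -> HelixKinkSeries:
    """Per-frame bend / wobble / face-shift of a kinked helix.

    ``pre_range`` and ``post_range`` are inclusive internal residue-index
    ranges flanking ``kink_residue``; each needs >= 4 residues with Calpha
    atoms.  Wobble is flagged unreliable for frames whose bend is below
    ``bend_floor`` (degrees), where its direction loses meaning.
    """
    top = frames.topology
    for lo, hi, label in (( *pre_range, "pre"), (*post_range, "post")):
        if hi - lo + 1 < 4:
            raise DegenerateFitError(f"{label}_range needs >= 4 residues")
    if not (pre_range[0] <= kink_residue <= post_range[1]):
        raise ValueError("kink_residue must lie between pre_range start and post_range end")

    def ca_indices(lo: int, hi: int) -> np.ndarray:
        return np.array([_atom_in_residue(top, r, "CA") for r in range(lo, hi + 1)])

    pre_idx = ca_indices(*pre_range)
    post_idx = ca_indices(*post_range)
    kink_ca = _atom_in_residue(top, kink_residue, "CA")
    pre_nums = np.arange(pre_range[0], pre_range[1] + 1, dtype=float)
    post_nums = np.arange(post_range[0], post_range[1] + 1, dtype=float)

    n = frames.n_frames
    bend = np.empty(n)
    wobble = np.empty(n)
    face = np.empty(n)
    for k in range(n):
        bend[k], wobble[k], face[k] = _kink_one_frame(
            frames.coordinates[k], pre_idx, post_idx, kink_ca,
            pre_nums, post_nums, float(kink_residue),
        )
    reliable = bend >= bend_floor
    return HelixKinkSeries(bend, wobble, face, reliable, bend_floor)
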