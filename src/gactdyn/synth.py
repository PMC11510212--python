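"""Synthetic topologies and trajectories with known ground truth.

Every analysis stage in this package (kink geometry, ionic-lock occupancy,
contact fractions, correlation matrices, PCA) is validated against
trajectories built here, where the quantity being estimated is a
construction parameter rather than an unknown.  All generators are pure
functions of their spec and seed; ground truth (hidden Markov states,
contact truth tables, kink parameters) is returned alongside the frames.

Geometry conventions: ideal alpha-helix with 1.5 A rise, 100 deg twist and
2.3 A Calpha radius, axis along +z; coordinates in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    Atom,
    FrameSeries,
    GactdynError,
    GenericNumberMap,
    Residue,
    Segment,
    Topology,
)

__all__ = [
    "SynthSpecError",
    "HelixSpec",
    "KinkSpec",
    "TwoStateLockSpec",
    "OccupancySpec",
    "CorrelationSpec",
    "make_ideal_helix",
    "make_kinked_helix",
    "make_two_state_lock_trajectory",
    "make_occupancy_trajectory",
    "make_correlated_trajectory",
    "make_pseudo_receptor",
    "build_backbone_frame",
    "make_backbone_trajectory",
    "make_chi_fixture",
]


class SynthSpecError(GactdynError):
    pass


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class HelixSpec:
    n_residues: int
    rise: float = 1.5          # A per residue
    twist: float = 100.0       # deg per residue
    radius: float = 2.3        # A

    def validate(self) -> None:
        if self.n_residues < 4:
            raise SynthSpecError("helix needs at least 4 residues")
        if self.rise <= 0:
            raise SynthSpecError("rise must be positive")


@dataclass
class KinkSpec:
    bend: float                # deg, [0, 180)
    wobble: float              # deg, (-180, 180]
    face_shift: float          # deg, (-180, 180]
    kink_residue: int          # index of the pivot ("proline") residue

    def validate(self, n_pre: int) -> None:
        if not 0 <= self.bend < 180:
            raise SynthSpecError(f"bend {self.bend} outside [0, 180)")
        for label, v in (("wobble", self.wobble), ("face_shift", self.face_shift)):
            if not -180 < v <= 180:
                raise SynthSpecError(f"{label} {v} outside (-180, 180]")
        if not 0 <= self.kink_residue < n_pre:
            raise SynthSpecError(
                f"kink_residue {self.kink_residue} outside pre-segment (0-{n_pre - 1})"
            )


@dataclass
class TwoStateLockSpec:
    p_open: float
    n_frames: int
    d_closed: float = 4.5      # A, formed-lock charge-centre distance
    d_open: float = 12.5       # A, broken-lock distance
    noise_sd: float = 0.3      # A
    dwell: float = 50.0        # mean frames per state episode
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.p_open <= 1:
            raise SynthSpecError("p_open must be in [0, 1]")
        if self.d_open <= self.d_closed:
            raise SynthSpecError("d_open must exceed d_closed")
        if self.n_frames < 1:
            raise SynthSpecError("need at least one frame")
        if self.dwell < 1:
            raise SynthSpecError("dwell must be >= 1 frame")


@dataclass
class OccupancySpec:
    pairs: dict[tuple[int, int], float]   # (author i, author j) -> fraction
    n_frames: int
    contact_distance: float = 3.5         # A between the detector atoms when in contact
    apart_distance: float = 9.0           # A when apart
    seed: int = 0

    def validate(self) -> None:
        if self.contact_distance >= self.apart_distance:
            raise SynthSpecError("contact_distance must be < apart_distance")
        seen: set[int] = set()
        for (i, j), f in self.pairs.items():
            if not 0 <= f <= 1:
                raise SynthSpecError(f"fraction {f} for pair ({i},{j}) outside [0,1]")
            if i in seen or j in seen or i == j:
                raise SynthSpecError("pairs must use disjoint residues")
            seen.update((i, j))


@dataclass
class CorrelationSpec:
    pairs: dict[tuple[int, int], float]   # (author i, author j) -> Pearson r
    n_frames: int
    displacement_sd: float = 1.0          # A per axis
    seed: int = 0

    def validate(self) -> None:
        seen: set[int] = set()
        for (i, j), r in self.pairs.items():
            if not -1 <= r <= 1:
                raise SynthSpecError(f"correlation {r} for pair ({i},{j}) outside [-1,1]")
            if i in seen or j in seen or i == j:
                raise SynthSpecError("pairs must use disjoint residues")
            seen.update((i, j))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _ca_topology(
    author_numbers: Sequence[int], names: Sequence[str] | None = None, chain: str = "A"
) -> Topology:
    names = names or ["ALA"] * len(author_numbers)
    residues = [Residue(num, "", nm, chain) for num, nm in zip(author_numbers, names)]
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", residue_index=i,
             is_sidechain=False, is_hydrogen=False)
        for i in range(len(residues))
    ]
    return Topology(atoms, residues)


def _helix_points(
    indices: np.ndarray, spec: HelixSpec, phase0: float = 0.0, z0: float = 0.0, k0: float = 0.0
) -> np.ndarray:
    """Calpha positions for residue indices k of an ideal helix along +z."""
    k = np.asarray(indices, dtype=float)
    th = np.deg2rad((k - k0) * spec.twist + phase0)
    return np.column_stack(
        [spec.radius * np.cos(th), spec.radius * np.sin(th), z0 + (k - k0) * spec.rise]
    )


# ---------------------------------------------------------------------------
# helix generators
# ---------------------------------------------------------------------------

def make_ideal_helix(spec: HelixSpec) -> FrameSeries:
    """Single-frame Calpha-only ideal helix, axis along +z."""
    spec.validate()
    coords = _helix_points(np.arange(spec.n_residues), spec)
    top = _ca_topology(range(1, spec.n_residues + 1))
    return FrameSeries(top, coords[None, :, :], np.array([0.0]), label="ideal_helix")


def make_kinked_helix(pre: HelixSpec, post: HelixSpec, kink: KinkSpec) -> FrameSeries:
    """Helix with a designed proline-style kink.

    Residues ``0 .. pre.n_residues-1`` form an ideal pre-segment.  The post
    segment continues the helix from the kink residue with the post spec's
    geometry, phase-shifted by ``face_shift`` about the axis, then rotated
    by ``bend`` about an in-plane axis through the kink residue's axis foot;
    the tilt direction makes an angle ``wobble`` with the kink residue's
    radial (Calpha) direction, right-handed about the pre-axis.
    """
    pre.validate()
    post.validate()
    kink.validate(pre.n_residues)

    n_pre, n_post = pre.n_residues, post.n_residues
    kidx = kink.kink_residue
    pre_pts = _helix_points(np.arange(n_pre), pre)

    kink_phase = kidx * pre.twist
    kink_z = kidx * pre.rise
    post_idx = np.arange(n_pre, n_pre + n_post)
    post_pts = _helix_points(
        post_idx, post, phase0=kink_phase + kink.face_shift, z0=kink_z, k0=kidx
    )

    # bend about an axis through the kink residue's axis foot; tilt direction
    # d = wobble rotation of the kink Calpha radial direction
    rho = np.array([np.cos(np.deg2rad(kink_phase)), np.sin(np.deg2rad(kink_phase)), 0.0])
    d = _rotation_about([0.0, 0.0, 1.0], kink.wobble) @ rho
    bend_axis = np.cross([0.0, 0.0, 1.0], d)
    if np.linalg.norm(bend_axis) > 1e-12 and kink.bend > 0:
        R = _rotation_about(bend_axis, kink.bend)
        pivot = np.array([0.0, 0.0, kink_z])
        post_pts = (post_pts - pivot) @ R.T + pivot

    coords = np.vstack([pre_pts, post_pts])
    top = _ca_topology(range(1, n_pre + n_post + 1))
    return FrameSeries(top, coords[None, :, :], np.array([0.0]), label="kinked_helix")


# ---------------------------------------------------------------------------
# two-state ionic-lock trajectory
# ---------------------------------------------------------------------------

def _group_topology_lock() -> tuple[Topology, GenericNumberMap]:
    residues = [
        Residue(173, "", "ARG", "A", segment=Segment.TM3, generic_number="3.50"),
        Residue(318, "", "GLU", "A", segment=Segment.TM6, generic_number="6.30"),
    ]
    names = [("CA", "C"), ("CZ", "C"), ("NH1", "N"), ("NH2", "N"),
             ("CA", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")]
    atoms = []
    for i, (nm, el) in enumerate(names):
        ridx = 0 if i < 4 else 1
        atoms.append(Atom(i + 1, nm, el, ridx, nm not in ("CA",), False))
    top = Topology(atoms, residues)
    gmap = GenericNumberMap(
        forward={"3.50": 0, "6.30": 1},
        reverse={0: "3.50", 1: "6.30"},
        segment_bounds={Segment.TM3: (173, 173), Segment.TM6: (318, 318)},
    )
    return top, gmap


def _markov_states(spec: TwoStateLockSpec, rng: np.random.Generator) -> np.ndarray:
    """Hidden open(1)/closed(0) chain, stationary P(open)=p_open, mean episode
    length = dwell (averaged over alternating open/closed episodes)."""
    p = spec.p_open
    n = spec.n_frames
    if p <= 0.0:
        return np.zeros(n, dtype=int)
    if p >= 1.0:
        return np.ones(n, dtype=int)
    q_oc = min(1.0, 1.0 / (2.0 * spec.dwell * p))         # open -> closed
    q_co = min(1.0, 1.0 / (2.0 * spec.dwell * (1.0 - p))) # closed -> open
    states = np.empty(n, dtype=int)
    states[0] = 1 if rng.random() < p else 0
    u = rng.random(n - 1)
    for t in range(1, n):
        leave = q_oc if states[t - 1] == 1 else q_co
        states[t] = (1 - states[t - 1]) if u[t - 1] < leave else states[t - 1]
    return states


def make_two_state_lock_trajectory(
    spec: TwoStateLockSpec, time_step_ns: float = 0.1
) -> tuple[FrameSeries, dict]:
    """Arg/Glu pseudo-residue pair whose charge-centre distance follows a
    hidden two-state (formed/broken) Markov chain.

    Returns (frames, truth) where truth carries the hidden state sequence,
    the noiseless per-frame distances and the generic-number map for the
    lock detector.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    states = _markov_states(spec, rng)
    d_clean = np.where(states == 1, spec.d_open, spec.d_closed)
    d = d_clean + rng.normal(0.0, spec.noise_sd, size=spec.n_frames)
    d = np.maximum(d, 1.0)

    top, gmap = _group_topology_lock()
    # Glu charge group fixed around the origin; Arg group translated along +x
    # so that the (CZ,NH1,NH2) centre sits exactly d from the (CD,OE1,OE2) centre.
    glu = np.array([[-0.8, -3.7, 0.0],   # CA
                    [-0.8, -0.7, 0.0],   # CD
                    [0.0, 0.0, 0.0],     # OE1
                    [-0.8, 0.7, 0.0]])   # OE2
    arg0 = np.array([[0.8, -3.7, 0.0],   # CA
                     [0.8, -0.7, 0.0],   # CZ
                     [0.0, 0.0, 0.0],    # NH1
                     [0.8, 0.7, 0.0]])   # NH2
    cc_glu = glu[1:].mean(axis=0)
    cc_arg0 = arg0[1:].mean(axis=0)
    coords = np.empty((spec.n_frames, 8, 3))
    for t in range(spec.n_frames):
        shift = cc_glu + np.array([d[t], 0.0, 0.0]) - cc_arg0
        coords[t, :4] = arg0 + shift
        coords[t, 4:] = glu
    times = np.arange(spec.n_frames) * time_step_ns
    frames = FrameSeries(top, coords, times, label="two_state_lock")
    truth = {
        "states": states,
        "distances": d,
        "broken_fraction": float(states.mean()),
        "gmap": gmap,
    }
    return frames, truth


# ---------------------------------------------------------------------------
# designed contact occupancies
# ---------------------------------------------------------------------------

# template side-chain groups per contact kind; the first listed atom of each
# partner is the "detector" atom whose separation is controlled exactly.
_OCC_TEMPLATES = {
    "salt_bridge": (
        ("ARG", [("NH1", "N", (0.0, 0.0, 0.0)), ("NH2", "N", (0.8, 0.7, 0.0)),
                 ("CZ", "C", (0.8, -0.7, 0.0)), ("CA", "C", (0.8, -3.7, 0.0))]),
        ("GLU", [("OE1", "O", (0.0, 0.0, 0.0)), ("OE2", "O", (-0.8, 0.7, 0.0)),
                 ("CD", "C", (-0.8, -0.7, 0.0)), ("CA", "C", (-0.8, -3.7, 0.0))]),
    ),
    "hbond": (
        ("SER", [("OG", "O", (0.0, 0.0, 0.0)), ("HG", "H", (-0.96, 0.0, 0.0)),
                 ("CB", "C", (0.7, 1.2, 0.0)), ("CA", "C", (0.7, 2.7, 0.0))]),
        ("GLU", [("OE1", "O", (0.0, 0.0, 0.0)), ("OE2", "O", (-0.8, 0.7, 0.0)),
                 ("CD", "C", (-0.8, -0.7, 0.0)), ("CA", "C", (-0.8, -3.7, 0.0))]),
    ),
    "hydrophobic": (
        ("LEU", [("CD1", "C", (0.0, 0.0, 0.0)), ("CD2", "C", (0.8, 1.2, 0.0)),
                 ("CG", "C", (0.9, -1.1, 0.0)), ("CB", "C", (0.9, -2.6, 0.0)),
                 ("CA", "C", (0.9, -4.1, 0.0))]),
        ("ILE", [("CD1", "C", (0.0, 0.0, 0.0)), ("CG1", "C", (-0.9, -1.1, 0.0)),
                 ("CB", "C", (-0.9, -2.6, 0.0)), ("CA", "C", (-0.9, -4.1, 0.0))]),
    ),
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def make_occupancy_trajectory(
    spec: OccupancySpec, kind: str = "salt_bridge", time_step_ns: float = 0.1
) -> tuple[FrameSeries, dict]:
    """Residue pairs whose contact state is an i.i.d. Bernoulli draw per frame.

    In the "in" state the detector atoms (e.g. Arg NH1 / Glu OE1) sit exactly
    ``contact_distance`` apart; in the "out" state ``apart_distance``.  Pairs
    are spatially isolated (50 A apart) so their contacts are independent.
    Returns (frames, truth) with truth["table"][(i, j)] the boolean series.
    """
    spec.validate()
    if kind not in _OCC_TEMPLATES:
        raise SynthSpecError(f"unknown occupancy kind {kind!r}")
    rng = np.random.default_rng(spec.seed)
    (name_a, tmpl_a), (name_b, tmpl_b) = _OCC_TEMPLATES[kind]

    residues: list[Residue] = []
    atoms: list[Atom] = []
    base_b: list[np.ndarray] = []
    offsets_a: list[np.ndarray] = []
    atom_slices: list[tuple[slice, slice]] = []
    pair_keys = sorted(spec.pairs)
    serial = 1
    for p, (i, j) in enumerate(pair_keys):
        iso = np.array([0.0, 50.0 * p, 0.0])
        for resname, tmpl, author in ((name_a, tmpl_a, i), (name_b, tmpl_b, j)):
            ridx = len(residues)
            residues.append(Residue(author, "", resname, "A"))
            start = len(atoms)
            for nm, el, _pos in tmpl:
                atoms.append(Atom(serial, nm, el, ridx,
                                  nm not in _BACKBONE_NAMES, el == "H"))
                serial += 1
            if resname == name_a and tmpl is tmpl_a:
                offsets_a.append(np.asarray([p_ for *_x, p_ in tmpl], dtype=float))
                slice_a = slice(start, len(atoms))
            else:
                base_b.append(np.asarray([p_ for *_x, p_ in tmpl], dtype=float) + iso)
                slice_b = slice(start, len(atoms))
        atom_slices.append((slice_a, slice_b))

    top = Topology(atoms, residues)
    n = spec.n_frames
    coords = np.empty((n, top.n_atoms, 3))
    table: dict[tuple[int, int], np.ndarray] = {}
    for p, (i, j) in enumerate(pair_keys):
        f = spec.pairs[(i, j)]
        if f <= 0.0:
            contact = np.zeros(n, dtype=bool)
        elif f >= 1.0:
            contact = np.ones(n, dtype=bool)
        else:
            contact = rng.random(n) < f
        table[(i, j)] = contact
        iso = np.array([0.0, 50.0 * p, 0.0])
        dists = np.where(contact, spec.contact_distance, spec.apart_distance)
        sa, sb = atom_slices[p]
        for t in range(n):
            shift = iso + np.array([dists[t], 0.0, 0.0])
            coords[t, sa] = offsets_a[p] + shift
            coords[t, sb] = base_b[p]
    times = np.arange(n) * time_step_ns
    frames = FrameSeries(top, coords, times, label=f"occupancy_{kind}")
    return frames, {"table": table, "targets": dict(spec.pairs)}


# ---------------------------------------------------------------------------
# designed motion correlations
# ---------------------------------------------------------------------------

def make_correlated_trajectory(
    spec: CorrelationSpec, time_step_ns: float = 0.1
) -> tuple[FrameSeries, dict]:
    """Calpha pairs with designed displacement correlation.

    For each pair the two residues' displacements are drawn per axis from a
    bivariate normal with correlation equal to the target, so the
    displacement-vector correlation (DCCM entry) equals the target in
    expectation; |target| = 1 is generated degenerately (exact).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pair_keys = sorted(spec.pairs)
    authors: list[int] = []
    for i, j in pair_keys:
        authors.extend((i, j))
    top = _ca_topology(authors)
    n = spec.n_frames
    coords = np.empty((n, top.n_atoms, 3))
    for p, (i, j) in enumerate(pair_keys):
        r = spec.pairs[(i, j)]
        base_i = np.array([20.0 * (2 * p), 0.0, 0.0])
        base_j = np.array([20.0 * (2 * p + 1), 0.0, 0.0])
        u = rng.normal(0.0, spec.displacement_sd, size=(n, 3))
        if abs(r) >= 1.0:
            v = np.sign(r) * u
        else:
            w = rng.normal(0.0, spec.displacement_sd, size=(n, 3))
            v = r * u + np.sqrt(1.0 - r * r) * w
        coords[:, 2 * p, :] = base_i + u
        coords[:, 2 * p + 1, :] = base_j + v
    times = np.arange(n) * time_step_ns
    frames = FrameSeries(top, coords, times, label="correlated")
    return frames, {"targets": dict(spec.pairs)}


# ---------------------------------------------------------------------------
# seven-helix pseudo-receptor
# ---------------------------------------------------------------------------

#: per-helix (author start, generic start position); 25 residues each,
#: generic x.50 anchored so R3.50 / E6.30 sit near the intracellular ends.
_PSEUDO_HELICES = {
    Segment.TM1: (100, 35),
    Segment.TM2: (140, 38),
    Segment.TM3: (180, 32),
    Segment.TM4: (220, 40),
    Segment.TM5: (260, 36),
    Segment.TM6: (300, 28),
    Segment.TM7: (340, 33),
}
_N_PER_HELIX = 25
_RISE = 1.5
_TWIST = 100.0
_HELIX_R = 2.3
_BUNDLE_R = 12.0


def make_pseudo_receptor(
    n_frames: int, activation: bool, seed: int, time_step_ns: float = 0.1
) -> tuple[FrameSeries, GenericNumberMap]:
    """Seven-helix bundle emulating the activation signature of a class-A GPCR.

    Odd helices run extracellular (+z) to intracellular (-z) and even ones
    the reverse, as in a real 7TM fold.  An Arg side-chain charge group at
    3.50 and a Glu group at 6.30 form a 4.5 A ionic lock.  With
    ``activation=True`` the intracellular third of TM6 swings outward over
    the second half of the trajectory, the Glu charge group follows
    (lock distance drifting 4.5 -> 12.5 A), and a pseudo-ligand sits 3.5 A
    from the extracellular end of TM5 for every frame.  Thermal jitter of
    0.3 A (per axis) is applied to all atoms.
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    # per-residue atom records (name, element, position, is_sidechain)
    res_atoms: list[list[tuple[str, str, np.ndarray, bool]]] = []
    forward: dict[str, int] = {}
    reverse: dict[int, str] = {}
    bounds: dict[Segment, tuple[int, int]] = {}
    helix_of_res: dict[int, Segment] = {}

    for h, (seg, (author0, gen0)) in enumerate(_PSEUDO_HELICES.items()):
        helix_no = h + 1
        down = helix_no % 2 == 1     # odd helices run N(extracellular) -> C(intracellular)
        alpha = 2.0 * np.pi * h / 7.0
        center = np.array([_BUNDLE_R * np.cos(alpha), _BUNDLE_R * np.sin(alpha), 0.0])
        bounds[seg] = (author0, author0 + _N_PER_HELIX - 1)
        for k in range(_N_PER_HELIX):
            author = author0 + k
            generic = f"{helix_no}.{gen0 + k}"
            z = 18.0 - _RISE * k if down else -18.0 + _RISE * k
            th = np.deg2rad(k * _TWIST + 35.0 * h)
            pos = center + np.array([_HELIX_R * np.cos(th), _HELIX_R * np.sin(th), z])
            ridx = len(residues)
            name = "ARG" if generic == "3.50" else "GLU" if generic == "6.30" else "ALA"
            residues.append(Residue(author, "", name, "A", segment=seg, generic_number=generic))
            forward[generic] = ridx
            reverse[ridx] = generic
            helix_of_res[ridx] = seg
            res_atoms.append([("CA", "C", pos, False)])

    gmap = GenericNumberMap(forward, reverse, bounds)
    ridx_arg = forward["3.50"]
    ridx_glu = forward["6.30"]
    ca_arg = res_atoms[ridx_arg][0][2]
    ca_glu = res_atoms[ridx_glu][0][2]

    # side-chain charge groups bridging the two Calphas, centres 4.5 A apart
    mid = 0.5 * (ca_arg + ca_glu)
    u = _unit(ca_glu - ca_arg)
    cc_arg = mid - 2.25 * u
    cc_glu = mid + 2.25 * u
    perp = _unit(np.cross(u, [0.0, 0.0, 1.0]))
    res_atoms[ridx_arg] += [
        ("CZ", "C", cc_arg - 0.7 * perp, True),
        ("NH1", "N", cc_arg + 0.1 * u + 0.35 * perp, True),
        ("NH2", "N", cc_arg - 0.1 * u + 0.35 * perp, True),
    ]
    res_atoms[ridx_glu] += [
        ("CD", "C", cc_glu - 0.7 * perp, True),
        ("OE1", "O", cc_glu + 0.1 * u + 0.35 * perp, True),
        ("OE2", "O", cc_glu - 0.1 * u + 0.35 * perp, True),
    ]

    if activation:
        # pseudo-ligand glued near the extracellular ends of TM5/TM6,
        # 3.5 A from the top TM5 residue
        top5 = res_atoms[forward["5.36"]][0][2]
        top6 = res_atoms[forward["6.52"]][0][2]
        anchor = top5 + 3.5 * _unit(top6 - top5)
        residues.append(Residue(900, "", "LIG", "A", segment=Segment.LIGAND))
        lig = [(f"C{q + 1}", "C", anchor + np.asarray(off, dtype=float), False)
               for q, off in enumerate([(0, 0, 0), (1.4, 0, 0), (0, 1.4, 0),
                                        (0, 0, 1.4), (1.0, 1.0, 0)])]
        res_atoms.append(lig)

    atoms: list[Atom] = []
    base: list[np.ndarray] = []
    ligand_atom_indices: list[int] = []
    glu_side_idx: list[int] = []
    serial = 1
    for ridx, records in enumerate(res_atoms):
        for nm, el, pos, side in records:
            atoms.append(Atom(serial, nm, el, ridx, side, False))
            serial += 1
            base.append(np.asarray(pos, dtype=float))
            if residues[ridx].segment is Segment.LIGAND:
                ligand_atom_indices.append(len(base) - 1)
            if ridx == ridx_glu and side:
                glu_side_idx.append(len(base) - 1)

    top = Topology(atoms, residues, ligand_atom_indices)
    base_arr = np.asarray(base)
    n_atoms = top.n_atoms
    coords = np.repeat(base_arr[None, :, :], n_frames, axis=0)

    if activation:
        # TM6 intracellular third swings radially outward over the 2nd half
        tm6_ca = [i for i, a in enumerate(top.atoms)
                  if a.name == "CA" and helix_of_res.get(a.residue_index) is Segment.TM6
                  and base_arr[i][2] < -6.0]
        half = n_frames // 2
        s = np.zeros(n_frames)
        if n_frames - half > 1:
            s[half:] = np.linspace(0.0, 1.0, n_frames - half)
        else:
            s[half:] = 1.0
        for i in tm6_ca:
            radial = base_arr[i].copy()
            radial[2] = 0.0
            radial = _unit(radial)
            depth = min(1.0, max(0.0, (-6.0 - base_arr[i][2]) / 12.0))
            coords[:, i, :] += np.outer(s, 8.0 * depth * radial)
        # Glu charge group follows TM6 directly away from the Arg group:
        # lock distance = 4.5 + 8*s, reaching 12.5 A at full swing
        coords[:, glu_side_idx, :] += np.outer(s, 8.0 * u)[:, None, :]

    coords += rng.normal(0.0, 0.3, size=(n_frames, n_atoms, 3))
    times = np.arange(n_frames) * time_step_ns
    label = "pseudo_receptor_active" if activation else "pseudo_receptor_inactive"
    return FrameSeries(top, coords, times, label=label), gmap


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# backbone construction from internal coordinates (for dihedral oracles)
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 111.2, 116.2


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: return D with |CD|=bond, angle(BCD)=angle and
    dihedral(A,B,C,D)=torsion (IUPAC sign convention)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone_frame(phis: Sequence[float], psis: Sequence[float],
                         omega: float = 180.0) -> np.ndarray:
    """N/CA/C coordinates (3 atoms per residue) for given phi/psi angles.

    ``phis[0]`` is unused (no preceding carbonyl); standard bond lengths and
    angles; peptide bond omega fixed (default trans).
    """
    nres = len(phis)
    if len(psis) != nres:
        raise ValueError("phi and psi lists must have equal length")
    coords = np.zeros((3 * nres, 3))
    coords[0] = [0.0, 0.0, 0.0]                       # N1
    coords[1] = [_B_N_CA, 0.0, 0.0]                   # CA1
    ang = np.deg2rad(_A_N_CA_C)
    coords[2] = coords[1] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])  # C1
    for i in range(1, nres):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        coords[3 * i:3 * i + 3] = [n_i, ca_i, c_i]
    return coords


def _backbone_topology(nres: int, names: Sequence[str] | None = None) -> Topology:
    names = names or ["ALA"] * nres
    residues = [Residue(i + 1, "", names[i], "A") for i in range(nres)]
    atoms = []
    serial = 1
    for i in range(nres):
        for nm in ("N", "CA", "C"):
            atoms.append(Atom(serial, nm, nm[0], i, False, False))
            serial += 1
    return Topology(atoms, residues)


def make_backbone_trajectory(
    per_frame_phis: Sequence[Sequence[float]],
    per_frame_psis: Sequence[Sequence[float]],
    time_step_ns: float = 0.1,
) -> FrameSeries:
    """Backbone-only trajectory rebuilt per frame from phi/psi lists."""
    frames = [build_backbone_frame(p, s) for p, s in zip(per_frame_phis, per_frame_psis)]
    nres = len(per_frame_phis[0])
    top = _backbone_topology(nres)
    times = np.arange(len(frames)) * time_step_ns
    return FrameSeries(top, np.stack(frames), times, label="backbone")


def make_chi_fixture(resname: str, chi1: float, chi2: float | None = None,
                     n_frames: int = 1) -> FrameSeries:
    """Single residue with backbone plus CB/CG(/CD1) built so that
    dihedral(N,CA,CB,CG) = chi1 and, when given, dihedral(CA,CB,CG,CD1) = chi2."""
    bb = build_backbone_frame([-57.0, -57.0, -57.0], [-47.0, -47.0, -47.0])
    n1, ca1, c1 = bb[3], bb[4], bb[5]   # middle residue
    cb = _place_atom(c1, n1, ca1, 1.53, 110.5, 122.5)
    gname = {"SER": "OG", "CYS": "SG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1"}.get(resname, "CG")
    cg = _place_atom(n1, ca1, cb, 1.52, 114.0, chi1)
    atom_spec = [("N", "N", n1), ("CA", "C", ca1), ("C", "C", c1),
                 ("CB", "C", cb), (gname, gname[0], cg)]
    if chi2 is not None:
        cd = _place_atom(ca1, cb, cg, 1.50, 114.0, chi2)
        atom_spec.append(("CD1", "C", cd))
    residues = [Residue(1, "", resname, "A")]
    atoms = [Atom(i + 1, nm, el, 0, nm not in _BACKBONE_NAMES, False)
             for i, (nm, el, _p) in enumerate(atom_spec)]
    top = Topology(atoms, residues)
    coords = np.repeat(np.asarray([p for *_x, p in atom_spec])[None, :, :], n_frames, axis=0)
    times = np.arange(n_frames) * 0.1
    return FrameSeries(top, coords, times, label=f"chi_{resname}")
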