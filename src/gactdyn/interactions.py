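"""Per-frame interaction detectors.

All detectors report residue-level contacts: a residue pair is in contact
in a frame if ANY qualifying atom pair satisfies the criterion, matching
how occupancy fractions of salt bridges, hydrogen bonds and hydrophobic
contacts are tabulated for MD ensembles.  Fractions are plain means of the
per-frame boolean series over the analysed window.

The ionic-lock metric is the distance between side-chain charge centres:
the mean of the Arg guanidinium atoms (CZ, NH1, NH2) and the mean of the
Glu carboxylate atoms (CD, OE1, OE2); for Lys/Asp the terminal amine and
carboxylate groups are used instead.  A frame counts as "broken" when that
distance exceeds the formed threshold (default 5.0 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import FrameSeries, GactdynError, GenericNumberMap, Segment, Topology
from .geometry import MissingAtomError

__all__ = [
    "NoLigandError",
    "LockDistanceSeries",
    "ContactSeries",
    "LigandContactProfile",
    "ionic_lock_series",
    "salt_bridge_contacts",
    "hydrogen_bond_contacts",
    "hydrophobic_contacts",
    "ligand_contact_profile",
]


class NoLigandError(GactdynError):
    pass


# charge-group atom names tried in order for each lock partner
_BASIC_GROUPS = [("CZ", "NH1", "NH2"), ("NZ",)]
_ACIDIC_GROUPS = [("CD", "OE1", "OE2"), ("CG", "OD1", "OD2")]

_BASIC_SIDE_N = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACIDIC_SIDE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_APOLAR = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "CYS"}


@dataclass
class LockDistanceSeries:
    distances: np.ndarray          # per-frame charge-centre distance (A)
    times: np.ndarray              # ns
    formed_threshold: float        # A
    broken_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.broken_fraction = float(np.mean(self.distances > self.formed_threshold))

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))

    def histogram(self, bin_width: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        lo = np.floor(self.distances.min() / bin_width) * bin_width
        hi = np.ceil(self.distances.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(self.distances, bins=edges)
        return counts, edges


@dataclass
class ContactSeries:
    pair: tuple[int, int]              # internal residue indices (i < j)
    pair_authors: tuple[int, int]      # author numbers for cross-ensemble keys
    kind: Literal["salt_bridge", "hbond", "hydrophobic", "ligand"]
    series: np.ndarray                 # per-frame bool
    settings: dict = field(default_factory=dict)
    fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=bool)
        self.fraction = float(self.series.mean()) if self.series.size else 0.0


def _group_indices(top: Topology, residue_index: int, groups) -> list[int]:
    names = {a.name: i for i, a in enumerate(top.atoms) if a.residue_index == residue_index}
    for group in groups:
        idx = [names[nm] for nm in group if nm in names]
        if len(idx) == len(group):
            return idx
    raise MissingAtomError(
        f"residue {top.residues[residue_index].name}"
        f"{top.residues[residue_index].author_number} lacks charge-group atoms "
        f"{' / '.join('+'.join(g) for g in groups)}"
    )


def ionic_lock_series(
    frames: FrameSeries,
    gmap: GenericNumberMap,
    pair: tuple[str, str] = ("3.50", "6.30"),
    formed_threshold: float = 5.0,
) -> LockDistanceSeries:
    """Charge-centre distance series for the ionic-lock residue pair.

    ``pair`` names the basic and acidic partners by generic number
    (default R3.50-E6.30, the class-A activation microswitch).
    """
    top = frames.topology
    r_basic = gmap.residue_index(pair[0])
    r_acid = gmap.residue_index(pair[1])
    basic_idx = _group_indices(top, r_basic, _BASIC_GROUPS)
    acid_idx = _group_indices(top, r_acid, _ACIDIC_GROUPS)
    cc_b = frames.coordinates[:, basic_idx, :].mean(axis=1)
    cc_a = frames.coordinates[:, acid_idx, :].mean(axis=1)
    d = np.linalg.norm(cc_b - cc_a, axis=1)
    return LockDistanceSeries(d, frames.times.copy(), formed_threshold)


def _sidechain_atoms(top: Topology, residue_index: int, names: tuple[str, ...]) -> list[int]:
    return [i for i, a in enumerate(top.atoms)
            if a.residue_index == residue_index and a.name in names]


def _min_dist_series(frames: FrameSeries, idx_a: list[int], idx_b: list[int]) -> np.ndarray:
    A = frames.coordinates[:, idx_a, :]
    B = frames.coordinates[:, idx_b, :]
    diff = A[:, :, None, :] - B[:, None, :, :]
    return np.sqrt(np.sum(diff ** 2, axis=3)).min(axis=(1, 2))


def salt_bridge_contacts(
    frames: FrameSeries,
    topology: Topology | None = None,
    cutoff: float = 4.0,
    his_basic: bool = False,
) -> list[ContactSeries]:
    """Basic-acidic residue pairs within ``cutoff`` of any side-chain N-O.

    His counts as basic only when ``his_basic`` is set (protonation unknown
    in a plain coordinate file).  Pairs never in contact are omitted.
    """
    top = topology or frames.topology
    basic_names = dict(_BASIC_SIDE_N)
    if not his_basic:
        basic_names.pop("HIS")
    basics = [(r, _sidechain_atoms(top, r, basic_names[top.residues[r].name]))
              for r in range(top.n_residues) if top.residues[r].name in basic_names]
    acids = [(r, _sidechain_atoms(top, r, _ACIDIC_SIDE_O[top.residues[r].name]))
             for r in range(top.n_residues) if top.residues[r].name in _ACIDIC_SIDE_O]
    out: list[ContactSeries] = []
    settings = {"cutoff": cutoff, "his_basic": his_basic}
    for rb, nb in basics:
        if not nb:
            continue
        for ra, oa in acids:
            if not oa or ra == rb:
                continue
            series = _min_dist_series(frames, nb, oa) <= cutoff
            if series.any():
                i, j = sorted((rb, ra))
                authors = (top.residues[i].author_number, top.residues[j].author_number)
                out.append(ContactSeries((i, j), authors, "salt_bridge", series, settings))
    return out


def hydrogen_bond_contacts(
    frames: FrameSeries,
    topology: Topology | None = None,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
) -> list[ContactSeries]:
    """Residue pairs linked by a donor-H...acceptor geometry.

    Donors are N/O heavy atoms with a covalently attached hydrogen
    (attachment inferred from the first frame, H within 1.25 A); acceptors
    are any N/O.  A bond requires donor-acceptor distance <= d_cut and,
    when hydrogens are present, D-H...A angle >= angle_cut.  In a
    heavy-atom-only topology the angle criterion is skipped and the
    ``settings`` of every returned series carry ``angle_criterion: False``.
    Same-residue and sequence-adjacent pairs are excluded.
    """
    top = topology or frames.topology
    first = frames.coordinates[0]
    h_idx = [i for i, a in enumerate(top.atoms) if a.is_hydrogen]
    have_h = bool(h_idx)
    polar = [i for i, a in enumerate(top.atoms)
             if a.element in ("N", "O") and not a.is_hydrogen]
    donors: dict[int, list[int]] = {}
    if have_h:
        for i in polar:
            attached = [h for h in h_idx
                        if top.atoms[h].residue_index == top.atoms[i].residue_index
                        and np.linalg.norm(first[h] - first[i]) <= 1.25]
            if attached:
                donors[i] = attached
    else:
        donors = {i: [] for i in polar}
    settings = {"d_cut": d_cut, "angle_cut": angle_cut, "angle_criterion": have_h}

    by_res: dict[tuple[int, int], np.ndarray] = {}
    coords = frames.coordinates
    for d_atom, hs in donors.items():
        rd = top.atoms[d_atom].residue_index
        for a_atom in polar:
            ra = top.atoms[a_atom].residue_index
            if ra == rd:
                continue
            res_d, res_a = top.residues[rd], top.residues[ra]
            if res_d.chain == res_a.chain and abs(res_d.author_number - res_a.author_number) < 2:
                continue
            dist = np.linalg.norm(coords[:, d_atom, :] - coords[:, a_atom, :], axis=1)
            ok = dist <= d_cut
            if have_h and ok.any():
                ang_ok = np.zeros(frames.n_frames, dtype=bool)
                for h in hs:
                    v1 = coords[:, d_atom, :] - coords[:, h, :]
                    v2 = coords[:, a_atom, :] - coords[:, h, :]
                    cosang = np.sum(v1 * v2, axis=1) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                    )
                    ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    ang_ok |= ang >= angle_cut
                ok = ok & ang_ok
            if ok.any():
                key = tuple(sorted((rd, ra)))
                by_res[key] = by_res.get(key, np.zeros(frames.n_frames, dtype=bool)) | ok
    out = []
    for (i, j), series in sorted(by_res.items()):
        authors = (top.residues[i].author_number, top.residues[j].author_number)
        out.append(ContactSeries((i, j), authors, "hbond", series, settings))
    return out


def hydrophobic_contacts(
    frames: FrameSeries,
    topology: Topology | None = None,
    cutoff: float = 4.5,
) -> list[ContactSeries]:
    """Carbon-mediated side-chain proximity between residue pairs.

    A pair qualifies if at least one partner is apolar (A/V/L/I/P/F/M/W/C)
    and any side-chain heavy-atom pair with at least one carbon lies within
    ``cutoff``; mixed pairs such as Ser-Ile count, the criterion being
    carbon-mediated proximity rather than both residues being apolar.
    Trivial neighbours (|author i - j| < 3 within a segment) are excluded.
    """
    top = topology or frames.topology
    side: list[tuple[int, list[int], bool]] = []
    for r in range(top.n_residues):
        res = top.residues[r]
        if res.segment is Segment.LIGAND:
            continue
        atoms = [i for i, a in enumerate(top.atoms)
                 if a.residue_index == r and a.is_sidechain and not a.is_hydrogen]
        if any(top.atoms[i].element == "C" for i in atoms):
            side.append((r, atoms, res.name in _APOLAR))
    out: list[ContactSeries] = []
    settings = {"cutoff": cutoff}
    coords = frames.coordinates
    for x in range(len(side)):
        rx, ax, apolar_x = side[x]
        for y in range(x + 1, len(side)):
            ry, ay, apolar_y = side[y]
            if not (apolar_x or apolar_y):
                continue
            res_x, res_y = top.residues[rx], top.residues[ry]
            same_seg = res_x.segment is res_y.segment
            if same_seg and abs(res_x.author_number - res_y.author_number) < 3:
                continue
            # candidate atom pairs: at least one partner atom is a carbon
            pairs = [(i, j) for i in ax for j in ay
                     if top.atoms[i].element == "C" or top.atoms[j].element == "C"]
            if not pairs:
                continue
            ii = [p[0] for p in pairs]
            jj = [p[1] for p in pairs]
            diff = coords[:, ii, :] - coords[:, jj, :]
            series = (np.linalg.norm(diff, axis=2) <= cutoff).any(axis=1)
            if series.any():
                authors = (res_x.author_number, res_y.author_number)
                out.append(ContactSeries((rx, ry), authors, "hydrophobic", series, settings))
    return out


@dataclass
class LigandContactProfile:
    percentages: dict[int, float]      # residue_index -> % of frames in contact
    cutoff: float

    def sorted_items(self) -> list[tuple[int, float]]:
        return sorted(self.percentages.items(), key=lambda kv: (-kv[1], kv[0]))


def ligand_contact_profile(
    frames: FrameSeries,
    topology: Topology | None = None,
    cutoff: float = 4.0,
) -> LigandContactProfile:
    """Percentage of frames each protein residue contacts the ligand
    (any heavy-atom pair within ``cutoff``)."""
    top = topology or frames.topology
    if not top.ligand_atom_indices:
        raise NoLigandError("topology has no ligand atoms")
    lig = [i for i in top.ligand_atom_indices if not top.atoms[i].is_hydrogen]
    coords = frames.coordinates
    L = coords[:, lig, :]
    percentages: dict[int, float] = {}
    for r in range(top.n_residues):
        if top.residues[r].segment is Segment.LIGAND:
            continue
        heavy = [i for i, a in enumerate(top.atoms)
                 if a.residue_index == r and not a.is_hydrogen]
        if not heavy:
            continue
        diff = coords[:, heavy, None, :] - L[:, None, :, :]
        contact = (np.sqrt(np.sum(diff ** 2, axis=3)).min(axis=(1, 2)) <= cutoff)
        percentages[r] = float(100.0 * contact.mean())
    return LigandContactProfile(percentages, cutoff)
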