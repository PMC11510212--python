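"""Core data model: topology, coordinate ensembles, selections and generic numbering.

The canonical on-disk trajectory format is the multi-model PDB file
(``MODEL``/``ENDMDL`` blocks with standard ``ATOM``/``HETATM`` columns).
Coordinates are in Angstrom, times in nanoseconds, and the membrane normal
is +z by convention.  Residues are addressed either by author (PDB) number
or by Ballesteros–Weinstein generic number ("helix.position", e.g. "3.50"),
the standard way of labelling topologically equivalent positions across
class-A G-protein-coupled receptors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Segment",
    "Atom",
    "Residue",
    "Topology",
    "FrameSeries",
    "GenericNumberMap",
    "Selection",
    "GactdynError",
    "FormatError",
    "EmptyInputError",
    "FrameAlignmentError",
    "SegmentTableError",
    "SelectionError",
    "EmptyWindowError",
    "load_topology",
    "load_frames",
    "write_frames",
    "load_segment_table",
    "assign_generic_numbers",
    "select",
    "slice_window",
]


class GactdynError(Exception):
    """Base class for all package errors."""


class FormatError(GactdynError):
    """Unparseable input file; the message names the offending line."""


class EmptyInputError(GactdynError):
    pass


class FrameAlignmentError(GactdynError):
    """A trajectory MODEL does not match the topology atom layout."""


class SegmentTableError(GactdynError):
    pass


class SelectionError(GactdynError):
    """Selection expression could not be parsed; message carries the position."""


class EmptyWindowError(GactdynError):
    pass


class Segment(str, Enum):
    TM1 = "TM1"
    TM2 = "TM2"
    TM3 = "TM3"
    TM4 = "TM4"
    TM5 = "TM5"
    TM6 = "TM6"
    TM7 = "TM7"
    H8 = "H8"
    ICL1 = "ICL1"
    ICL2 = "ICL2"
    ICL3 = "ICL3"
    ECL1 = "ECL1"
    ECL2 = "ECL2"
    ECL3 = "ECL3"
    NTERM = "NTERM"
    CTERM = "CTERM"
    LIGAND = "LIGAND"
    OTHER = "OTHER"


#: residue names treated as solvent/ions and dropped on ingestion
WATER_ION_NAMES = {"HOH", "WAT", "TIP3", "NA", "CL", "K"}

_BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}
_BACKBONE_H = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    is_sidechain: bool
    is_hydrogen: bool


@dataclass
class Residue:
    author_number: int
    insertion_code: str
    name: str
    chain: str
    segment: Segment = Segment.OTHER
    generic_number: str | None = None


@dataclass
class Topology:
    atoms: list[Atom]
    residues: list[Residue]
    ligand_atom_indices: list[int] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_atom_indices(self, residue_index: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index]

    def find_residue(self, author_number: int, chain: str | None = None) -> int:
        for i, r in enumerate(self.residues):
            if r.author_number == author_number and (chain is None or r.chain == chain):
                return i
        raise KeyError(f"no residue with author number {author_number}")


@dataclass
class FrameSeries:
    """An ordered coordinate ensemble sharing one topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times``
    are strictly increasing, in nanoseconds.
    """

    topology: Topology
    coordinates: np.ndarray
    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.coordinates.shape[0] != self.times.shape[0]:
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class GenericNumberMap:
    """Bijection between generic numbers and internal residue indices."""

    forward: dict[str, int]
    reverse: dict[int, str]
    segment_bounds: dict[Segment, tuple[int, int]]

    def residue_index(self, generic: str) -> int:
        try:
            return self.forward[generic]
        except KeyError:
            raise KeyError(f"generic number {generic!r} not in map") from None


@dataclass
class Selection:
    atom_indices: list[int]
    description: str = ""

    def __post_init__(self) -> None:
        self.atom_indices = sorted(set(int(i) for i in self.atom_indices))

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# multi-model PDB I/O
# ---------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    stripped = name.strip()
    # names like 1HB2, 2HG are hydrogens with a leading digit
    stripped = stripped.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    two = stripped[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(name.strip()) > 1:
        # only trust two-letter elements when not a plain carbon name like "CA"
        if name.strip() in {"CA", "CB", "CG", "CD", "CE", "CZ", "CH"}:
            return name.strip()[0]
        return two.capitalize()
    return stripped[0]


def _parse_atom_line(line: str, lineno: int) -> tuple[int, str, str, str, int, str, str, float, float, float]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable PDB record at line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    element = element.capitalize()
    return serial, name, resname, chain, resseq, icode, element, x, y, z


def _iter_models(path: str | Path):
    """Yield (model_number, list of (lineno, line)) for each model block."""
    model_no = 0
    current: list[tuple[int, str]] = []
    in_model = False
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                in_model = True
                try:
                    model_no = int(line.split()[1])
                except (IndexError, ValueError):
                    model_no += 1
                current = []
            elif rec == "ENDMDL":
                in_model = False
                yield model_no, current
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append((lineno, line))
    if current:
        if saw_model_record and in_model:
            yield model_no, current
        elif not saw_model_record:
            yield 1, current


def load_topology(path: str | Path) -> Topology:
    """Build a :class:`Topology` from the first model of a multi-model PDB.

    Waters and simple ions (HOH/WAT/TIP3/NA/CL/K) are excluded.  HETATM
    records that are not water/ion become LIGAND residues and their atom
    indices are collected in ``ligand_atom_indices``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = None
    for _model_no, lines in _iter_models(path):
        first = lines
        break
    if first is None:
        raise EmptyInputError(f"no ATOM/HETATM records in {path}")

    atoms: list[Atom] = []
    residues: list[Residue] = []
    ligand_atom_indices: list[int] = []
    res_key = None
    for lineno, line in first:
        is_het = line.startswith("HETATM")
        serial, name, resname, chain, resseq, icode, element, *_ = _parse_atom_line(line, lineno)
        if resname in WATER_ION_NAMES:
            continue
        key = (chain, resseq, icode, resname)
        if key != res_key:
            seg = Segment.LIGAND if is_het else Segment.OTHER
            residues.append(Residue(resseq, icode, resname, chain, segment=seg))
            res_key = key
        ridx = len(residues) - 1
        is_h = element == "H"
        is_ligand = residues[ridx].segment is Segment.LIGAND
        is_side = (not is_ligand) and name not in _BACKBONE_HEAVY and name not in _BACKBONE_H
        atoms.append(Atom(serial, name, element, ridx, is_side, is_h))
        if is_ligand:
            ligand_atom_indices.append(len(atoms) - 1)
    # a waters/ions-only file yields a valid empty topology; only a file with
    # no ATOM/HETATM records at all is an error (caught above)
    return Topology(atoms, residues, ligand_atom_indices)


def load_frames(path: str | Path, topology: Topology, time_step_ns: float) -> FrameSeries:
    """Read every model of a multi-model PDB as a trajectory.

    Frame ``k`` is stamped ``k * time_step_ns``.  Every model must contain
    exactly the atoms of ``topology`` in the same order (after water/ion
    exclusion); a mismatch raises :class:`FrameAlignmentError` naming the
    model.
    """
    frames: list[np.ndarray] = []
    n_expected = topology.n_atoms
    for model_no, lines in _iter_models(path):
        coords = []
        for lineno, line in lines:
            parsed = _parse_atom_line(line, lineno)
            _, _, resname, *_rest = parsed
            if resname in WATER_ION_NAMES:
                continue
            coords.append(parsed[-3:])
        if len(coords) != n_expected:
            raise FrameAlignmentError(
                f"MODEL {model_no}: {len(coords)} atoms, topology has {n_expected}"
            )
        frames.append(np.asarray(coords, dtype=float))
    if not frames:
        raise EmptyInputError(f"no models found in {path}")
    times = np.arange(len(frames), dtype=float) * float(time_step_ns)
    return FrameSeries(topology, np.stack(frames), times, label=str(path))


def write_frames(frames: FrameSeries, path: str | Path) -> None:
    """Write a FrameSeries as a multi-model PDB (coordinates to 0.001 A)."""
    top = frames.topology
    with open(path, "w") as fh:
        for k in range(frames.n_frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            for i, atom in enumerate(top.atoms):
                res = top.residues[atom.residue_index]
                record = "HETATM" if res.segment is Segment.LIGAND else "ATOM  "
                x, y, z = frames.coordinates[k, i]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record}{atom.serial:5d} {name:<4s}{res.name:>4s} "
                    f"{(res.chain or 'A'):1s}{res.author_number:4d}{res.insertion_code or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# segment table & generic numbering
# ---------------------------------------------------------------------------

_ANCHOR_RE = re.compile(r"^(\d+)\.(\d+)@(-?\d+)$")


def load_segment_table(path: str | Path) -> dict[str, dict]:
    """Load a YAML segment table.

    Layout::

        TM3: {start: 152, end: 178, anchor: "3.50@173"}
        ECL2: {start: 218, end: 230}

    ``anchor`` is "helix.position@author_number"; segments without an anchor
    get segment labels but no generic numbers.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SegmentTableError(f"segment table {path} is not a mapping")
    return raw


def assign_generic_numbers(
    topology: Topology, segment_table: Mapping[str, Mapping]
) -> GenericNumberMap:
    """Assign segments and Ballesteros–Weinstein generic numbers.

    Within a segment the generic position increments by one per author
    residue number away from the anchor (anchor "3.50@173" gives author 172
    -> "3.49", 174 -> "3.51").  Loop-style anchors (e.g. "45.52@...") work
    identically.  Overlapping segment ranges or an anchor outside its range
    raise :class:`SegmentTableError`.
    """
    entries = []
    for seg_name, entry in segment_table.items():
        try:
            seg = Segment(seg_name)
        except ValueError:
            raise SegmentTableError(f"unknown segment name {seg_name!r}")
        try:
            start, end = int(entry["start"]), int(entry["end"])
        except (KeyError, TypeError, ValueError):
            raise SegmentTableError(f"segment {seg_name}: needs integer start/end")
        if start > end:
            raise SegmentTableError(f"segment {seg_name}: start {start} > end {end}")
        anchor = entry.get("anchor")
        if anchor is not None:
            m = _ANCHOR_RE.match(str(anchor))
            if not m:
                raise SegmentTableError(f"segment {seg_name}: bad anchor {anchor!r}")
            helix, pos, at = m.group(1), int(m.group(2)), int(m.group(3))
            if not (start <= at <= end):
                raise SegmentTableError(
                    f"segment {seg_name}: anchor residue {at} outside range {start}-{end}"
                )
            anchor = (helix, pos, at)
        entries.append((seg, start, end, anchor))

    entries.sort(key=lambda e: e[1])
    for (s1, a1, b1, _), (s2, a2, b2, _) in zip(entries, entries[1:]):
        if a2 <= b1:
            raise SegmentTableError(
                f"segments {s1.value} ({a1}-{b1}) and {s2.value} ({a2}-{b2}) overlap"
            )

    forward: dict[str, int] = {}
    reverse: dict[int, str] = {}
    bounds: dict[Segment, tuple[int, int]] = {}
    for seg, start, end, anchor in entries:
        bounds[seg] = (start, end)
        for ridx, res in enumerate(topology.residues):
            if res.segment is Segment.LIGAND:
                continue
            if start <= res.author_number <= end:
                res.segment = seg
                if anchor is not None:
                    helix, pos, at = anchor
                    generic = f"{helix}.{pos + (res.author_number - at)}"
                    if generic in forward:
                        raise SegmentTableError(f"duplicate generic number {generic}")
                    forward[generic] = ridx
                    reverse[ridx] = generic
                    res.generic_number = generic
    return GenericNumberMap(forward, reverse, bounds)


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*([A-Za-z0-9_.\-']+|\(|\))")


class _Tokens:
    def __init__(self, query: str):
        self.query = query
        self.items: list[tuple[str, int]] = []
        pos = 0
        while pos < len(query):
            m = _TOKEN_RE.match(query, pos)
            if m is None:
                if query[pos:].strip():
                    raise SelectionError(
                        f"unparseable character at position {pos} in {query!r}"
                    )
                break
            self.items.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.items[self.i] if self.i < len(self.items) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection {self.query!r}")
        self.i += 1
        return tok


def _parse_range(text: str, what: str, pos: int):
    m = re.match(r"^(-?\d+)(?:-(-?\d+))?$", text)
    if not m:
        raise SelectionError(f"bad {what} range {text!r} at position {pos}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    return lo, hi


def _parse_generic_range(text: str, pos: int):
    m = re.match(r"^(\d+)\.(\d+)(?:-(\d+)\.(\d+))?$", text)
    if not m:
        raise SelectionError(f"bad generic-number token {text!r} at position {pos}")
    helix = m.group(1)
    lo = int(m.group(2))
    if m.group(3):
        if m.group(3) != helix:
            raise SelectionError(
                f"generic range {text!r} at position {pos} crosses helices"
            )
        hi = int(m.group(4))
    else:
        hi = lo
    return helix, lo, hi


def _primitive_mask(topology: Topology, gmap: GenericNumberMap | None, tokens: _Tokens) -> np.ndarray:
    word, pos = tokens.next()
    n = topology.n_atoms
    lower = word.lower()
    if lower == "name":
        value, _ = tokens.next()
        return np.array([a.name == value for a in topology.atoms])
    if lower == "segment":
        value, vpos = tokens.next()
        try:
            seg = Segment(value.upper())
        except ValueError:
            raise SelectionError(f"unknown segment {value!r} at position {vpos}")
        return np.array(
            [topology.residues[a.residue_index].segment is seg for a in topology.atoms]
        )
    if lower == "generic":
        value, vpos = tokens.next()
        helix, lo, hi = _parse_generic_range(value, vpos)
        if gmap is None:
            raise SelectionError("'generic' selection requires a GenericNumberMap")
        wanted = set()
        for p in range(lo, hi + 1):
            ridx = gmap.forward.get(f"{helix}.{p}")
            if ridx is not None:
                wanted.add(ridx)
        return np.array([a.residue_index in wanted for a in topology.atoms])
    if lower == "resnum":
        value, vpos = tokens.next()
        lo, hi = _parse_range(value, "residue", vpos)
        return np.array(
            [lo <= topology.residues[a.residue_index].author_number <= hi
             for a in topology.atoms]
        )
    if lower == "sidechain":
        return np.array([a.is_sidechain for a in topology.atoms])
    if lower == "heavy":
        return np.array([not a.is_hydrogen for a in topology.atoms])
    if lower == "protein":
        return np.array(
            [topology.residues[a.residue_index].segment is not Segment.LIGAND
             for a in topology.atoms]
        )
    if lower == "ligand":
        mask = np.zeros(n, dtype=bool)
        mask[topology.ligand_atom_indices] = True
        return mask
    if lower == "all":
        return np.ones(n, dtype=bool)
    raise SelectionError(f"unknown token {word!r} at position {pos}")


def _parse_factor(topology, gmap, tokens: _Tokens) -> np.ndarray:
    tok = tokens.peek()
    if tok is None:
        raise SelectionError(f"unexpected end of selection {tokens.query!r}")
    word, pos = tok
    if word.lower() == "not":
        tokens.next()
        return ~_parse_factor(topology, gmap, tokens)
    if word == "(":
        tokens.next()
        mask = _parse_expr(topology, gmap, tokens)
        closing = tokens.peek()
        if closing is None or closing[0] != ")":
            raise SelectionError(f"missing ')' in selection {tokens.query!r}")
        tokens.next()
        return mask
    return _primitive_mask(topology, gmap, tokens)


def _parse_term(topology, gmap, tokens: _Tokens) -> np.ndarray:
    mask = _parse_factor(topology, gmap, tokens)
    while True:
        tok = tokens.peek()
        if tok is None or tok[0].lower() != "and":
            return mask
        tokens.next()
        mask = mask & _parse_factor(topology, gmap, tokens)


def _parse_expr(topology, gmap, tokens: _Tokens) -> np.ndarray:
    mask = _parse_term(topology, gmap, tokens)
    while True:
        tok = tokens.peek()
        if tok is None or tok[0].lower() != "or":
            return mask
        tokens.next()
        mask = mask | _parse_term(topology, gmap, tokens)


def select(topology: Topology, query: str, gmap: GenericNumberMap | None = None) -> Selection:
    """Evaluate a selection expression against a topology.

    Grammar: primitives ``name <atom>``, ``segment <seg>``, ``generic
    h.p[-h.q]``, ``resnum a[-b]``, ``sidechain``, ``heavy``, ``protein``,
    ``ligand``, ``all`` combined with ``and``/``or``/``not`` and parentheses.
    """
    tokens = _Tokens(query)
    if tokens.peek() is None:
        raise SelectionError("empty selection expression")
    mask = _parse_expr(topology, gmap, tokens)
    trailing = tokens.peek()
    if trailing is not None:
        raise SelectionError(
            f"unexpected token {trailing[0]!r} at position {trailing[1]}"
        )
    return Selection(list(np.nonzero(mask)[0]), description=query)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

_TIME_TOL = 1e-9


def slice_window(frames: FrameSeries, t_start_ns: float, t_end_ns: float) -> FrameSeries:
    """Restrict a FrameSeries to frames with t_start <= t <= t_end (ns)."""
    if not t_start_ns < t_end_ns:
        raise ValueError(f"t_start ({t_start_ns}) must be < t_end ({t_end_ns})")
    mask = (frames.times >= t_start_ns - _TIME_TOL) & (frames.times <= t_end_ns + _TIME_TOL)
    if not mask.any():
        raise EmptyWindowError(
            f"window [{t_start_ns}, {t_end_ns}] ns selects no frames "
            f"(trajectory spans {frames.times[0]}-{frames.times[-1]} ns)"
        )
    return FrameSeries(
        frames.topology, frames.coordinates[mask], frames.times[mask], label=frames.label
    )
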