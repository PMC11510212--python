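"""Ensemble-level statistics.

Differential contact networks (Delta-fraction per residue pair between a
test and a reference ensemble), combined principal component analysis of
concatenated trajectories, dynamic cross-correlation matrices (DCCM),
windowed correlation fractions, and membrane-plane (x/y) projections of
helix-end movements.

Sign convention for differential matrices: delta = f_test - f_ref, so a
positive entry means the interaction is more occupied in the test
ensemble (e.g. agonist-bound) than in the reference (e.g. apo).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import (
    Atom,
    FrameSeries,
    GactdynError,
    GenericNumberMap,
    Residue,
    Segment,
    Selection,
    Topology,
)
from .geometry import kabsch_superpose
from .interactions import ContactSeries

__all__ = [
    "SettingsMismatchError",
    "WindowError",
    "SegmentNotFoundError",
    "DifferentialMatrix",
    "PCAResult",
    "CorrelationResult",
    "ProjectionTrace",
    "delta_fractions",
    "top_differential_pairs",
    "combined_pca",
    "ev_trace_frames",
    "dccm",
    "windowed_correlation_fractions",
    "delta_dccm",
    "delta_correlation_fractions",
    "helix_end_projection",
]


class SettingsMismatchError(GactdynError):
    pass


class WindowError(GactdynError):
    pass


class SegmentNotFoundError(GactdynError):
    pass


# ---------------------------------------------------------------------------
# differential contact networks
# ---------------------------------------------------------------------------

@dataclass
class DifferentialMatrix:
    """Signed Delta-fraction per residue pair, keyed by author-number pairs."""

    delta: dict[tuple[int, int], float]
    kind: str
    labels: tuple[str, str]            # (test, reference)

    def __getitem__(self, pair: tuple[int, int]) -> float:
        return self.delta[tuple(sorted(pair))]


def delta_fractions(
    test: Sequence[ContactSeries],
    ref: Sequence[ContactSeries],
    labels: tuple[str, str] = ("test", "reference"),
) -> DifferentialMatrix:
    """f_test - f_ref over the union of pairs; a pair missing from one
    ensemble contributes fraction 0 there.  Pairs absent from both are
    excluded.  Detector kinds and settings must match."""
    def index(series: Sequence[ContactSeries]) -> dict[tuple[int, int], ContactSeries]:
        return {tuple(sorted(cs.pair_authors)): cs for cs in series}

    ti, ri = index(test), index(ref)
    kinds = {cs.kind for cs in list(test) + list(ref)}
    if len(kinds) > 1:
        raise SettingsMismatchError(f"mixed contact kinds {kinds}")
    settings = [cs.settings for cs in list(test) + list(ref)]
    if settings and any(s != settings[0] for s in settings[1:]):
        raise SettingsMismatchError("contact series computed with different detector settings")
    delta: dict[tuple[int, int], float] = {}
    for pair in sorted(set(ti) | set(ri)):
        ft = ti[pair].fraction if pair in ti else 0.0
        fr = ri[pair].fraction if pair in ri else 0.0
        if ft == 0.0 and fr == 0.0:
            continue
        delta[pair] = ft - fr
    kind = kinds.pop() if kinds else "unknown"
    return DifferentialMatrix(delta, kind, labels)


def top_differential_pairs(
    matrix: DifferentialMatrix, min_abs_delta: float = 0.2
) -> list[tuple[tuple[int, int], float]]:
    """Pairs with |delta| >= threshold, descending |delta|; ties break by
    the pair's author numbers (deterministic)."""
    items = [(pair, d) for pair, d in matrix.delta.items() if abs(d) >= min_abs_delta]
    items.sort(key=lambda kv: (-abs(kv[1]), kv[0]))
    return items


# ---------------------------------------------------------------------------
# combined PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    mean_structure: np.ndarray         # (N, 3) A
    eigenvectors: np.ndarray           # (3N, m) columns, orthonormal
    eigenvalues: np.ndarray            # A^2, descending
    contributions: np.ndarray          # %, sums to 100
    projections: list[np.ndarray]      # per ensemble, (n_frames_e, m)
    labels: list[str]
    topology: Topology                 # subset topology of the analysed atoms

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def _subset_topology(topology: Topology, selection: Selection) -> Topology:
    """Topology containing only the selected atoms (residues renumbered)."""
    old_res: dict[int, int] = {}
    residues: list[Residue] = []
    atoms: list[Atom] = []
    for new_i, i in enumerate(selection.atom_indices):
        a = topology.atoms[i]
        if a.residue_index not in old_res:
            old_res[a.residue_index] = len(residues)
            r = topology.residues[a.residue_index]
            residues.append(Residue(r.author_number, r.insertion_code, r.name,
                                    r.chain, r.segment, r.generic_number))
        atoms.append(Atom(new_i + 1, a.name, a.element, old_res[a.residue_index],
                          a.is_sidechain, a.is_hydrogen))
    lig = [i for i, a in enumerate(atoms)
           if residues[a.residue_index].segment is Segment.LIGAND]
    return Topology(atoms, residues, lig)


def combined_pca(
    ensembles: Sequence[FrameSeries],
    selection: Selection | Sequence[Selection],
    superpose: bool = True,
) -> PCAResult:
    """PCA of the covariance of concatenated, mean-superposed trajectories.

    All ensembles contribute their selected coordinates (one Selection for
    all, or one per ensemble with equal atom counts).  Frames are superposed
    to the concatenated mean structure, with the mean recomputed and the
    fit repeated (two iterations), so neither ensemble's mean biases the
    separating mode; pass ``superpose=False`` for frames already fitted.
    Contributions are eigenvalue / trace as percent.
    """
    if isinstance(selection, Selection):
        selections = [selection] * len(ensembles)
    else:
        selections = list(selection)
        if len(selections) != len(ensembles):
            raise ValueError("need one selection per ensemble")
    sizes = {len(s) for s in selections}
    if len(sizes) != 1:
        raise ValueError(f"selections pick different atom counts: {sizes}")
    n_total = sum(f.n_frames for f in ensembles)
    if n_total < 2:
        raise ValueError("combined PCA needs at least 2 frames in total")

    blocks = [f.coordinates[:, s.index_array, :] for f, s in zip(ensembles, selections)]
    X = np.concatenate(blocks, axis=0)            # (n_total, N, 3)
    if superpose:
        for _ in range(2):
            ref = X.mean(axis=0)
            for k in range(X.shape[0]):
                X[k] = kabsch_superpose(X[k], ref).apply(X[k])
    mean = X.mean(axis=0)
    flat = (X - mean).reshape(X.shape[0], -1)     # (n_total, 3N)
    cov = flat.T @ flat / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    contributions = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    projections = []
    start = 0
    for f in ensembles:
        stop = start + f.n_frames
        projections.append(flat[start:stop] @ evecs)
        start = stop
    return PCAResult(
        mean_structure=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        contributions=contributions,
        projections=projections,
        labels=[f.label for f in ensembles],
        topology=_subset_topology(ensembles[0].topology, selections[0]),
    )


def ev_trace_frames(
    pca: PCAResult, component: int, n_frames: int = 6, amplitude_sigma: float = 2.0
) -> FrameSeries:
    """Mean structure displaced along one eigenvector.

    ``n_frames`` evenly spaced amplitudes spanning +/- amplitude_sigma
    standard deviations (sigma = sqrt(eigenvalue)); exportable as a
    multi-model PDB to visualise the mode.
    """
    if not 0 <= component < pca.n_components:
        raise IndexError(f"component {component} out of range (0-{pca.n_components - 1})")
    sigma = float(np.sqrt(pca.eigenvalues[component]))
    amps = np.linspace(-amplitude_sigma * sigma, amplitude_sigma * sigma, n_frames)
    mode = pca.eigenvectors[:, component].reshape(-1, 3)
    coords = pca.mean_structure[None, :, :] + amps[:, None, None] * mode[None, :, :]
    return FrameSeries(pca.topology, coords, np.arange(n_frames, dtype=float),
                       label=f"EV{component + 1}_trace")


# ---------------------------------------------------------------------------
# residue-pair correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    dccm: np.ndarray                       # residue x residue, NaN where undefined
    residue_indices: list[int]             # topology residue index per row
    window_length: int | None = None       # frames, for windowed fractions
    threshold: float | None = None
    windowed_fractions: dict[tuple[int, int], tuple[float, float]] | None = None
    # pair (row, col in matrix order) -> (fraction of windows C > +t, fraction C < -t)


def _one_atom_per_residue(frames: FrameSeries, selection: Selection) -> list[int]:
    res = [frames.topology.atoms[i].residue_index for i in selection.atom_indices]
    if len(set(res)) != len(res):
        raise ValueError("DCCM selection must pick one atom per residue")
    return res


def _dccm_matrix(X: np.ndarray) -> np.ndarray:
    """Normalized displacement covariance; X is (n_frames, N, 3)."""
    d = X - X.mean(axis=0)
    inner = np.einsum("kia,kja->ij", d, d) / d.shape[0]
    var = np.diag(inner).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.clip(inner / denom, -1.0, 1.0)
    C[(var < 1e-20)[:, None] | (var < 1e-20)[None, :]] = np.nan
    np.fill_diagonal(C, np.where(var >= 1e-20, 1.0, np.nan))
    return C


def dccm(frames: FrameSeries, selection: Selection) -> CorrelationResult:
    """Dynamic cross-correlation matrix of displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) about the mean
    positions.  Frames are expected to be pre-superposed on the same
    selection.  Zero-variance residues yield NaN (missing), never 0.
    """
    if frames.n_frames < 10:
        raise WindowError("DCCM needs at least 10 frames")
    res = _one_atom_per_residue(frames, selection)
    X = frames.coordinates[:, selection.index_array, :]
    return CorrelationResult(_dccm_matrix(X), res)


def windowed_correlation_fractions(
    frames: FrameSeries,
    selection: Selection,
    window: int = 100,
    threshold: float = 0.5,
) -> CorrelationResult:
    """Fraction of non-overlapping windows whose DCCM entry exceeds +/-threshold.

    The whole-trajectory DCCM is returned too.  Windows are non-overlapping
    so the per-window correlations entering the fraction are independent.
    """
    n = frames.n_frames
    if window > n // 2:
        raise WindowError(f"window ({window}) must be <= half the trajectory ({n // 2})")
    res = _one_atom_per_residue(frames, selection)
    X = frames.coordinates[:, selection.index_array, :]
    n_windows = n // window
    mats = np.stack([
        _dccm_matrix(X[w * window:(w + 1) * window]) for w in range(n_windows)
    ])
    N = len(res)
    fractions: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(N):
        for j in range(i + 1, N):
            vals = mats[:, i, j]
            ok = ~np.isnan(vals)
            if not ok.any():
                continue
            pos = float(np.mean(vals[ok] > threshold))
            neg = float(np.mean(vals[ok] < -threshold))
            fractions[(res[i], res[j])] = (pos, neg)
    return CorrelationResult(_dccm_matrix(X), res, window, threshold, fractions)


def delta_dccm(test: CorrelationResult, ref: CorrelationResult) -> np.ndarray:
    """Raw correlation-coefficient difference C_test - C_ref."""
    if test.dccm.shape != ref.dccm.shape:
        raise SettingsMismatchError("DCCM shapes differ between ensembles")
    return test.dccm - ref.dccm


def delta_correlation_fractions(
    test: CorrelationResult, ref: CorrelationResult
) -> dict[tuple[int, int], tuple[float, float]]:
    """Windowed-fraction differences per pair: (delta correlated, delta anti)."""
    if test.windowed_fractions is None or ref.windowed_fractions is None:
        raise SettingsMismatchError("windowed fractions missing; run windowed_correlation_fractions")
    if (test.window_length, test.threshold) != (ref.window_length, ref.threshold):
        raise SettingsMismatchError("windowed fractions computed with different settings")
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for pair in sorted(set(test.windowed_fractions) | set(ref.windowed_fractions)):
        tp, tn = test.windowed_fractions.get(pair, (0.0, 0.0))
        rp, rn = ref.windowed_fractions.get(pair, (0.0, 0.0))
        out[pair] = (tp - rp, tn - rn)
    return out


# ---------------------------------------------------------------------------
# membrane-plane projections of helix ends
# ---------------------------------------------------------------------------

@dataclass
class ProjectionTrace:
    helix: Segment
    end: Literal["intracellular", "extracellular"]
    xy: np.ndarray                     # (n_frames, 2) end-centroid positions
    extents: tuple[float, float] = field(init=False)   # (range_x, range_y) A

    def __post_init__(self) -> None:
        rng = self.xy.max(axis=0) - self.xy.min(axis=0)
        self.extents = (float(rng[0]), float(rng[1]))


def helix_end_projection(
    frames: FrameSeries,
    gmap: GenericNumberMap,
    helix: Segment,
    end: Literal["intracellular", "extracellular"],
    n_end_residues: int = 4,
) -> ProjectionTrace:
    """x/y (membrane-plane) trace of a helix end's Calpha centroid.

    Frames are expected globally superposed; the membrane normal is +z and
    the intracellular side is -z by this package's convention.  The end
    group is the ``n_end_residues`` residues at the appropriate axial
    extreme of the segment.
    """
    top = frames.topology
    members = [r for r in range(top.n_residues) if top.residues[r].segment is helix]
    if not members:
        raise SegmentNotFoundError(f"no residues assigned to segment {helix.value}")
    members.sort(key=lambda r: top.residues[r].author_number)
    ca = []
    for r in members:
        for i, a in enumerate(top.atoms):
            if a.residue_index == r and a.name == "CA":
                ca.append(i)
                break
    mean_z = frames.coordinates[:, ca, 2].mean(axis=0)
    order = np.argsort(mean_z)           # ascending z: intracellular first
    chosen = order[:n_end_residues] if end == "intracellular" else order[-n_end_residues:]
    idx = [ca[i] for i in chosen]
    xy = frames.coordinates[:, idx, :2].mean(axis=1)
    return ProjectionTrace(helix, end, xy)
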