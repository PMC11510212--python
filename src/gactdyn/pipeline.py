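"""Whole-pipeline runs on a test/reference ensemble pair.

Given two trajectory ensembles (e.g. agonist-bound vs apo), the pipeline
computes per-ensemble RMSD, RMSF and ionic-lock series, then the pairwise
comparisons: combined PCA, Delta-fraction matrices for salt bridges,
hydrogen bonds and hydrophobic contacts, and residue-pair correlation
differences (both raw DCCM differences and windowed-fraction differences).
Everything is written as TSV/CSV plus a machine-readable JSON summary and
a provenance record carrying the configuration hash, so any number in the
outputs can be traced to the exact parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .model import (
    FrameSeries,
    GactdynError,
    GenericNumberMap,
    Segment,
    Topology,
    assign_generic_numbers,
    load_frames,
    load_segment_table,
    load_topology,
    select,
    slice_window,
)
from .geometry import rmsd_series, rmsf
from .interactions import (
    hydrogen_bond_contacts,
    hydrophobic_contacts,
    ionic_lock_series,
    salt_bridge_contacts,
)
from .ensemble import (
    combined_pca,
    delta_correlation_fractions,
    delta_fractions,
    top_differential_pairs,
    windowed_correlation_fractions,
)

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(GactdynError):
    """A stage failed; the message names the stage and echoes its parameters."""


@dataclass
class RunConfig:
    ensembles: list[dict]              # [{"path": ..., "label": ...}, ...] test first
    segment_table: str
    outdir: str
    time_step_ns: float = 0.1
    window: list[float] | None = None  # [t_start, t_end] ns; default skips first 20%
    lock_pair: list[str] = field(default_factory=lambda: ["3.50", "6.30"])
    lock_threshold: float = 5.0
    salt_cutoff: float = 4.0
    hbond_d_cut: float = 3.5
    hbond_angle_cut: float = 120.0
    hydrophobic_cutoff: float = 4.5
    ligand_cutoff: float = 4.0
    transition_threshold: float = 30.0
    delta_threshold: float = 0.2
    corr_window: int = 100
    corr_threshold: float = 0.5
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Load and validate a YAML run configuration.

    Every violation is reported at once; a non-empty error list means the
    config is unusable.
    """
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]

    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    for key in ("ensembles", "segment_table", "outdir"):
        if key not in raw:
            errors.append(f"missing required config key {key!r}")

    ensembles = raw.get("ensembles", [])
    if not isinstance(ensembles, list) or len(ensembles) < 2:
        errors.append("ensembles: need at least two entries (test first, reference second)")
    else:
        labels = []
        for e, entry in enumerate(ensembles):
            if not isinstance(entry, dict) or "path" not in entry or "label" not in entry:
                errors.append(f"ensembles[{e}]: needs 'path' and 'label'")
                continue
            labels.append(entry["label"])
            if not Path(entry["path"]).exists():
                errors.append(f"ensembles[{e}]: path {entry['path']!r} does not exist")
        if len(labels) != len(set(labels)):
            errors.append("ensemble labels must be unique")

    if "segment_table" in raw and not Path(str(raw["segment_table"])).exists():
        errors.append(f"segment_table: path {raw['segment_table']!r} does not exist")

    for key in ("lock_threshold", "salt_cutoff", "hbond_d_cut", "hbond_angle_cut",
                "hydrophobic_cutoff", "ligand_cutoff", "transition_threshold",
                "delta_threshold", "corr_threshold", "time_step_ns"):
        if key in raw:
            try:
                if float(raw[key]) <= 0:
                    errors.append(f"{key}: must be positive")
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number")
    if "corr_window" in raw:
        try:
            if int(raw["corr_window"]) < 2:
                errors.append("corr_window: must be >= 2 frames")
        except (TypeError, ValueError):
            errors.append("corr_window: not an integer")
    window = raw.get("window")
    if window is not None:
        if (not isinstance(window, (list, tuple)) or len(window) != 2
                or not all(isinstance(v, (int, float)) for v in window)
                or not window[0] < window[1]):
            errors.append("window: must be [t_start, t_end] with t_start < t_end")

    if errors:
        return None, errors
    return RunConfig(**{k: raw[k] for k in raw if k in known}), []


def _residue_label(top: Topology, residue_index: int) -> str:
    r = top.residues[residue_index]
    tag = r.generic_number or r.segment.value
    return f"{r.name}{r.author_number}({tag})"


def _author_label(top: Topology, author: int) -> str:
    try:
        return _residue_label(top, top.find_residue(author))
    except KeyError:
        return str(author)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.6f}" if isinstance(v, float) else str(v) for v in row
            ) + "\n")


class _Stage:
    """Context manager tagging any failure with the stage name."""

    def __init__(self, name: str, log: list[dict], **params):
        self.name = name
        self.log = log
        self.params = params

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(
                f"stage {self.name!r} failed ({exc}); parameters: {self.params}"
            ) from exc
        self.log.append({"stage": self.name, "params": _jsonable(self.params)})
        return False


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-ensemble comparison; returns the summary dict.

    Deterministic: the same config and inputs produce byte-identical
    numeric outputs (timestamps live only in provenance.json).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    summary: dict[str, Any] = {"config_hash": config.config_hash(), "ensembles": {}}

    with _Stage("segment_table", stages, path=config.segment_table):
        table = load_segment_table(config.segment_table)

    loaded: list[tuple[FrameSeries, GenericNumberMap]] = []
    for entry in config.ensembles:
        with _Stage("load", stages, **entry):
            top = load_topology(entry["path"])
            gmap = assign_generic_numbers(top, table)
            frames = load_frames(entry["path"], top, config.time_step_ns)
            frames.label = entry["label"]
        with _Stage("window", stages, label=entry["label"], window=config.window):
            if config.window is not None:
                frames = slice_window(frames, *config.window)
            else:
                t0, t1 = frames.times[0], frames.times[-1]
                if frames.n_frames > 4 and t1 > t0:
                    frames = slice_window(frames, t0 + 0.2 * (t1 - t0), t1)
        loaded.append((frames, gmap))

    contact_kinds = {}
    for frames, gmap in loaded:
        label = frames.label
        es: dict[str, Any] = {"n_frames": frames.n_frames,
                              "window_ns": [float(frames.times[0]), float(frames.times[-1])]}
        ca = select(frames.topology, "name CA and protein", gmap)
        with _Stage("rmsd", stages, label=label):
            series = rmsd_series(frames, frames.coordinates[0], ca)
            _write_tsv(outdir / f"rmsd_{label}.tsv", ["time_ns", "rmsd_A"],
                       [[float(t), float(v)] for t, v in zip(frames.times, series)])
            es["mean_rmsd_A"] = float(series.mean())
        with _Stage("rmsf", stages, label=label):
            prof = rmsf(frames, ca)
            _write_tsv(
                outdir / f"rmsf_{label}.tsv", ["residue", "rmsf_A"],
                [[_residue_label(frames.topology, r), float(v)] for r, v in prof.rmsf.items()],
            )
            es["mean_rmsf_A"] = float(np.mean(list(prof.rmsf.values())))
        with _Stage("lock", stages, label=label, pair=config.lock_pair,
                    threshold=config.lock_threshold):
            lock = ionic_lock_series(frames, gmap, tuple(config.lock_pair),
                                     config.lock_threshold)
            _write_tsv(outdir / f"lock_{label}.tsv", ["time_ns", "distance_A"],
                       [[float(t), float(d)] for t, d in zip(lock.times, lock.distances)])
            es["lock_broken_fraction"] = lock.broken_fraction
            es["lock_mean_distance_A"] = lock.mean_distance
        with _Stage("contacts", stages, label=label):
            contact_kinds[label] = {
                "salt_bridge": salt_bridge_contacts(frames, cutoff=config.salt_cutoff),
                "hbond": hydrogen_bond_contacts(frames, d_cut=config.hbond_d_cut,
                                                angle_cut=config.hbond_angle_cut),
                "hydrophobic": hydrophobic_contacts(frames, cutoff=config.hydrophobic_cutoff),
            }
        summary["ensembles"][label] = es

    (test_frames, test_gmap), (ref_frames, _ref_gmap) = loaded[0], loaded[1]
    test_label, ref_label = test_frames.label, ref_frames.label
    summary["comparison"] = {"test": test_label, "reference": ref_label}

    with _Stage("combined_pca", stages, test=test_label, reference=ref_label):
        sels = [select(f.topology, "name CA and protein", g) for f, g in loaded[:2]]
        pca = combined_pca([test_frames, ref_frames], sels)
        _write_tsv(
            outdir / "pca_eigenvalues.tsv",
            ["component", "eigenvalue_A2", "contribution_pct"],
            [[i + 1, float(pca.eigenvalues[i]), float(pca.contributions[i])]
             for i in range(min(20, pca.n_components))],
        )
        rows = []
        for label, proj in zip(pca.labels, pca.projections):
            rows += [[label, float(p[0]), float(p[1])] for p in proj]
        _write_tsv(outdir / "pca_projections.tsv", ["ensemble", "EV1_A", "EV2_A"], rows)
        summary["pca"] = {
            "ev1_contribution_pct": float(pca.contributions[0]),
            "ev2_contribution_pct": float(pca.contributions[1]),
        }

    summary["delta_fractions"] = {}
    for kind in ("salt_bridge", "hbond", "hydrophobic"):
        with _Stage(f"delta_{kind}", stages, threshold=config.delta_threshold):
            dm = delta_fractions(contact_kinds[test_label][kind],
                                 contact_kinds[ref_label][kind],
                                 labels=(test_label, ref_label))
            top_pairs = top_differential_pairs(dm, config.delta_threshold)
            _write_tsv(
                outdir / f"delta_{kind}.tsv",
                ["residue_i", "residue_j", "delta_fraction"],
                [[_author_label(test_frames.topology, i),
                  _author_label(test_frames.topology, j), float(d)]
                 for (i, j), d in sorted(dm.delta.items())],
            )
            summary["delta_fractions"][kind] = [
                {"pair": [_author_label(test_frames.topology, i),
                          _author_label(test_frames.topology, j)],
                 "delta": float(d)}
                for (i, j), d in top_pairs
            ]

    with _Stage("correlation", stages, window=config.corr_window,
                threshold=config.corr_threshold):
        corr = {}
        for frames, gmap in loaded[:2]:
            ca = select(frames.topology, "name CA and protein", gmap)
            corr[frames.label] = windowed_correlation_fractions(
                frames, ca, window=min(config.corr_window, frames.n_frames // 2),
                threshold=config.corr_threshold,
            )
        dcf = delta_correlation_fractions(corr[test_label], corr[ref_label])
        rows = [[_author_label(test_frames.topology,
                               test_frames.topology.residues[i].author_number),
                 _author_label(test_frames.topology,
                               test_frames.topology.residues[j].author_number),
                 float(dp), float(dn)]
                for (i, j), (dp, dn) in sorted(dcf.items())
                if abs(dp) >= config.delta_threshold or abs(dn) >= config.delta_threshold]
        _write_tsv(outdir / "delta_correlation_fractions.tsv",
                   ["residue_i", "residue_j", "delta_correlated", "delta_anticorrelated"],
                   rows)
        summary["correlation_pairs_changed"] = len(rows)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": stages,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(_jsonable(provenance), fh, indent=2)
    return summary
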