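# gactdyn

Analysis of GPCR activation dynamics from molecular-dynamics trajectory
ensembles, for structural biologists comparing ligand-bound (holo) and
ligand-free (apo) simulations of class-A receptors such as the serotonin
5-HT2A receptor.

Class-A GPCR activation leaves a well-defined signature in an MD ensemble:
the intracellular "ionic lock" salt bridge between R3.50 (DRY motif, TM3)
and E6.30 (TM6) breaks, the intracellular end of TM6 swings outward, the
W6.48 toggle switch and nearby backbone torsions shift, and the contact
network around TM5/TM6 rewires. `gactdyn` quantifies each of these from
plain coordinate ensembles:

- **Ionic-lock monitoring** — per-frame distance between the Arg
  guanidinium charge centre (mean of CZ/NH1/NH2) and the Glu carboxylate
  centre (mean of CD/OE1/OE2), with the broken fraction over the analysis
  window: frames with d > threshold (default 5 Å).
- **Helix-kink geometry** — per-frame bend, wobble and face-shift angles of
  proline-kinked helices: bend = ∠(û_pre, û_post) between the pre- and
  post-kink helix axes; wobble = direction of the bend about û_pre measured
  from the kink residue's radial direction; face shift = change in helical
  phase across the kink relative to the extrapolated pre-segment twist.
- **Dihedral statistics** — φ/ψ/χ1/χ2 series with circular means and SDs,
  and first-half/second-half transition detection.
- **Differential contact networks** — salt-bridge, hydrogen-bond and
  hydrophobic contact occupancies per residue pair, differenced between
  ensembles as Δf = f_test − f_ref ∈ [−1, 1].
- **Combined PCA** — eigendecomposition of the 3N×3N covariance of the
  concatenated, mean-superposed ensembles; per-component contribution
  λ_i/Σλ and per-frame projections tagged by ensemble.
- **Residue-pair correlations** — DCCM
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) plus windowed correlation
  fractions and their ensemble differences.
- **RMSD/RMSF and membrane-plane (x/y) projections** of helix-end motion.

A synthetic-trajectory generator (`gactdyn.synth`) builds seven-helix
pseudo-receptors, two-state ionic-lock trajectories, designed contact
occupancies, designed motion correlations and proline-kinked helices with
known ground truth, so every analysis stage is verifiable without running
MD. The canonical trajectory format is multi-model PDB; Ballesteros–
Weinstein generic numbers ("3.50") are assigned from a small YAML segment
table with per-helix anchors.

## Worked example

```python
import gactdyn as g
from gactdyn.synth import (HelixSpec, KinkSpec, TwoStateLockSpec,
                           make_kinked_helix, make_two_state_lock_trajectory,
                           make_pseudo_receptor)

# ionic-lock occupancy on a hidden two-state (formed/broken) trajectory
spec = TwoStateLockSpec(p_open=0.56, n_frames=8000, dwell=50, seed=1)
frames, truth = make_two_state_lock_trajectory(spec)
lock = g.ionic_lock_series(frames, truth["gmap"])
print(f"lock broken fraction: {lock.broken_fraction:.3f} "
      f"(hidden truth {truth['broken_fraction']:.3f})")

# kink angles of a TM6-like proline kink
kinked = make_kinked_helix(HelixSpec(14), HelixSpec(14),
                           KinkSpec(bend=34.5, wobble=-63.1, face_shift=89.3,
                                    kink_residue=13))
ks = g.prokink_angles(kinked, 13, pre_range=(0, 13), post_range=(14, 27))
print(f"bend {ks.avg_bend:.2f}  wobble {ks.avg_wobble:.2f}  "
      f"face shift {ks.avg_face_shift:.2f}")

# activation signature of the pseudo-receptor
active, gmap = make_pseudo_receptor(200, activation=True, seed=7)
apo, gmap0 = make_pseudo_receptor(200, activation=False, seed=8)
for label, fr, gm in (("DOI-like", active, gmap), ("APO", apo, gmap0)):
    s = g.ionic_lock_series(fr, gm)
    print(f"{label:8s} lock broken {100*s.broken_fraction:5.1f}% "
          f"mean distance {s.mean_distance:.1f} A")
```

prints

```
lock broken fraction: 0.537 (hidden truth 0.515)
bend 34.50  wobble -63.10  face shift 89.30
DOI-like lock broken  49.0% mean distance 6.5 A
APO      lock broken   1.0% mean distance 4.5 A
```

The first line shows the lock detector recovering the hidden Markov-state
occupancy (the small excess over the truth is the Gaussian distance noise
crossing the 5 Å threshold). The second shows an exact round trip of the
kink construction parameters. The last two lines are the activation
signature: the agonist-like ensemble breaks the lock for about half the
frames while the apo ensemble keeps it formed at 4.5 Å.

## Command line

`gactdyn` exposes each stage as a subcommand over multi-model PDB inputs:

```sh
gactdyn synth --kind pseudo_receptor --frames 200 --seed 7 --out active
gactdyn lock active.pdb --segments segments.yml --out lock.csv
gactdyn prokink helix.pdb --kink 14 --pre 1 14 --post 15 28
gactdyn diff test.pdb ref.pdb --kind salt --threshold 0.2
gactdyn run --config run.yml        # whole two-ensemble comparison
```

`run` writes per-frame TSV series, Δ-fraction tables (residues labelled in
both author and generic numbering), PCA eigenvalues/projections, a JSON
summary and a provenance record keyed by the configuration hash. Exit
codes: 0 ok, 2 configuration error, 3 data error.

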