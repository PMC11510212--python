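# Methods

## Scope and data model

`gactdyn` analyses coordinate ensembles of 7TM receptors for the
conformational signature of class-A GPCR activation. The canonical
on-disk format is the multi-model PDB file (one MODEL per frame), parsed
and written by the package itself so that fixtures remain plain text; an
adapter seam for binary trajectory formats can be layered on top by
constructing `FrameSeries` objects directly. Coordinates are in Å, times
in ns, the membrane normal is +z, and the intracellular side is −z by
convention. Waters and simple ions (HOH/WAT/TIP3/NA/CL/K) are dropped on
ingestion; HETATM residues other than these become the ligand.

Residues carry both author (PDB) numbers and Ballesteros–Weinstein generic
numbers. Generic numbers are assigned from a YAML segment table mapping
each segment to an author-number range plus an anchor
(`"3.50@173"`); within a segment the generic position increments by one
per author residue. Loop-style numbers (e.g. 45.52) are supported only
through explicit anchors, because author and generic numbering are mixed
freely in the literature and no reliable automatic rule exists.

## Ionic lock

The lock metric is the distance between side-chain charge centres: the
mean of the Arg guanidinium atoms (CZ, NH1, NH2; NZ for Lys) and the mean
of the Glu carboxylate atoms (CD, OE1, OE2; CG/OD1/OD2 for Asp). A frame
is "broken" when this distance exceeds `formed_threshold` (default 5.0 Å,
configurable). The charge-centre metric rather than a minimum-atom
distance matches the observation that a formed lock sits near 4.5 Å; no
universal threshold exists in the literature, so the value is logged with
every output. Note that with distance noise of σ ≈ 0.3 Å around a formed
lock at 4.5 Å, a 5.0 Å threshold counts the upper Gaussian tail
(≈ 5% of formed frames) as broken; the estimator is exact whenever the
threshold separates the formed and broken distance distributions.

## Helix-kink geometry (bend / wobble / face shift)

Per frame, helix axes are fitted separately to the pre-kink and post-kink
Cα ranges. The axis direction is obtained from the least-squares screw
operation: the Kabsch rotation superposing residues 1..n−1 onto residues
2..n has the helix axis as its rotation axis. This is exact for an ideal
helix of any length ≥ 4 and degrades gracefully under noise (worst-case
≈ 3.5° at σ = 0.3 Å for 12 residues). A principal-component direction was
rejected: it is biased by up to tens of degrees for short helical arcs
because the Cα phases do not cover full turns. The axis point is the
algebraic circle-fit centre of the Cα positions projected on the normal
plane.

With û_pre and û_post the two axis directions (oriented N→C):

- **bend** = arccos(û_pre·û_post) ≥ 0;
- **wobble** = signed angle, right-handed about û_pre, from the kink
  residue's radial direction (Cα minus its foot on the pre-axis) to the
  projection of û_post onto the plane ⊥ û_pre;
- **face shift** = circular mean over the post residues of (observed
  helical phase about û_post) − (phase predicted by extrapolating the
  pre-segment twist), with the phase reference frame transported from the
  pre-axis to the post-axis by the minimal rotation taking û_pre to
  û_post. The pre-segment twist is the slope of the unwrapped pre-segment
  phases, so a non-canonical helix geometry does not bias the face shift.

Wobble loses meaning as the bend approaches zero; frames with bend below
`bend_floor` (default 5°, configurable) are flagged `wobble_reliable =
False`. These conventions are validated by round-trip against the
generator (construction parameters recovered to well under 1° for bends
of 10–60°); they may differ from other Prokink implementations by a fixed
sign or offset, so cross-tool comparisons should compare differences
between ensembles rather than absolute wobble/face-shift values.

## Dihedrals and circular statistics

Torsions follow the standard IUPAC sign convention (cis = 0°,
trans = 180°), verified against MDAnalysis on random quadruples. φ uses
(C_{i−1}, N_i, CA_i, C_i), ψ uses (N_i, CA_i, C_i, N_{i+1}); χ1/χ2 use
the standard side-chain atom tables for the twenty amino acids. All
angle averages are circular (atan2 of mean sine and cosine): arithmetic
averages are wrong near ±180°, which matters in practice — e.g. a φ
angle near −157° wraps. A degenerate (zero-resultant) angle set raises
an error rather than returning an arbitrary mean. The half-split
transition detector compares circular means of the first and second
halves of the analysis window and flags differences above a threshold
(default 30°); the threshold is configurable because "substantial
change" has no canonical value.

## Contact detectors

All detectors are residue-level: a pair is in contact in a frame if any
qualifying atom pair satisfies the criterion; fractions are plain means
of the boolean series. Defaults (all configurable, all echoed in output):

| detector     | criterion                                              | default |
|--------------|--------------------------------------------------------|---------|
| salt bridge  | min basic side-chain N to acidic side-chain O distance | 4.0 Å   |
| hydrogen bond| donor–acceptor N/O distance AND D–H…A angle            | 3.5 Å, 120° |
| hydrophobic  | any side-chain heavy-atom pair with ≥ 1 carbon         | 4.5 Å   |
| ligand       | any heavy-atom pair to ligand                          | 4.0 Å   |

His is counted as basic only on request (protonation is unknowable from
coordinates alone). Donor hydrogens are identified by proximity (≤ 1.25 Å
in the first frame); in a heavy-atom-only topology the angle criterion is
skipped and the output flags `angle_criterion: False`. Hydrophobic
eligibility requires only one apolar partner (A/V/L/I/P/F/M/W/C), since
carbon-mediated proximity of mixed pairs such as Ser–Ile is a real
packing interaction; pairs closer than 3 in sequence within a segment are
excluded as trivial. Hydrogen-bond pairs additionally exclude
sequence-adjacent residues. Differential matrices are Δf = f_test −
f_ref over the union of pairs (missing ⇒ 0), with exact antisymmetry
under swapping the roles; pairs absent from both ensembles are excluded.

## Combined PCA

Frames of all ensembles are concatenated and superposed to the
concatenated mean (two mean-refit iterations), so neither ensemble's mean
biases the separating mode; the 3N×3N covariance is then
eigendecomposed. Contributions are λ_i/Σλ as percent and sum to 100.
Eigenvector traces displace the mean structure by ±2σ (σ = √λ) in six
frames by default, exportable as multi-model PDB. `superpose=False` is
available for pre-fitted frames.

## Residue-pair correlations

DCCM entries are normalized displacement covariances about the mean
position. Zero-variance residues yield missing values, never 0 (a frozen
residue is not "uncorrelated"). "Fraction of correlated windows" is
computed over non-overlapping windows (default 100 frames = 10 ns at a
100 ps stride) as the fraction with C > +t and with C < −t (default
t = 0.5); windows are non-overlapping so the counts entering the fraction
are independent. Because the literature does not fix whether correlation
heatmaps difference raw coefficients or windowed fractions, both ΔC and
Δfraction are computed and exported.

## Synthetic generators and what they do / do not show

Every generator is a pure function of its spec and seed and returns its
ground truth (hidden states, truth tables, construction angles) for
oracle tests.

- **Two-state lock**: a hidden Markov chain with stationary open
  probability `p_open` and mean episode length `dwell` (default 50
  frames, emulating the long dwell episodes seen in lock-distance traces),
  emitting charge-centre distances of 4.5 Å (formed) / 12.5 Å (broken)
  plus Gaussian noise (σ 0.3 Å). The Markov structure forces occupancy
  estimators to face realistic autocorrelation: at p_open = 0.56 and
  n = 8000 the effective sample size is ≈ 165, not 8000.
- **Occupancy fixtures**: per-frame Bernoulli contact states placing
  template side-chain groups exactly at the contact or apart distance, one
  isolated site per pair; templates exist for all three detector kinds.
- **Correlation fixtures**: per-axis bivariate normal displacements with
  correlation equal to the target (degenerate at ±1), so the DCCM entry
  equals the target in expectation.
- **Kinked helices**: ideal α-helix parameters (rise 1.5 Å, twist 100°,
  radius 2.3 Å) with the post-segment phase-shifted and tilted by the
  construction angles. The face shift is applied as a phase jump, so the
  backbone is deliberately discontinuous at the kink — detectors only
  read Cα positions of the flanking ranges.
- **Pseudo-receptor**: seven 25-residue ideal helices on a 12 Å circle
  with alternating up/down orientation as in a real 7TM fold, x.50
  anchors, an Arg/Glu charge-group pair forming a 4.5 Å lock near the
  intracellular ends of TM3/TM6, 0.3 Å thermal jitter, and (when active)
  a progressive outward swing of the intracellular third of TM6 over the
  second half of the trajectory that carries the Glu group from 4.5 to
  12.5 Å, plus a pseudo-ligand glued near the extracellular ends of
  TM5/TM6.

Passing tests on these fixtures demonstrates that the estimators recover
known construction parameters under autocorrelation, noise and rigid
motion. They do not demonstrate force-field realism: the generators have
no energetics, no rotamer structure beyond the atoms the detectors read,
and motion amplitudes chosen for clear signal rather than physical
fidelity. Quantities from real MD ensembles (e.g. specific Δ-fraction
values or PCA contributions) depend on the trajectories themselves and
are not reproduced by the synthetic stand-ins.

## Numerical choices

- Superposition by Kabsch SVD with reflection guard; degenerate fits
  (< 3 atoms or collinear) raise errors.
- RMSF uses a two-pass mean-structure fit (mean, refit, mean).
- Angles are wrapped to (−180°, 180°]; all invariance tests run at 1e-6°.
- PDB coordinates round-trip at the format's 0.001 Å precision.
- The analysis window defaults to dropping the first 20% of each
  trajectory (equilibration) when not given explicitly.
- Pipeline outputs are byte-deterministic for a fixed config and inputs;
  timestamps appear only in the provenance record.

## Problem sizes

Tests and the acceptance script run the full stack at desk scale: 50
random kinks of 24 residues, 8000-frame lock chains, 20 occupancy designs
of 5000 frames, 10000-frame correlation fixtures, and 120–200-frame
pseudo-receptor ensembles of ~180 atoms. These sizes give sampling errors
well inside the asserted tolerances while keeping the whole suite in the
tens of seconds.

## Known limitations

- No automatic generic-numbering from sequence; the segment table is the
  single source of truth.
- Hydrogen-bond detection without hydrogens reduces to a distance
  criterion.
- No π-stacking, cation-π or water-mediated interactions.
- Kink conventions are self-consistent and generator-validated, not
  calibrated against any external kink-analysis tool.
- The multi-model PDB reader expects well-formed fixed columns; malformed
  lines fail loudly with the line number rather than being skipped.
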