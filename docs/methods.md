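# Methods

## Model and quantities

All analysis operates on a fixed, ordered atom set with coordinates in Å.
The root-mean-square deviation between matched coordinate sets is the
unweighted

RMSD(a, b) = sqrt( (1/N) Σᵢ δᵢ² ),

with δᵢ the distance between atom i and its reference position. No mass
weighting is applied anywhere.

Per system (trajectory), the package computes:

- **Movement RMSD (M).** Per-frame RMSD against the trajectory's own
  per-atom time-average structure; the scalar M is the arithmetic mean of
  the series, reported together with SD, min and max. Because the time
  average is the least-squares minimiser, the inequality "own-average RMSD
  ≤ fixed-reference RMSD" is exact only for the *root-mean-square* of the
  series, so `RmsdSeries.rms` is exposed alongside the arithmetic mean and
  the property tests use the RMS form.
- **Reference RMSD.** Per-frame RMSD against a fixed external structure
  (a crystal), on the atom map between trajectory topology and reference.
- **RMSF.** Per atom, sqrt of the time-mean squared displacement from that
  atom's time-average position; per residue, the unweighted mean over the
  residue's selected atoms (a Cα-only reduction is available).
- **Minimum-distance series.** Per frame, the minimum Euclidean distance
  between a trajectory atom group and a fixed (or per-frame) reference
  group, e.g. the crystal pose of a ligand versus the protein — for
  unliganded systems the crystal ligand coordinates serve as the fixed
  reference.

Per pair of systems, on the atoms matched between the two topologies by
(chain, residue number, atom name):

- **Joint-reference RMSD (A₁, A₂).** Mean per-frame RMSD of each system
  against the average structure of the pooled frames of both systems.
- **Score S = (A₁ − M₁) + (A₂ − M₂).** M here is recomputed on the mapped
  atoms so both terms describe the same atom set. S is symmetric, exactly
  zero for a system paired with a copy of itself, and invariant under a
  rigid offset applied identically to both trajectories (fitting off).
  Higher S means more structural difference beyond intrinsic movement.

The 2×2 cross-over study takes four systems (two origin structures × ligand
present/absent) and two crystals (one liganded, one unliganded), and emits
reference-RMSD means, M summaries, the six pair scores sorted ascending
(ties broken by labels, so the ranking is deterministic), and a per-system
verdict: the system "resembles" the crystal with the lower mean reference
RMSD; resemblance to the crystal whose ligand state matches the system's
own is called induced fit, the cross pairing no induced fit, and an exact
tie is reported as indeterminate.

## Superposition convention

No fitting is performed before RMSD by default: the intended inputs are
trajectories produced with a fixed positional reference (e.g. a restrained
heme group), which already share a coordinate frame, and fitting would
silently absorb part of the signal. An explicit fit flag enables a Kabsch
least-squares superposition (proper rotations only; reflections are
rejected) computed on a chosen selection. Crystal-vs-crystal RMSD is the
exception: two crystals share no frame, so `crystal_rmsd` fits by default.
The fit requires ≥ 3 non-collinear points; collinearity is detected from
the second singular value of the centred covariance (relative threshold
1e-10). The rotation itself comes from scipy's `Rotation.align_vectors`.

## Averaging choices

- The scalar M and the A values are arithmetic means over frames (a table
  reporting one RMSD with SD/min/max implies the arithmetic mean); the RMS
  alternative is exposed for the minimiser property.
- The joint average weighs every pooled frame equally; if the two systems
  have different frame counts the longer one contributes proportionally
  more. A per-system equal weighting (`weighting="system"`) is available.
- Scores are computed from unrounded M/A and rounded only at render time;
  rounding M/A first and then combining can differ by ±0.1 in the last
  digit, which is why machine-readable output keeps full precision.
- Frames are uniformly weighted; equilibration trimming is an explicit
  `--skip-frames` option, default 0.

## Selections and atom matching

Residue numbers are PDB author numbering, never renumbered, so literature
ranges apply verbatim; the `active-site-cyp3a4` preset hard-codes the six
CYP3A4 active-site segments (54–60, 100–122, 207–218, 238–244, 296–311,
367–375). `main_chain` is {N, CA, C, O}; `heavy` excludes hydrogens
(element column, with an atom-name heuristic when the element is blank).
HETATM atoms (ligand, heme, waters) are excluded from protein selections
unless requested by residue name; `all` keeps everything. Alternate
locations default to the first (blank/"A") convention, occupancy ignored.
Atom matching across structures keys on (chain, resnum, name), keeps the
intersection in the first structure's order, and logs how many atoms each
side dropped (crystal structures with unresolved loop residues simply
contribute fewer pairs). Coordinates are assumed whole-molecule; no
periodic-boundary unwrapping is done.

## Synthetic trajectories

`simulate_fluctuation` draws per-atom, per-coordinate Gaussian noise around
a base structure, optionally AR(1)-correlated in time with stationary SD
equal to sigma (the first frame is drawn from the stationary distribution).
`simulate_two_state` adds drift between two matched conformers via a hard
switch frame or an arbitrary per-frame blend schedule. There is no
inter-atom covariance (no elastic-network coupling), no solvent and no
force field: the generator reproduces the *statistical* structure the
analysis assumes — amplitudes, temporal correlation, conformer occupancy —
with known ground truth, which is exactly what the closed forms need: an
atom with per-coordinate SD σ has RMSF σ√3, and for many atoms the
per-frame RMSD concentrates so the mean movement RMSD → σ√3 (0.866 Å at
σ = 0.5 Å). Passing tests therefore validate the estimators and the score
algebra, not the realism of protein force fields; anisotropic or
collectively coupled motions in real MD are not emulated.

`make_crossover_fixture` packages a full 2×2 study: a 60-residue toy
backbone (4 atoms/residue, 3.8 Å Cα spacing), an 11-residue loop relocated
by 4 Å between the apo and holo conformers, a rigid 5-atom dummy ligand
held fixed in the liganded systems, stiff liganded (default σ = 0.2 Å) vs
floppy unliganded (σ = 0.7 Å) dynamics, and a brief initial dwell (5 % of
frames) in the start conformation before each cross-over system adopts its
destination conformer — enough to make the within-condition pairs the two
most similar and every verdict induced fit, mirroring the qualitative
pattern the analysis is designed to detect. Per-system seeds are spawned
from one master seed, so fixtures are bitwise reproducible.

Default problem sizes (60 residues, a few thousand frames) keep every
statistic's Monte-Carlo error well below the effects being measured while
the full suite runs in about a minute.

## File formats

PDB (single- and multi-model) via biotite; DCD (CHARMM/NAMD, float32)
via mdtraj's low-level reader — both store Å natively. Multi-model frames
are checked atom-by-atom against the topology and errors name the
offending frame; malformed fixed-column records are reported with their
line number. Round-tripping preserves coordinates to format precision
(10⁻³ Å for PDB, float32 for DCD).

## Known limitations

- The score compares time-averaged occupancies of conformational space; two
  systems that visit the same states with different kinetics score ≈ 0.
- Arithmetic-mean M can exceed arithmetic-mean A in small-sample or
  strongly drifting cases (the minimiser guarantee is RMS-form only), so
  single pair scores can be slightly negative; this is expected behaviour
  of the published definition, not an error.
- mmCIF, solvent/ion handling and PDB retrieval are out of scope; users
  supply files.
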