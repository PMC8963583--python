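# crossflex

Cross-over induced-fit analysis of liganded/unliganded protein trajectory
pairs.

**Who it is for.** Structural bioinformaticians who have molecular-dynamics
trajectories of the same enzyme simulated with and without a bound ligand —
classically an apo/holo crystal pair such as CYP3A4 1TQN (apo) and 3NXU
(ritonavir-bound) — and want a numerical answer to the question: *does the
ligand induce a distinct enzyme geometry (induced fit), and how similar are
two systems' sampled conformations once their intrinsic mobility is
discounted?*

## The statistics

For a trajectory of frames $x_t$ over $N$ matched atoms, with $\bar{x}$ the
per-atom time average:

- **Movement RMSD** $M = \frac{1}{T}\sum_t \mathrm{RMSD}(x_t, \bar{x})$,
  where $\mathrm{RMSD}(a,b) = \sqrt{\tfrac{1}{N}\sum_i \delta_i^2}$ and
  $\delta_i$ is the distance of atom $i$ from its reference position. $M$
  measures a system's intrinsic mobility, independent of any external
  reference.
- **Joint-reference RMSD** $A_k$: the same per-frame average for system
  $k$, but against the average structure of *both* systems' pooled frames.
- **Bias-corrected pair similarity score**

  $$S = (A_1 - M_1) + (A_2 - M_2).$$

  If two systems sample the same region of conformational space, the joint
  average coincides with each own average and $S \approx 0$; the further
  apart the sampled regions, the larger $S$. Subtracting $M$ removes the
  bias that a stiff (liganded) system would otherwise look "different"
  from a floppy one merely because it moves less.

A 2×2 **cross-over study** pairs two start structures (apo and holo
crystals) with two ligand states (ligand present/absent): four systems, six
pairwise scores, plus per-system RMSD against both crystals. A liganded
system ending closer to the holo crystal — or an unliganded one closer to
the apo crystal — is evidence of induced fit. Per-residue RMSF profiles and
minimum-distance series between a ligand reference pose and the protein
complete the picture.

By default no superposition is applied before RMSD (trajectories produced
with a fixed positional restraint, e.g. a restrained heme group, already
share a frame); an optional Kabsch fit handles inputs that do not. Crystal
vs. crystal comparisons always fit, since two crystals share no frame.

## Worked example

A synthetic cross-over study with known ground truth: a 60-residue toy
protein whose 11-residue loop is relocated by 4 Å between the apo and holo
conformers, liganded systems stiff (σ = 0.2 Å per coordinate), unliganded
floppy (σ = 0.7 Å), 2000 frames each:

```python
import crossflex as cf

fx = cf.make_crossover_fixture(stiff_sigma=0.2, floppy_sigma=0.7,
                               n_frames=2000, seed=7)
sel = cf.Selection(atom_class="main_chain")
report = cf.crossover_study(fx.systems, fx.crystals, selection=sel)

from crossflex.report import pair_table
print(pair_table(report))
```

```
    system1   system2  M1_A  M2_A  A1_A  A2_A  score_A
0  HOLO+LIG   APO+LIG   0.3   0.4   0.3   0.4     -0.0
1   APO-LIG  HOLO-LIG   1.2   1.3   1.2   1.3      0.0
2   APO+LIG  HOLO-LIG   0.4   1.3   0.9   1.5      0.7
3   APO-LIG   APO+LIG   1.2   0.4   1.5   1.0      0.8
4  HOLO+LIG  HOLO-LIG   0.3   1.3   0.9   1.5      0.8
5  HOLO+LIG   APO-LIG   0.3   1.2   0.9   1.5      0.8
```

Reading the table: the two liganded systems (row 0) and the two unliganded
systems (row 1) score ≈ 0 — they sampled the same conformer, despite the
unliganded pair moving three times as much (M ≈ 1.2 vs 0.3 Å). Every
liganded/unliganded pair scores ≈ 0.8 Å: a genuine structural difference
(the relocated loop) that survives the movement correction. The per-system
verdicts all come out `induced_fit`, matching how the fixture was built.

The same pipeline runs from the shell:

```sh
crossflex simulate --n-frames 300 --seed 7 --out fixture/
crossflex crossfit fixture/study.yaml --out report/
crossflex rmsd traj.pdb top.pdb --reference crystal.pdb \
    --selection active-site-cyp3a4
```

`--selection active-site-cyp3a4` expands to the six literature CYP3A4
active-site segments (residues 54–60, 100–122, 207–218, 238–244, 296–311,
367–375).

As a calibration of the movement statistic: isotropic Gaussian fluctuation
with σ = 0.5 Å per coordinate gives `M = 0.865 Å` over 5000 frames
(closed form σ√3 ≈ 0.866 Å).

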