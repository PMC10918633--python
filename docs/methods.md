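# Methods

## The model

shapeflex treats a molecule's shape as the boundary of the union of
atom-centered spheres with element-specific van der Waals radii (Bondi
table, overridable). The surface is represented as a dense *colored point
cloud*: each point carries the pharmacophoric class of its nearest atom,

| class | meaning | members |
|---|---|---|
| 1 | apolar | nonpolar H; Cl, Br, I |
| 2 | polar / H-bond capable | N, O, S, F; H bonded to N or O |
| 3 | skeleton | C, P, B |
| 4 | other | everything else |

Aligning two molecules means rigidly registering the source cloud onto the
fixed target cloud and scoring the overlay with Tversky-style (α = 0)
source-coverage scores:

* **gfit** = fraction of source points with a target point within the
  match radius (0.7 Å default). A shape perfectly embedded in the target
  scores 1.0, which makes the score asymmetric on purpose: a fragment can
  score 1.0 against a larger molecule.
* **hfit** = fraction of class-matched points among source points outside
  class 1 (the apolar class dominates surfaces and would otherwise
  swamp the signal). Both scores are in [0, 1]; the optimization target is
  their sum.

## Rigid registration

1. *Sampling.* Each atom's sphere is sampled with a deterministic
   Fibonacci lattice at the configured density (default 10 points/Å²,
   giving a few thousand points for a drug-sized molecule); points
   strictly inside another sphere are removed. The lattice is laid out in
   an atom-local frame built from bonded-neighbor directions, so the cloud
   co-rotates exactly with the molecule and needs no random seed.
2. *Global registration.* FPFH descriptors (33-bin, standard α/φ/θ
   histograms with distance-weighted neighbor pooling; normals are the
   exact sphere normals) are computed on voxel-downsampled clouds
   (0.8 Å voxel) and matched by mutual nearest neighbor in feature space.
   A seeded RANSAC over 3-point correspondence triples, with an
   edge-length-compatibility prefilter and inlier count as consensus,
   yields the coarse transform, polished by a short geometric ICP.
3. *Colored refinement.* Class-aware ICP: for each source point the
   correspondence is chosen among the k = 6 nearest target points within
   1.5 Å by the cost d² + λ·(1 Å²)·[class differs], and class-mismatched
   pairs enter the weighted Kabsch update with weight 1 − λ (λ = 0.5
   default). The routine returns whichever of {initial, refined} transform
   scores the higher fitness total, so refinement can never degrade an
   overlay.

Because the pipeline is stochastic only through RANSAC, each alignment run
derives its own sub-seed from the master seed (SHA-256 of seed + labels,
truncated below 2³¹), and repeated runs with the best-total selection are
the intended way to escape bad basins (defaults: 10 conformers × 2 runs).

## Flexible alignment

The flexible optimizer improves a rigid overlay by optimizing the source
*conformation* under the constraint of the target shape:

1. **Fragmentation** (bond graph only): fused/spiro ring systems are the
   connected components of the ring-bond graph; exocyclic double-bonded
   atoms stay with their ring; acyclic atoms linking two ring systems form
   linkers (union of shortest chains between attachment atoms, side
   branches split off as substituents); remaining acyclic appendages are
   substituents; hydrogens follow their heavy atom. An acyclic molecule is
   one substituent fragment. The minimum fragment size is 1 heavy atom —
   a methyl or a halogen is a legitimate fragment (a higher threshold
   merges such pieces into their largest neighboring fragment and is
   config-exposed, but collapses e.g. toluene to a single fragment).
2. **Fragment re-alignment**: each fragment's sub-cloud is re-aligned
   independently against the target points within 4.0 Å of it, using the
   colored refinement seeded at the current pose. Moves beyond 3.0 Å
   centroid displacement or 60° rotation are rejected (fragments must stay
   attachable), as are moves that do not improve the fragment's own
   fitness objective (gfit+hfit by default).
3. **Reassembly + MMFF94**: fragment transforms are applied and the
   geometry relaxed with MMFF94 (500 cycles). Heavy atoms of fragments
   that moved are held by flat-bottom position restraints (free within
   0.3 Å, then 100 kcal/mol/Å²): the restraints let the minimizer repair
   the distorted attachment bonds and angles without simply pulling the
   fragments back to where they started, which plain minimization does.
   The reported energies are always plain MMFF94 energies of the final
   geometry.
4. **Final registration**: the relaxed conformer is registered once more
   onto the target with the colored refinement (a full new global
   registration is off by default and config-switchable).
5. **Acceptance**: steps 1–4 form one sweep; sweeps are iterated (3 by
   default, stopping early when the score total stalls below 10⁻³), and
   the best-scoring conformer is kept only if its gfit+hfit strictly
   exceeds the rigid baseline. Otherwise the rigid pose is returned
   unchanged, so the flexible result never scores below the rigid one.

Ensembles: ETKDG-embedded conformers, MMFF94-optimized, pruned at 1.0 Å
symmetry-aware heavy-atom RMSD (re-checked after optimization so the
returned coordinate sets respect the threshold). Each conformer × run gets
a derived seed; the single best total wins, ties to the earlier trial.

## Pose grading

`rmsd_in_place` matches atoms over all graph automorphisms (element- and
bond-aware, via substructure matching on the sanitized molecule, so
aromatic rings keep their full symmetry) and evaluates RMSD on fixed
coordinates — the relevant score when the question is whether an overlay
was reproduced in the target's frame. `rmsd_best_fit` adds a Kabsch
superposition per matching and measures pure conformational difference.
Default scope is heavy atoms (hydrogen positions are generator-dependent).
Benchmark tables report mean RMSD and the fractions of poses within
0.5 / 1 / 2 Å, which are nested by construction.

The cross-alignment harness selects, for each ligand, the pose with the
lowest RMSD to its own reference across all partners — an evaluation-only
oracle that deliberately peeks at the answer, mirroring the
best-predicted-ensemble protocol; blind use must rely on the fitness
scores instead. Whether the per-overlay mean should average over ligands
or over ligand-pair alignments is ambiguous, so the table carries both
(`mean_rmsd`, `settings["mean_pair_rmsd"]`).

## Synthetic fixtures — what they do and do not show

The bundled 30-molecule SMILES list spans 1–8 fragments per molecule
(mean ≈ 3.2), rotatable-bond counts from 0 to ~12, halogens and H-bond
donors/acceptors so all four point classes occur. A fixture case pairs a
minimized ETKDG reference with decoys built by rotating 1–3 rotatable
heavy-atom torsions by 60–180° and re-minimizing with those torsions
restrained — a controlled analog of the experimental-vs-generated
conformer gap.

What passing the fixture benchmark shows: the flexible optimizer
systematically recovers torsion-level conformational error that rigid
alignment cannot, and the score totals order poses usefully. What it does
not show: performance on experimental X-ray geometries (crystal
conformations are not MMFF94 minima), on charged/tautomeric systems, on
macrocycle ring-conformation errors (decoys perturb acyclic torsions
only), or at the chemical diversity of the public overlay benchmarks.

Benchmark problem sizes in the shipped tests (20 molecules × 10 conformers
× 2 runs for the self-alignment analog; 24 decoy cases for the
median-recovery property) were chosen as the smallest sets at which the
rigid-vs-flexible gap is stable across seeds.

## Numerical choices and degenerate inputs

* Surface points exactly on another sphere's boundary survive only on the
  lowest-indexed atom, so exactly superimposed atoms contribute one
  surface, not two; burial uses a 10⁻⁶ Å strict-interiority tolerance.
* Nearest-atom labeling uses surface distance (center distance minus
  radius), ties to the lower atom index.
* RANSAC falls back to a centroid shift when no 3-triple consensus exists;
  colored ICP returns the initial transform (with a warning) when no
  correspondences lie within the search radius.
* Clouds below `min_cloud_size` (50 points) are rejected for registration;
  raise the density for very small molecules.
* Graded recovery of a known motion is only defined up to the molecule's
  geometric symmetry group (a benzene cloud is invariant under 60°
  rotation); the test suite grades it accordingly.
* MMFF94-unparameterizable molecules raise in single-molecule operations
  and are excluded (with a count) in benchmark batches.

## Known limitations

* Fragment moves are local (3 Å / 60° per sweep); grossly folded decoys
  whose rigid overlay is already poor (total ≲ 1.0) are usually not
  rescued from a single start — conformer ensembles and repeated runs are
  the intended remedy, exactly as in the published protocol.
* hfit's denominator convention (exclude all of class 1 vs only nonpolar
  hydrogens) changes absolute values on halogen-rich molecules; both are
  implemented (`hfit_exclude`), compare like with like.
* The point-count magnitudes match the published clouds only to order of
  magnitude; the exact original sampler density is not recoverable.
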