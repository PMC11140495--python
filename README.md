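# latticepick

Lattice-aware particle picking for cryo-electron tomography.

Biological complexes often assemble into flexible, partial or imperfect
lattices (viral protein shells, bacterial S-layers, axonemal repeats).
`latticepick` traces such lattices by iterative constrained template
matching: starting from a few seed particles, it repeatedly predicts
neighbor positions through a user-defined *transition list* (local-frame
displacement vectors), aligns each candidate to a reference by masked
normalized cross-correlation over restricted angular/translational search
grids, and accepts candidates whose correlation passes a threshold —
accepted particles seed the next iteration until the lattice is exhausted.

The package also provides:

* **geometry-based cleaning** — flag particles with too few neighbors or a
  large mean inter-axis tilt (a local-curvature proxy),
* **segmentation-label round trips** — build binary cube-label volumes from
  coordinates (training targets for voxel classifiers) and retrieve
  coordinates from segmentation/probability maps by single-linkage
  clustering,
* **post-processing** — recenter along local axes, convert the lattice axis
  from local Y to local Z, export place-back marker/transform files and
  bad-particle-free STAR tables, assemble per-tomogram tables,
* **synthetic data** — ground-truth hexagonal lattices on planes and
  spheres (geodesic, with coherent orientation fields), 1D filament
  repeats, oriented-template rendering with Gaussian noise, and a
  deterministic two-patch worked-example fixture,
* **standard formats** — MRC volumes (mode 2), Relion-4-style STAR particle
  tables, two-point seed files, JSON parameter files.

## Conventions

* Volumes are numpy arrays indexed `[x, y, z]`; MRC files are transposed at
  the I/O boundary (sections on disk run `[z, y, x]`).
* Positions are continuous 0-based voxel coordinates `(x, y, z)`.
* Orientations are intrinsic ZYZ Euler angles `(rot, tilt, psi)` in
  degrees; the matrix maps particle-local coordinates into the tomogram.
* A particle's lattice-normal axis is its **local Y** (two-point stalk
  convention); `latticepick placeback`/`postprocess.yaxis_to_z` convert to
  the local-Z convention expected downstream.

## Command line

```bash
latticepick simulate --kind two-patch --out-dir fixture/   # synthetic data
latticepick seeds --pairs picks.txt --out seeds.star       # 2-point picks
latticepick expand --tomo fixture/volume.mrc \
    --seeds fixture/seeds.star --reference fixture/reference.mrc \
    --mask fixture/mask.mrc --params fixture/params.json --out-dir run/
latticepick regather --cache-dir run/volume_cache --seeds fixture/seeds.star \
    --cc-threshold 0.8 --d-min 4 --out re.star              # iteration-0 mode
latticepick clean --star run/volume_final/particles.star --radius 12 \
    --out clean.star --stats-out stats.tsv
latticepick labels --star clean.star --shape 152 96 32 --cube-side 3 \
    --out labels.mrc
latticepick seg2coords --map labels.mrc --out coords.star
latticepick placeback --star clean.star --radius 12 --out-prefix pb --cmm
latticepick assemble t1.star t2.star --out all.star
```

`expand` writes the per-tomogram `NAME/` (working, with `run.log` and the
effective parameters), `NAME_cache/` (one JSON record per iteration) and
`NAME_final/particles.star`, and logs the per-iteration bookkeeping
(seeds, candidates, accepted, rejected). `regather` re-thresholds the
cached alignments without re-aligning anything.

The expansion parameter JSON mirrors `latticepick.core.ExpansionParams`:

```json
{
  "transition_list": [[8, 0, 0], [4, 0, 6.93], "... local-frame voxels"],
  "spacing": 8.0,            // expected neighbor distance, voxels
  "cc_threshold": 0.5,
  "box_size": 16,            // alignment box side, voxels
  "angular_ranges": [8, 8, 8],   // half-ranges, degrees (local X/Y/Z offsets)
  "angular_steps": [4, 4, 4],    // degrees
  "translational_range": 2.0,    // voxels
  "translational_step": 1.0,     // voxels
  "max_iterations": 20,
  "d_min": 4.0               // dedup distance, voxels (default spacing/2)
}
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(worked-example bookkeeping, recovery on a noise-free and noisy geodesic
sphere, termination/dedup, regather equivalence, cleaning, segmentation
round trips, I/O exactness). The sphere-recovery tests take several
minutes; everything else runs in seconds.

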