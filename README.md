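# voxpocket

Geometric detection and ranking of concave ligand-binding regions on protein
surfaces. The pipeline voxelises a PDB structure into a van der Waals
occupancy grid, computes a solid angle for every surface voxel by virtual
sphere voxel counting, clusters the most concave voxels into candidate
pockets, scores each candidate by a cavity depth indicator (a stepwise
transform of solid angles) and a cavity volume indicator (a 7-direction ray
scan of nearby empty voxels), and ranks regions by a weighted combination of
both. An evaluation module scores predictions against annotated binding
residues (sensitivity, specificity, accuracy, PPV, MCC, top-k success), and
a synthetic-shape generator provides analytic solids (as occupancy grids and
pseudo-atom PDB files with ground-truth tables) so the whole pipeline is
testable without downloading anything.

## Layout

| module | role |
| --- | --- |
| `voxpocket.structure_io` | PDB parsing (model 1, first altloc), van der Waals radius assignment, PDB writing |
| `voxpocket.voxelization` | occupancy grid construction and exterior/interior/surface labelling |
| `voxpocket.solid_angle` | per-surface-voxel solid angles, `SA = 4π·V_in/V_sphere` |
| `voxpocket.pocket_clustering` | top-fraction candidate selection, single-linkage clustering, anchors |
| `voxpocket.cavity_features` | depth bins {5..1, −1}, cluster average depth, 7-direction cavity volume |
| `voxpocket.ranking` | `rv = (CD_avg/CD_max)·w1 + (CV/CV_max)·w2`, ordered predictions |
| `voxpocket.evaluation` | confusion metrics and region/residue matching against truth tables |
| `voxpocket.synthetic_shapes` | analytic solids, pseudo-atom fixtures, pocket truth tables |
| `voxpocket.cli` | `predict`, `evaluate`, `fixtures`, `summarize` subcommands |

## CLI

```sh
# generate a synthetic pocket fixture (PDB + truth table + expected JSON)
voxpocket fixtures sphere_with_cap_pocket -o fixtures/ --atom-pitch 1.0

# run the pipeline
voxpocket predict fixtures/sphere_with_cap_pocket.pdb -o out/ \
    --fraction 0.10 --sa-band 0.628

# score against the truth table (or derive truth from HETATM ligands
# with --ligand-truth)
voxpocket evaluate out/predictions.json \
    --pdb fixtures/sphere_with_cap_pocket.pdb \
    --truth fixtures/sphere_with_cap_pocket.truth.tsv -k 1 -o report.json

# aggregate several per-protein reports
voxpocket summarize report.json -o summary.json
```

`predict` writes `predictions.tsv`, `predictions.json` (including member
voxel centers, used by `evaluate`) and a reproducibility manifest. Defaults:
1 Å grid spacing, 6 Å solid-angle sphere, top 20% candidates, 20 Å cluster
linkage, 10 Å volume probe, ≥4 of 7 interior directions, equal weights
w1 = w2 = 0.5; all configurable via flags.

## Library example

```python
from voxpocket import (RunConfig, parse_pdb, run_pipeline)

structure = parse_pdb("protein.pdb", chains={"A"})
result = run_pipeline(structure, RunConfig())
for region in result.regions[:3]:
    print(region.rank, region.rv, region.cluster.anchor)
```
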