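# abensemble

Clustered antibody model ensembles for docking.

Structure predictors handle the antibody variable domain well except for the
third heavy-chain hypervariable loop (CDR-H3), which is long, lacks
co-evolutionary signal, and is frequently mispredicted. When the predictor's
own confidence for the loop (mean H3 pLDDT) drops below ~80, a single model
cannot be trusted — but a *generative* ensemble of heavy-chain models can
cover the true conformation, provided its hundreds of members are reduced to
a small, structurally diverse set that a docking engine can actually use.

`abensemble` implements that reduction and the surrounding bookkeeping:

- **Loop geometry** — framework-aligned CDR loop backbone RMSD: structures
  are superposed by least squares (Kabsch) over the conserved framework
  backbone, and the RMSD is evaluated over the loop backbone atoms
  ({N, CA, C, O} by default) with no second fit on the loop.
- **Ensemble reduction** — agglomerative clustering of an ensemble on the
  pairwise H3 loop RMSD matrix (single/average/complete linkage; complete by
  default), keeping the medoid of each cluster. The operating point is
  N = 100 models → K = 20 centers; a 25 → 5 preset (`af2-baseline`) covers
  the conventional 5-seed AlphaFold2 treatment.
- **Assembly + clash filter** — merge each heavy-chain center with a light
  chain model and discard models with more than one backbone clash, where a
  clash is an inter-chain backbone atom pair closer than 63 % of the sum of
  the atoms' van der Waals radii.
- **pLDDT triage** — partition models into *confident* (loop mean
  pLDDT ≥ 80) and *difficult* (< 80), plus the pLDDT–accuracy Pearson
  correlation diagnostic.
- **CAPRI evaluation** — fnat, ligand RMSD (L-RMSD), interface RMSD
  (i-RMSD), the high/medium/acceptable/incorrect quality classes, and top-N
  success rates for ranked docking runs.
- **Synthetic fixtures** — deterministic toy antibody-like backbones with
  planted cluster structure, planted clashes, and planted interfaces, so the
  whole pipeline is testable without external data.

Structures are exchanged as (multi-model) PDB files with per-residue pLDDT
in the B-factor column, the format convention of AlphaFold-family predictors
and of docking engines such as HADDOCK.

## Worked example

Generate a toy ensemble with three planted loop conformations, reduce it to
three cluster centers, and triage it:

```bash
abensemble make-fixtures --seed 5 --conformations 3 \
    --members-per-conformation 8 --outdir demo
abensemble reduce demo/ensemble.pdb --regions demo/regions.yaml \
    --k 3 -o demo/reduced.pdb
abensemble triage demo/ensemble.pdb --regions demo/regions.yaml | head -4
```

The triage table starts:

```
model	loop_mean_plddt	class
ensemble_1	70.0	difficult
ensemble_2	70.0	difficult
ensemble_3	70.0	difficult
```

Every member is *difficult* because the fixture writes a loop pLDDT of 70
(below the 80 threshold) — exactly the regime in which ensemble reduction is
worth running. `demo/reduced.pdb` holds 3 models, one medoid per planted
conformation.

The same reduction from Python, at the standard operating point:

```python
from abensemble import read_ensemble, reduce_ensemble, RegionDefinition

ensemble = read_ensemble("heavy_ensemble.pdb")      # e.g. 100 members
regions = RegionDefinition.from_yaml("regions.yaml")
reduced = reduce_ensemble(ensemble, regions, loop="H3", k=20, linkage="complete")
len(reduced)   # -> 20
```

Scoring a docking pose against its reference complex:

```bash
abensemble capri-eval pose.pdb reference.pdb \
    --receptor-chains H,L --ligand-chains A
```

prints one row per pose with `fnat`, `lrmsd`, `irmsd` and the CAPRI class.

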