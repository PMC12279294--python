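# Methods

## The problem

Antibodies bind antigen through six hypervariable loops (CDRs H1–H3,
L1–L3). Five of them fall into a small number of canonical conformational
classes; CDR-H3 does not. It is assembled from three gene loci, is the
longest and most variable loop, and most H3 conformations have no close
structural neighbour outside the antibody world. Single-model predictors
consequently fail on H3 far more often than on any other part of the
variable domain, and their per-residue confidence (pLDDT, stored in the
PDB B-factor column) is the best available signal for when they have
failed. When the H3-loop mean pLDDT is low, a generative ensemble of
heavy-chain models can sample the correct conformation among many wrong
ones — but a docking engine cannot afford hundreds of starting conformers,
so the ensemble must be reduced to a small set that preserves its
conformational diversity. `abensemble` implements that reduction and the
evaluation machinery around it.

## Framework-aligned loop RMSD

All loop comparisons use one distance: superpose the two structures by
least squares over the backbone atoms of the *framework* region (the
conserved scaffold outside the CDR loops), then compute the RMSD over the
loop backbone atoms in that frame, with **no second fit on the loop**.
This decouples loop placement from global domain placement: a model with a
perfect scaffold and a displaced loop scores exactly the displacement.

- Superposition is the Kabsch algorithm (proper rotations only; handled by
  `scipy.spatial.transform.Rotation.align_vectors`). Collinear point sets
  produce a best-effort fit plus a `DegeneracyWarning`; fewer than three
  points is an error.
- The backbone atom set defaults to {N, CA, C, O}; {N, CA, C} is supported
  for users who follow the three-atom convention. The choice changes
  absolute values slightly but not orderings; the four-atom set is the
  default because it is the common convention in antibody loop
  benchmarking.
- Residues are paired by author numbering `(seq_id, insertion_code)` on a
  named chain, and ensembles are required to share residue identities
  exactly. A residue or backbone atom missing from a required region is a
  hard error, never a silent skip — skipping atoms silently changes the
  metric.
- Framework and loop ranges come from a YAML region config (no automatic
  CDR annotation or renumbering is performed; any numbering scheme works as
  long as the config matches the files).

## Ensemble reduction by agglomerative clustering

The reduction clusters the all-vs-all loop-RMSD matrix bottom-up from
singletons: at each step, merge the pair of clusters with the smallest
inter-cluster distance under the chosen linkage (single = minimum pairwise
member distance, complete = maximum, average = unweighted mean), stopping
at K clusters. Complete linkage is the default: it produces compact,
diameter-bounded clusters, and single linkage demonstrably chains planted
conformations together (the planted-partition tests permit single linkage
to fail).

Numerical/determinism choices, all exercised by tests:

- Merge ties (two candidate pairs at exactly equal distance) resolve to the
  smallest pair of minimum member indices; clusters are kept ordered by
  minimum member index so the scan order realizes that rule. Identical
  inputs therefore always give identical partitions.
- The cluster *center* is the medoid by sum of distances — the member
  minimizing the summed RMSD to its co-members, well-defined from the
  distance matrix alone; ties go to the member earliest in ensemble order.
  (Medoid-by-maximum or a constructed average structure are defensible
  alternatives; medoid-by-sum is the common choice and is what is
  implemented.)
- Output cluster indices are ordered by descending size, ties by smallest
  member index, so reduced ensembles are stable across runs.
- The implementation is authored in-package (a vectorized
  Lance-Williams-style update) because the tie-break and center rules must
  be exact; `scipy.cluster.hierarchy` is used only as an independent
  cross-check in the test suite, alongside a from-scratch O(N³) reference.

Operating point: keep the first 100 ensemble members (ensemble order, i.e.
generation order) and reduce to K = 20 — a factor-of-5 reduction that keeps
the best loop conformation in the retained set at minimal cost. The
`af2-baseline` preset applies the same operation at n = 25, K = 5, the
conventional treatment of a five-seed AlphaFold2 run. A sweep utility
reports best-center loop RMSD against a reference over an (n, K, linkage)
grid, together with the pre-clustering minimum ("ALL" column); on any fixed
ensemble the best-center RMSD is monotonically non-increasing in K and can
never beat the ensemble minimum.

## Assembly and the clash filter

Generated heavy chains are merged with a separately predicted light chain
(chains relabelled H and L; coordinates untouched; no orientation
optimization). Because the loop was sampled with no knowledge of the light
chain, some conformations collide with it. The filter is a hard-sphere
criterion: two backbone heavy atoms clash when their distance is
**strictly lower** than 0.63 × (r_a + r_b), with r the element van der
Waals radius; models with **more than one** such inter-chain clash are
removed. Defaults and conventions:

- Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å — a standard van der Waals set,
  fully overridable from YAML.
- Backbone atoms only by default ("backbone clash" is the phenomenon of
  interest — a diffused loop running through the partner chain); all-atom
  checking is available behind a flag.
- Pairs within one residue, or between sequence-adjacent residues of the
  same chain, are excluded so covalent geometry is never counted. The
  inter-chain use case is unaffected by this exclusion.
- The production scan uses a k-d tree pruned at the largest possible
  threshold (2 × max radius × fraction), which is exact with respect to
  the all-pairs definition; tests compare it against a loop-based O(n²)
  oracle on every fixture.
- An ensemble whose members are all removed yields an empty ensemble plus
  a warning (the pipeline turns that into a non-zero exit); it is not an
  exception at the library level.

Energy minimization of the assembled models is intentionally out of scope;
it belongs to the downstream docking suite, and the run manifest records
`"minimization": "external"` so the gap is explicit.

## pLDDT triage

Per-residue pLDDT is read from the B-factor of the CA atom (mean over
atoms when CA is absent); the loop value is the unweighted mean over loop
residues. Models with loop mean pLDDT **strictly below** 80 are
*difficult* — the regime where generative ensembles pay off — and models
at or above 80 are *confident*; the boundary value 80.0 itself is
confident, mirroring the strict "below" in the definition of the difficult
class. The complementary split by realized accuracy calls a target *right*
when its best loop RMSD is strictly below 3.0 Å and *wrong* otherwise
(3.0 Å exactly is wrong). The pLDDT–RMSD Pearson correlation (negative for
a well-calibrated predictor) is provided as a diagnostic; it refuses
fewer than three points or zero variance.

## CAPRI evaluation

Docking poses are scored against the reference complex with the three
community-standard metrics: fnat (fraction of reference interface
residue–residue contacts reproduced; contact = any heavy-atom pair across
the receptor/ligand partition within 5 Å), L-RMSD (ligand backbone RMSD
after superposing on the receptor backbone), and i-RMSD (backbone RMSD
over reference-defined interface residues — any heavy atom within 10 Å of
the partner — after fitting on those same atoms). Both cutoffs are the
CAPRI community convention and are exposed as flags. Quality classes are
evaluated in order: high (fnat ≥ 0.5 and L-RMSD ≤ 1 or i-RMSD ≤ 1),
medium (fnat ≥ 0.3 and L-RMSD ≤ 5 or i-RMSD ≤ 2), acceptable (fnat ≥ 0.1
and L-RMSD ≤ 10 or i-RMSD ≤ 4), else incorrect.

Some published restatements of these criteria carry a separate "incorrect"
clause (fnat < 0.1, or L-RMSD > 10 *and* i-RMSD > 2) whose i-RMSD bound
contradicts the acceptable rule above. The default here defines incorrect
simply as "fails the acceptable rule", which is self-consistent;
`strict_printed_incorrect=True` applies the conflicting clause verbatim
for comparison, and the tests pin down the region where the two disagree.
The top-N success rate of ranked runs counts targets whose best class in
the first N models meets a minimum class; it is non-decreasing in N and
non-increasing in the quality bar.

## Synthetic fixtures

The generators produce idealized poly-alanine backbones — N, CA, C, O per
residue with near-ideal bond lengths and 3.8 Å CA–CA spacing — laid out
along x with a central loop (named H3) flanked by framework residues.
Alternative conformations displace the loop block rigidly along z by a
configurable shift; member-to-member variation is iid Gaussian noise on
loop atoms only, so the framework is bit-identical across members and the
framework fit is exact. Default generator conditions: 20 framework + 8
loop residues, 6 Å conformation spacing, 0.15 Å atom noise, framework
pLDDT 95 / loop 70. Planted-ensemble tests use a shift-to-noise ratio of
10, representing the easy-separation regime in which a clustering method
has no excuse to fail.

What these fixtures emulate is exactly — and only — the geometry the
pipeline consumes: every quantity under test (framework-aligned RMSD,
cluster structure, clash counts, interface contacts) depends on backbone
coordinates alone. They are not folded antibodies: there is no side-chain
packing, no realistic Ramachandran statistics, no correlation structure in
the noise, and the generative ensemble they stand in for has none of the
mode structure of a real flow-matching sampler beyond the planted
conformations. Passing tests therefore certify the correctness and
determinism of the algorithms, not prediction accuracy on real antibodies.

Each generator is a pure function of its spec and seed (repeat calls are
byte-identical), and generators that plant a countable property (clashes,
contacts) re-verify it by brute force before returning — a fixture that
fails self-verification raises instead of silently feeding tests. The
clash generator positions one partner atom per requested clash 1.8 Å above
an early-framework CA, below that pair's threshold while every other
inter-chain pair clears its own threshold by at least 0.2 Å.

## Pipeline

`run_prepare` composes the stages — truncate to the first n models,
cluster to K centers, merge with the light chain, clash-filter — and
writes the multi-model PDB, per-member cluster and clash TSVs, and a JSON
manifest (config snapshot, input SHA-256 hashes, per-stage counts, tool
version, timestamp). Stage counts are monotone non-increasing by
construction and validated. Clustering and geometry are deterministic by
construction; seeds exist only in the fixture generators, so two runs on
identical inputs produce byte-identical ensembles and manifests equal up
to timestamps.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run entirely on generated
fixtures, sized so the whole suite completes in well under a minute of
CPU: clustering oracle comparisons use matrices up to N = 12 (where an
O(N³) from-scratch reference is itself trustworthy), planted-partition
recovery uses 20–50-member ensembles, and the end-to-end runs use the
full 100 → 20 operating point. The acceptance script recomputes every
reported quantity at run time from its `--seed`; nothing is cached or
hard-coded.

## Known limitations

- PDB is the only fully supported interchange format (mmCIF parses through
  the same reader but the writer emits PDB).
- No sequence-based CDR detection, antibody numbering, structure repair,
  or protonation; region definitions are the user's responsibility.
- The reduction assumes ensembles share residue identities exactly;
  heterogeneous-length ensembles (e.g. mixed loop lengths) are rejected
  rather than aligned.
- `plddt_rmsd_correlation` is a diagnostic, not a calibrated predictor;
  discriminating recoverable from unrecoverable low-confidence loops
  better than raw pLDDT is out of scope.
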