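"""Deterministic toy antibody-like structures for tests and demos.

Every generator here is a pure function of its spec and seed.  The chains
are idealized poly-alanine backbones (N, CA, C, O with realistic bond
geometry and ~3.8 angstrom CA-CA spacing) laid out along x, with a central
"H3" loop flanked by framework residues.  Alternative loop conformations
are produced by displacing the loop block rigidly along z; Gaussian noise
of configurable width is added to loop atoms only, so the framework is
bit-identical across members and framework superposition is exact.

These fixtures are *not* folded antibodies.  Every property the pipeline
measures — framework-aligned loop RMSD, cluster structure, steric clashes,
interface contacts — depends only on backbone geometry, so an analytically
controlled backbone is the right substrate: planted quantities (cluster
labels, clash counts, contact sets) are known exactly and each generator
re-verifies them by brute force before returning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import DEFAULT_RADII, RadiiTable, merge_chains
from .capri import ContactSet
from .errors import PlacementError, ValidationError
from .geometry import RegionDefinition, ResidueRange
from .structure import Atom, Chain, Ensemble, Residue, Structure

__all__ = [
    "FixtureSpec",
    "PlantedEnsemble",
    "ToyComplex",
    "make_toy_chain",
    "make_planted_ensemble",
    "plant_clashes",
    "make_toy_complex",
]

# in-plane offsets (x, y) from CA giving near-ideal bond lengths:
# N-CA 1.44, CA-C 1.50, C=O 1.22, peptide C(i)-N(i+1) 1.30 angstrom
_OFFSETS = {"N": (-1.20, 0.80), "CA": (0.0, 0.0), "C": (1.30, 0.75), "O": (1.50, 1.95)}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}
_CA_SPACING = 3.8


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-ensemble generator.

    ``n_conformations`` (G) distinct loop conformations are planted,
    ``inter_conformation_shift`` angstrom apart along z, each sampled
    ``members_per_conformation[i]`` times with loop-atom Gaussian noise of
    sd ``intra_noise_sigma``.  ``plddt_profile`` optionally fixes the
    per-residue B-factor template (defaults: framework 95, loop 70).
    """

    seed: int = 0
    framework_len: int = 20
    loop_len: int = 8
    n_conformations: int = 1
    members_per_conformation: tuple[int, ...] = (10,)
    intra_noise_sigma: float = 0.15
    inter_conformation_shift: float = 6.0
    plddt_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.framework_len < 4 or self.loop_len < 1:
            raise ValidationError("framework_len >= 4 and loop_len >= 1 required")
        if self.n_conformations < 1 or len(self.members_per_conformation) != self.n_conformations:
            raise ValidationError("members_per_conformation must list one count per conformation")
        if any(m < 1 for m in self.members_per_conformation):
            raise ValidationError("all member counts must be positive")
        if self.intra_noise_sigma < 0:
            raise ValidationError("intra_noise_sigma must be >= 0")
        if self.n_conformations > 1 and self.inter_conformation_shift <= 0:
            raise ValidationError("inter_conformation_shift must be > 0 when G > 1")
        n_res = self.framework_len + self.loop_len
        if self.plddt_profile is not None and len(self.plddt_profile) != n_res:
            raise ValidationError(f"plddt_profile must have {n_res} entries")

    @property
    def n_residues(self) -> int:
        return self.framework_len + self.loop_len


def _default_profile(spec: FixtureSpec) -> np.ndarray:
    fw1 = spec.framework_len // 2
    prof = np.full(spec.n_residues, 95.0)
    prof[fw1 : fw1 + spec.loop_len] = 70.0
    return prof


def _regions(spec: FixtureSpec, chain_id: str) -> RegionDefinition:
    fw1 = spec.framework_len // 2
    loop_start, loop_end = fw1 + 1, fw1 + spec.loop_len
    return RegionDefinition(
        chain_id=chain_id,
        framework=(
            ResidueRange((1, ""), (fw1, "")),
            ResidueRange((loop_end + 1, ""), (spec.n_residues, "")),
        ),
        loops={"H3": ResidueRange((loop_start, ""), (loop_end, ""))},
    )


def _backbone_residue(chain_id: str, seq_id: int, origin: np.ndarray, bfactor: float) -> Residue:
    atoms = [
        Atom(
            name=name,
            element=_ELEMENTS[name],
            coord=origin + np.array([dx, dy, 0.0]),
            bfactor=bfactor,
        )
        for name, (dx, dy) in _OFFSETS.items()
    ]
    # canonical N, CA, C, O order
    atoms.sort(key=lambda a: ("N", "CA", "C", "O").index(a.name))
    return Residue(chain_id=chain_id, seq_id=seq_id, insertion_code="", res_name="ALA", atoms=atoms)


def make_toy_chain(
    spec: FixtureSpec,
    conformation_id: int = 0,
    member_index: int = 0,
    chain_id: str = "H",
    model_id: str | None = None,
) -> tuple[Structure, RegionDefinition]:
    """One poly-alanine chain with its loop in the requested planted conformation.

    The loop block (marked H3 in the returned region definition) sits
    ``conformation_id * inter_conformation_shift`` angstrom along z, plus
    per-atom Gaussian noise of sd ``intra_noise_sigma`` drawn from a stream
    keyed on ``(seed, conformation_id, member_index)`` — repeat calls are
    byte-identical.
    """
    if not 0 <= conformation_id < spec.n_conformations:
        raise ValidationError(
            f"conformation_id {conformation_id} out of range [0, {spec.n_conformations})"
        )
    rng = np.random.default_rng([spec.seed, conformation_id, member_index])
    profile = (
        np.asarray(spec.plddt_profile, float)
        if spec.plddt_profile is not None
        else _default_profile(spec)
    )
    regions = _regions(spec, chain_id)
    fw1 = spec.framework_len // 2
    residues = []
    for i in range(spec.n_residues):
        seq_id = i + 1
        origin = np.array([_CA_SPACING * i, 0.0, 0.0])
        res = _backbone_residue(chain_id, seq_id, origin, float(profile[i]))
        if fw1 <= i < fw1 + spec.loop_len:  # loop residue
            shift = np.array([0.0, 0.0, conformation_id * spec.inter_conformation_shift])
            for a in res.atoms:
                a.coord = a.coord + shift + rng.normal(0.0, spec.intra_noise_sigma, size=3)
        residues.append(res)
    label = model_id or f"conf{conformation_id}_m{member_index}"
    structure = Structure(model_id=label, chains=[Chain(id=chain_id, residues=residues)])
    return structure, regions


class PlantedEnsemble(NamedTuple):
    ensemble: Ensemble
    truth: list[int]  #: planted conformation id per member, in ensemble order
    regions: RegionDefinition


def make_planted_ensemble(spec: FixtureSpec) -> PlantedEnsemble:
    """Shuffled ensemble with known cluster structure.

    ``members_per_conformation[g]`` members are drawn around each planted
    conformation ``g``; member order is then shuffled by the spec seed and
    the ground-truth conformation ids are returned alongside.
    """
    members: list[Structure] = []
    truth: list[int] = []
    regions = None
    for g, count in enumerate(spec.members_per_conformation):
        for m in range(count):
            st, regions = make_toy_chain(spec, conformation_id=g, member_index=m)
            members.append(st)
            truth.append(g)
    order = np.random.default_rng([spec.seed, 0xE5]).permutation(len(members))
    return PlantedEnsemble(
        ensemble=Ensemble(
            members=[members[i] for i in order], labels=[members[i].model_id for i in order]
        ),
        truth=[truth[i] for i in order],
        regions=regions,
    )


def _brute_force_interchain_clashes(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    radii: RadiiTable,
    fraction: float,
) -> list[tuple[float, float]]:
    """(distance, threshold) for every violating backbone pair; pure O(n^2) loops."""
    out = []
    for ra in structure.chain(chain_a).residues:
        for aa in ra.backbone():
            for rb in structure.chain(chain_b).residues:
                for ab in rb.backbone():
                    d = float(np.linalg.norm(aa.coord - ab.coord))
                    thr = fraction * (radii.radius(aa.element) + radii.radius(ab.element))
                    if d < thr:
                        out.append((d, thr))
    return out


def plant_clashes(
    structure: Structure,
    partner: Structure,
    n_clashes: int,
    radii: RadiiTable = DEFAULT_RADII,
    fraction: float = 0.63,
    seed: int = 0,
) -> Structure:
    """Merge ``structure`` (chain H) and ``partner`` (chain L) with exactly
    ``n_clashes`` planted inter-chain backbone clashes.

    The partner is parked far from the structure, then one partner N atom
    per requested clash is repositioned 1.8 angstrom above an early-framework
    CA of the structure: below the 0.63-fraction threshold for that pair,
    while every other inter-chain pair clears its threshold by >= 0.2
    angstrom.  The construction is re-verified by an all-pairs brute force
    before returning.  (The partner's internal geometry is sacrificed; only
    inter-chain distances matter to the clash filter.)
    """
    if n_clashes < 0:
        raise ValidationError("n_clashes must be >= 0")
    merged = merge_chains(structure, partner, heavy_id="H", light_id="L")
    heavy, light = merged.chain("H"), merged.chain("L")
    if len(light.residues) < n_clashes or len(heavy.residues) < 2 * n_clashes:
        raise PlacementError(
            f"need >= {n_clashes} partner residues and >= {2 * n_clashes} structure residues"
        )
    # park the light chain far away (+y), keeping determinism trivially
    for res in light.residues:
        for a in res.atoms:
            a.coord = a.coord + np.array([0.0, 80.0, 0.0])
    for j in range(n_clashes):
        target_ca = heavy.residues[2 * j].atom("CA")
        planted = light.residues[j].atom("N")
        planted.coord = target_ca.coord + np.array([0.0, 0.0, 1.8])
    violations = _brute_force_interchain_clashes(merged, "H", "L", radii, fraction)
    if len(violations) != n_clashes:
        raise PlacementError(
            f"planted {n_clashes} clashes but brute force finds {len(violations)}"
        )
    # margin check: every non-violating pair must clear its threshold by 0.2 A
    margin_violations = _count_within_margin(merged, radii, fraction, margin=0.2) - len(violations)
    if margin_violations:
        raise PlacementError(f"{margin_violations} non-clash pairs within the 0.2 A margin")
    return merged


def _count_within_margin(
    structure: Structure, radii: RadiiTable, fraction: float, margin: float
) -> int:
    count = 0
    for ra in structure.chain("H").residues:
        for aa in ra.backbone():
            for rb in structure.chain("L").residues:
                for ab in rb.backbone():
                    d = float(np.linalg.norm(aa.coord - ab.coord))
                    thr = fraction * (radii.radius(aa.element) + radii.radius(ab.element))
                    if d < thr + margin:
                        count += 1
    return count


class ToyComplex(NamedTuple):
    reference: Structure
    model: Structure
    expected_contacts: ContactSet


def make_toy_complex(
    seed: int = 0,
    interface_size: int = 6,
    perturbation: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ToyComplex:
    """Two-chain toy complex with a constructed interface and a perturbed pose.

    The receptor (chain A) is a toy backbone along x; the ligand (chain B,
    ``interface_size`` residues) runs parallel 4.2 angstrom above it, so the
    interface contacts are dense and enumerable.  ``perturbation`` is a pair
    ``(rotvec, translation)`` applied rigidly to the ligand about its
    centroid to build the model pose.  Expected reference contacts are
    enumerated by an all-pairs brute force and returned.
    """
    if interface_size < 1:
        raise ValidationError("interface_size must be >= 1")
    rec_len = max(12, interface_size + 4)
    spec = FixtureSpec(seed=seed, framework_len=rec_len, loop_len=1, intra_noise_sigma=0.0,
                       members_per_conformation=(1,))
    receptor, _ = make_toy_chain(spec, chain_id="A", model_id="receptor")
    lig_res = []
    x0 = _CA_SPACING * 2  # start the ligand over receptor residue 3
    for i in range(interface_size):
        origin = np.array([x0 + _CA_SPACING * i, 0.0, 4.2])
        lig_res.append(_backbone_residue("B", i + 1, origin, 90.0))
    reference = Structure(
        model_id="reference",
        chains=[receptor.chains[0], Chain(id="B", residues=lig_res)],
    )
    model = reference.copy()
    model.model_id = "pose"
    if perturbation is not None:
        rotvec, translation = perturbation
        R = Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix()
        lig = model.chain("B")
        coords = np.array([a.coord for r in lig.residues for a in r.atoms])
        centroid = coords.mean(axis=0)
        for res in lig.residues:
            for a in res.atoms:
                a.coord = R @ (a.coord - centroid) + centroid + np.asarray(translation, float)
    # brute-force enumeration of expected reference contacts (all heavy atoms)
    expected: set = set()
    for res_a in reference.chain("A").residues:
        for res_b in reference.chain("B").residues:
            close = any(
                np.linalg.norm(aa.coord - ab.coord) <= 5.0
                for aa in res_a.atoms
                for ab in res_b.atoms
            )
            if close:
                expected.add((res_a.key, res_b.key))
    return ToyComplex(reference=reference, model=model, expected_contacts=frozenset(expected))
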