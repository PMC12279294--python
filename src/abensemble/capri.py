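"""CAPRI-standard evaluation of docking models.

A docking pose is compared to the reference complex with the three community
metrics:

``fnat``
    fraction of the reference's interface residue-residue contacts (any
    heavy-atom pair across the receptor/ligand partition within 5 angstrom)
    reproduced by the model;
``L-RMSD``
    backbone RMSD of the ligand after superposing on the receptor backbone;
``i-RMSD``
    backbone RMSD over the reference-defined interface residues (any heavy
    atom within 10 angstrom of the partner) after superposing on those same
    atoms.

The quality classes are evaluated in order:

* high:       fnat >= 0.5 and (L-RMSD <= 1 or i-RMSD <= 1)
* medium:     fnat >= 0.3 and (L-RMSD <= 5 or i-RMSD <= 2)
* acceptable: fnat >= 0.1 and (L-RMSD <= 10 or i-RMSD <= 4)
* incorrect:  otherwise.

By default "incorrect" is simply the complement of "acceptable", which is
self-consistent with the thresholds above.  Some published restatements of
the criteria give a separate incorrect clause (``fnat < 0.1 or (L-RMSD > 10
and i-RMSD > 2)``) whose i-RMSD bound disagrees with the acceptable rule;
``strict_printed_incorrect=True`` applies that clause verbatim for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError, ValidationError
from .geometry import backbone_coords, kabsch_superpose, rmsd
from .structure import BACKBONE_ATOMS, Structure

__all__ = [
    "ContactSet",
    "CapriScores",
    "QUALITY_ORDER",
    "native_contacts",
    "fnat",
    "ligand_rmsd",
    "interface_rmsd",
    "classify_quality",
    "evaluate_pose",
    "success_rate",
]

QUALITY_ORDER: dict[str, int] = {"incorrect": 0, "acceptable": 1, "medium": 2, "high": 3}

ResKey = tuple[str, int, str]
#: Unordered-within-partition residue contact: (receptor residue, ligand residue).
ContactSet = frozenset[tuple[ResKey, ResKey]]


@dataclass
class CapriScores:
    fnat: float
    lrmsd: float
    irmsd: float
    quality: str

    def __post_init__(self) -> None:
        if self.quality != classify_quality(self.fnat, self.lrmsd, self.irmsd):
            raise ValidationError("quality class inconsistent with scores")


def _group_atoms(structure: Structure, chain_ids: Sequence[str]):
    keys, coords = [], []
    for cid in chain_ids:
        for res in structure.chain(cid).residues:
            for a in res.atoms:
                keys.append(res.key)
                coords.append(a.coord)
    return keys, np.asarray(coords, float)


def _check_partition(receptor_chains: Sequence[str], ligand_chains: Sequence[str]) -> None:
    if not receptor_chains or not ligand_chains:
        raise ValidationError("receptor and ligand chain groups must be non-empty")
    if set(receptor_chains) & set(ligand_chains):
        raise ValidationError("receptor and ligand chain groups must be disjoint")


def native_contacts(
    complex_structure: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    cutoff: float = 5.0,
) -> ContactSet:
    """Residue contacts across the receptor/ligand partition.

    A (receptor residue, ligand residue) pair is a contact when any
    heavy-atom pair across the partition lies within ``cutoff`` angstrom.
    """
    _check_partition(receptor_chains, ligand_chains)
    rkeys, rcoords = _group_atoms(complex_structure, receptor_chains)
    lkeys, lcoords = _group_atoms(complex_structure, ligand_chains)
    pairs: set[tuple[ResKey, ResKey]] = set()
    if len(rcoords) and len(lcoords):
        rtree = cKDTree(rcoords)
        for li, neighbours in enumerate(rtree.query_ball_point(lcoords, r=cutoff)):
            for ri in neighbours:
                pairs.add((rkeys[ri], lkeys[li]))
    return frozenset(pairs)


def fnat(
    model: Structure,
    reference: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    cutoff: float = 5.0,
) -> float:
    """Fraction of the reference's contacts present in the model."""
    ref_contacts = native_contacts(reference, receptor_chains, ligand_chains, cutoff)
    if not ref_contacts:
        raise UndefinedMetricError("reference complex has no contacts; fnat undefined")
    model_contacts = native_contacts(model, receptor_chains, ligand_chains, cutoff)
    return len(ref_contacts & model_contacts) / len(ref_contacts)


def _chain_backbone(structure: Structure, chain_ids: Sequence[str], atom_set=BACKBONE_ATOMS):
    coords = []
    for cid in chain_ids:
        keys = [(r.seq_id, r.insertion_code) for r in structure.chain(cid).residues]
        coords.append(backbone_coords(structure, cid, keys, atom_set))
    return np.vstack(coords)


def ligand_rmsd(
    model: Structure,
    reference: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
) -> float:
    """Backbone RMSD of the ligand after superposing on the receptor backbone."""
    _check_partition(receptor_chains, ligand_chains)

    def collect(st: Structure, chains):
        coords = []
        for cid in chains:
            keys = [(r.seq_id, r.insertion_code) for r in reference.chain(cid).residues]
            coords.append(backbone_coords(st, cid, keys))
        return np.vstack(coords)

    fit = kabsch_superpose(collect(model, receptor_chains), collect(reference, receptor_chains))
    return rmsd(fit.apply(collect(model, ligand_chains)), collect(reference, ligand_chains))


def interface_residues(
    reference: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    interface_cutoff: float = 10.0,
) -> list[ResKey]:
    """Reference residues with any heavy atom within the cutoff of the partner."""
    contacts = native_contacts(reference, receptor_chains, ligand_chains, interface_cutoff)
    residues = {r for r, _ in contacts} | {l for _, l in contacts}
    order = {res.key: i for i, res in enumerate(reference.residues())}
    return sorted(residues, key=order.__getitem__)


def interface_rmsd(
    model: Structure,
    reference: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    interface_cutoff: float = 10.0,
) -> float:
    """Backbone RMSD over reference-defined interface residues after fitting on them."""
    _check_partition(receptor_chains, ligand_chains)
    residues = interface_residues(reference, receptor_chains, ligand_chains, interface_cutoff)
    if not residues:
        raise UndefinedMetricError("no interface residues within cutoff; i-RMSD undefined")
    by_chain: dict[str, list[tuple[int, str]]] = {}
    for cid, seq, icode in residues:
        by_chain.setdefault(cid, []).append((seq, icode))

    def collect(st: Structure):
        return np.vstack([backbone_coords(st, cid, keys) for cid, keys in by_chain.items()])

    fit = kabsch_superpose(collect(model), collect(reference))
    return fit.fit_rmsd


def classify_quality(
    fnat_value: float,
    lrmsd_value: float,
    irmsd_value: float,
    strict_printed_incorrect: bool = False,
) -> str:
    """CAPRI quality class from (fnat, L-RMSD, i-RMSD); rules evaluated high-first."""
    for v in (fnat_value, lrmsd_value, irmsd_value):
        if not np.isfinite(v):
            raise ValidationError(f"scores must be finite, got {v}")
    if strict_printed_incorrect and (
        fnat_value < 0.1 or (lrmsd_value > 10.0 and irmsd_value > 2.0)
    ):
        return "incorrect"
    if fnat_value >= 0.5 and (lrmsd_value <= 1.0 or irmsd_value <= 1.0):
        return "high"
    if fnat_value >= 0.3 and (lrmsd_value <= 5.0 or irmsd_value <= 2.0):
        return "medium"
    if fnat_value >= 0.1 and (lrmsd_value <= 10.0 or irmsd_value <= 4.0):
        return "acceptable"
    return "incorrect"


def evaluate_pose(
    model: Structure,
    reference: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    contact_cutoff: float = 5.0,
    interface_cutoff: float = 10.0,
) -> CapriScores:
    """All three CAPRI metrics plus the quality class for one docking pose."""
    f = fnat(model, reference, receptor_chains, ligand_chains, contact_cutoff)
    l = ligand_rmsd(model, reference, receptor_chains, ligand_chains)
    i = interface_rmsd(model, reference, receptor_chains, ligand_chains, interface_cutoff)
    return CapriScores(fnat=f, lrmsd=l, irmsd=i, quality=classify_quality(f, l, i))


def success_rate(
    ranked_runs: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    top_n: int = 1,
    min_quality: str = "acceptable",
) -> float:
    """Fraction of targets with a model of at least ``min_quality`` in the top N.

    ``ranked_runs`` maps each target to its quality classes in rank order;
    a ``top_n`` beyond a run's length uses the full run.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if min_quality not in QUALITY_ORDER:
        raise ValueError(f"unknown quality class {min_quality!r}")
    runs = list(ranked_runs.values()) if isinstance(ranked_runs, Mapping) else list(ranked_runs)
    if not runs:
        raise ValidationError("no runs supplied")
    need = QUALITY_ORDER[min_quality]
    hits = 0
    for run in runs:
        head = list(run)[:top_n]
        if head and max(QUALITY_ORDER[q] for q in head) >= need:
            hits += 1
    return hits / len(runs)
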