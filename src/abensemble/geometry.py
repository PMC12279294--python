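"""Framework superposition and loop backbone RMSD.

The accuracy metric used throughout the package is the *framework-aligned
loop RMSD*: the two structures are superposed by least squares over the
backbone atoms of the conserved framework region, and the RMSD is then
evaluated over the backbone atoms of one CDR loop **without refitting on the
loop**.  This separates "where is the loop" from "where is the domain", which
is what makes the value usable both as an accuracy measure against a crystal
reference and as a clustering distance within a generative ensemble.

Superpositions use the Kabsch algorithm (proper rotations only) via
``scipy.spatial.transform.Rotation.align_vectors``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import CoverageError, DegeneracyError, DegeneracyWarning, ValidationError
from .structure import BACKBONE_ATOMS, Ensemble, Structure

__all__ = [
    "ResidueRange",
    "RegionDefinition",
    "SuperpositionResult",
    "kabsch_superpose",
    "apply_transform",
    "loop_rmsd",
    "pairwise_loop_distances",
    "rmsd",
]

LOOP_NAMES = ("H1", "H2", "H3", "L1", "L2", "L3")


def _reskey(seq_id: int, icode: str = "") -> tuple[int, str]:
    return (seq_id, icode)


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbering residue range ``start..end`` (icode-aware)."""

    start: tuple[int, str]
    end: tuple[int, str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"empty residue range {self.start}..{self.end}")

    def contains(self, seq_id: int, icode: str = "") -> bool:
        return self.start <= (seq_id, icode) <= self.end

    @classmethod
    def parse(cls, start, end) -> "ResidueRange":
        return cls(start=_parse_resid(start), end=_parse_resid(end))


def _parse_resid(value) -> tuple[int, str]:
    """Parse ``42`` or ``"42A"`` into ``(42, 'A')``."""
    if isinstance(value, int):
        return (value, "")
    s = str(value).strip()
    i = len(s)
    while i > 0 and not s[i - 1].isdigit():
        i -= 1
    return (int(s[:i]), s[i:])


@dataclass
class RegionDefinition:
    """Partition of a chain into framework ranges and named CDR loops.

    Residue ranges are written against author numbering so that definitions
    survive numbering gaps.  Framework and loop ranges must be disjoint.
    """

    chain_id: str
    framework: tuple[ResidueRange, ...]
    loops: dict[str, ResidueRange] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.framework = tuple(self.framework)
        if not self.framework:
            raise ValidationError("at least one framework range is required")
        for name in self.loops:
            if name not in LOOP_NAMES:
                raise ValidationError(f"unknown loop name {name!r}; expected one of {LOOP_NAMES}")
        ranges = list(self.framework) + list(self.loops.values())
        for i, a in enumerate(ranges):
            for b in ranges[i + 1 :]:
                if a.start <= b.end and b.start <= a.end:
                    raise ValidationError(f"overlapping residue ranges {a} and {b}")

    def loop(self, name: str) -> ResidueRange:
        try:
            return self.loops[name]
        except KeyError:
            raise KeyError(f"loop {name!r} not defined; have {sorted(self.loops)}") from None

    # -- config I/O ---------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RegionDefinition":
        chain = str(data["chain"])
        framework = tuple(ResidueRange.parse(lo, hi) for lo, hi in data["framework"])
        loops = {
            str(name): ResidueRange.parse(lo, hi) for name, (lo, hi) in data.get("loops", {}).items()
        }
        return cls(chain_id=chain, framework=framework, loops=loops)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def fmt(k: tuple[int, str]):
            return k[0] if not k[1] else f"{k[0]}{k[1]}"

        return {
            "chain": self.chain_id,
            "framework": [[fmt(r.start), fmt(r.end)] for r in self.framework],
            "loops": {n: [fmt(r.start), fmt(r.end)] for n, r in self.loops.items()},
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    # -- residue/atom selection --------------------------------------------

    def region_keys(self, structure: Structure, region: str | Iterable[ResidueRange]) -> list[tuple[int, str]]:
        """Residue ids of ``structure``'s region, in ascending (seq_id, icode) order.

        ``region`` is ``"framework"``, a loop name, or an explicit range list.
        """
        if region == "framework":
            ranges: Iterable[ResidueRange] = self.framework
        elif isinstance(region, str):
            ranges = (self.loop(region),)
        else:
            ranges = region
        keys = [
            (r.seq_id, r.insertion_code)
            for r in structure.residues(self.chain_id)
            if any(rng.contains(r.seq_id, r.insertion_code) for rng in ranges)
        ]
        if not keys:
            raise CoverageError(
                f"model {structure.model_id!r}: no residues of chain {self.chain_id!r} "
                f"fall in region {region!r}"
            )
        return sorted(keys)


def backbone_coords(
    structure: Structure,
    chain_id: str,
    keys: Sequence[tuple[int, str]],
    atom_set: Sequence[str] = BACKBONE_ATOMS,
) -> np.ndarray:
    """Stack backbone coordinates for the given residues, strict on coverage.

    A residue or backbone atom missing from ``structure`` is a hard error:
    silently skipping atoms would change the metric.
    """
    resmap = structure.residue_map()
    missing_res = [k for k in keys if (chain_id, k[0], k[1]) not in resmap]
    if missing_res:
        raise CoverageError(
            f"model {structure.model_id!r}: chain {chain_id!r} missing residues {missing_res}"
        )
    coords = []
    for k in keys:
        res = resmap[(chain_id, k[0], k[1])]
        for name in atom_set:
            atom = res.atom(name)
            if atom is None:
                raise CoverageError(
                    f"model {structure.model_id!r}: residue {res.key} missing atom {name!r}"
                )
            coords.append(atom.coord)
    return np.array(coords, dtype=float)


@dataclass
class SuperpositionResult:
    """Proper rigid transform ``x -> R x + t`` fitted by least squares."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return apply_transform(coords, self.rotation, self.translation)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + np.asarray(translation, float)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equally shaped (n, 3) arrays."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns the proper rotation (det +1; reflections corrected) and
    translation minimizing the RMSD of the transformed mobile coordinates
    against the reference.  Collinear point sets yield a best-effort fit and
    a :class:`DegeneracyWarning`.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegeneracyError(f"coordinate sets must both be (n, 3); got {P.shape} and {Q.shape}")
    if len(P) < 3:
        raise DegeneracyError(f"need at least 3 points to superpose, got {len(P)}")
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise DegeneracyError("non-finite coordinates")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rot, _ = Rotation.align_vectors(Q - qc, P - pc)
    for w in caught:
        warnings.warn(
            f"degenerate point set in superposition: {w.message}", DegeneracyWarning, stacklevel=2
        )
    R = rot.as_matrix()
    t = qc - R @ pc
    fitted = apply_transform(P, R, t)
    return SuperpositionResult(rotation=R, translation=t, fit_rmsd=rmsd(fitted, Q))


def loop_rmsd(
    model: Structure,
    reference: Structure,
    regions: RegionDefinition,
    loop: str = "H3",
    atom_set: Sequence[str] = BACKBONE_ATOMS,
) -> float:
    """Framework-aligned backbone RMSD of one CDR loop.

    The model is superposed on the reference over the framework backbone
    atoms; the returned value is the RMSD over the loop's backbone atoms in
    that frame, with no second fit on the loop.
    """
    fw_keys = regions.region_keys(reference, "framework")
    loop_keys = regions.region_keys(reference, loop)
    fit = kabsch_superpose(
        backbone_coords(model, regions.chain_id, fw_keys, atom_set),
        backbone_coords(reference, regions.chain_id, fw_keys, atom_set),
    )
    moved = fit.apply(backbone_coords(model, regions.chain_id, loop_keys, atom_set))
    return rmsd(moved, backbone_coords(reference, regions.chain_id, loop_keys, atom_set))


def pairwise_loop_distances(
    ensemble: Ensemble,
    regions: RegionDefinition,
    loop: str = "H3",
    atom_set: Sequence[str] = BACKBONE_ATOMS,
):
    """All-vs-all framework-aligned loop RMSD matrix over an ensemble.

    Entry ``(i, j)`` is the loop RMSD of member *i* measured against member
    *j* as the reference.  The matrix is symmetric (the least-squares RMSD is
    direction-independent) with a zero diagonal.
    """
    from .cluster import DistanceMatrix  # local import to avoid a cycle

    n = len(ensemble)
    if n == 0:
        raise ValidationError("empty ensemble")
    fw_keys = regions.region_keys(ensemble[0], "framework")
    loop_keys = regions.region_keys(ensemble[0], loop)
    fw = [backbone_coords(m, regions.chain_id, fw_keys, atom_set) for m in ensemble.members]
    lp = [backbone_coords(m, regions.chain_id, loop_keys, atom_set) for m in ensemble.members]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            try:
                fit = kabsch_superpose(fw[i], fw[j])
            except DegeneracyError as exc:
                raise DegeneracyError(
                    f"superposition failed for pair ({ensemble.labels[i]}, {ensemble.labels[j]}): {exc}"
                ) from exc
            values[i, j] = rmsd(fit.apply(lp[i]), lp[j])
    # enforce exact symmetry against float round-off (differences are ~1e-12)
    values = 0.5 * (values + values.T)
    return DistanceMatrix(labels=list(ensemble.labels), values=values)
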