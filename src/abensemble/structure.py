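"""Hierarchical structure model and PDB I/O.

Structures are stored as chains of residues of heavy atoms, with coordinates
in angstrom and per-atom B-factors.  For predicted models the B-factor column
carries the per-residue pLDDT confidence (0-100), the universal convention of
AlphaFold-family predictors.  Parsing and serialization of the PDB format are
delegated to gemmi; this module only maps between gemmi's document model and
the lightweight containers used by the rest of the package.

Conventions applied on reading:

* hetero and solvent records are skipped (predictions contain none; crystal
  references may),
* hydrogens are dropped everywhere — RMSDs and clash checks operate on heavy
  atoms only,
* alternate locations are collapsed to the highest-occupancy conformer,
  ties broken by altloc letter order,
* residues are identified by ``(chain_id, author seq_id, insertion_code)``,
  never by serial position, so residue ranges written against author
  numbering survive gaps.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .errors import EmptyResidueError, PDBParseError, ValidationError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Ensemble",
    "BACKBONE_ATOMS",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "residue_plddt",
]

#: Backbone heavy atoms in their canonical order.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A single heavy atom: label, element, position (angstrom), occupancy, B-factor."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValidationError(
                f"atom {self.name!r}: coord must be 3 finite components, got {self.coord!r}"
            )
        if not self.name:
            raise ValidationError("atom name must be non-empty")


@dataclass
class Residue:
    """One residue; identity is (chain_id, seq_id, insertion_code) in author numbering."""

    chain_id: str
    seq_id: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def backbone(self) -> list[Atom]:
        """Backbone atoms in fixed N, CA, C, O order (subset if some are absent)."""
        found = {a.name: a for a in self.atoms if a.name in BACKBONE_ATOMS}
        return [found[n] for n in BACKBONE_ATOMS if n in found]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """A single structural model: ordered chains of residues of atoms."""

    model_id: str
    chains: list[Chain] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate chain ids in model {self.model_id!r}: {ids}")
        if not any(c.residues for c in self.chains):
            raise ValidationError(f"model {self.model_id!r} has no residues")
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise ValidationError(f"duplicate residue {res.key} in model {self.model_id!r}")
            seen.add(res.key)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in model {self.model_id!r}")

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        for c in self.chains:
            if chain_id is None or c.id == chain_id:
                yield from c.residues

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues()}

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, in traversal order."""
        return np.array([a.coord for r in self.residues() for a in r.atoms], dtype=float)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy: ``x -> R x + t``."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in out.residues():
            for a in res.atoms:
                a.coord = R @ a.coord + t
        return out

    def residue_identities(self) -> tuple[tuple[str, int, str, str], ...]:
        """Per-residue identity fingerprint (chain, seq_id, icode, res_name)."""
        return tuple((r.chain_id, r.seq_id, r.insertion_code, r.res_name) for r in self.residues())


@dataclass
class Ensemble:
    """An ordered collection of structures sharing residue identities.

    Member order is stable: it is the order of the MODEL records on disk or
    of construction, and every downstream operation (clustering tie-breaks,
    "first n models" truncation) refers to it.
    """

    members: list[Structure] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [m.model_id for m in self.members]
        if len(self.labels) != len(self.members):
            raise ValidationError("labels and members must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("ensemble labels must be unique")
        if self.members:
            ref = self.members[0].residue_identities()
            for lab, m in zip(self.labels, self.members):
                if m.residue_identities() != ref:
                    raise ValidationError(
                        f"ensemble member {lab!r} has residue identities differing "
                        f"from member {self.labels[0]!r}"
                    )

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i: int) -> Structure:
        return self.members[i]

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        return Ensemble(
            members=[self.members[i] for i in indices],
            labels=[self.labels[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# gemmi conversion


def _element_symbol(gatom: gemmi.Atom) -> str:
    sym = gatom.element.name
    return sym if sym and sym != "X" else gatom.name[:1]


def _convert_residue(chain_id: str, gres: gemmi.Residue) -> Residue | None:
    res = Residue(
        chain_id=chain_id,
        seq_id=gres.seqid.num,
        insertion_code=gres.seqid.icode.strip(),
        res_name=gres.name,
        atoms=[],
    )
    # collapse altlocs: highest occupancy wins, ties by altloc letter
    best: dict[str, gemmi.Atom] = {}
    for ga in gres:
        if ga.element.is_hydrogen:
            continue
        prev = best.get(ga.name)
        if (
            prev is None
            or ga.occ > prev.occ
            or (ga.occ == prev.occ and _altloc_rank(ga) < _altloc_rank(prev))
        ):
            best[ga.name] = ga
    for ga in gres:
        if ga.name in best and best[ga.name] is ga:
            res.atoms.append(
                Atom(
                    name=ga.name,
                    element=_element_symbol(ga),
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    bfactor=ga.b_iso,
                )
            )
    return res if res.atoms else None


def _altloc_rank(ga: gemmi.Atom) -> str:
    return ga.altloc if ga.altloc != "\0" else ""


def _convert_model(gmodel: gemmi.Model, model_id: str, source: str) -> Structure:
    chains: list[Chain] = []
    for gchain in gmodel:
        chain = Chain(id=gchain.name, residues=[])
        for gres in gchain:
            if gres.is_water() or gres.het_flag == "H":
                continue
            res = _convert_residue(gchain.name, gres)
            if res is not None:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    return Structure(model_id=model_id, chains=chains, source=source)


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    return st


def read_structure(path: str | Path, model_index: int | None = None) -> Structure:
    """Read one model from a (possibly multi-model) PDB file.

    Parameters
    ----------
    path:
        PDB (or mmCIF) file.
    model_index:
        1-based MODEL selector; ``None`` takes the first model.
    """
    st = _read_gemmi(path)
    if model_index is None:
        idx = 0
    else:
        idx = model_index - 1
        if idx < 0 or idx >= len(st):
            raise IndexError(
                f"model_index {model_index} out of range: {path} has {len(st)} model(s)"
            )
    gmodel = st[idx]
    return _convert_model(gmodel, model_id=f"{Path(path).stem}_{gmodel.num}", source=str(path))


def read_ensemble(path: str | Path) -> Ensemble:
    """Read every model of a multi-model PDB file into an :class:`Ensemble`."""
    st = _read_gemmi(path)
    stem = Path(path).stem
    members = [_convert_model(m, model_id=f"{stem}_{m.num}", source=str(path)) for m in st]
    return Ensemble(members=members)


def _to_gemmi(ensemble: Ensemble) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "abensemble"
    for i, member in enumerate(ensemble.members):
        gm = gemmi.Model(i + 1)
        for chain in member.chains:
            gc = gemmi.Chain(chain.id)
            for res in chain.residues:
                gr = gemmi.Residue()
                gr.name = res.res_name
                gr.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
                gr.het_flag = "A"
                for a in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coord)
                    ga.occ = a.occupancy
                    ga.b_iso = a.bfactor
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    return st


def write_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB with one MODEL record per member.

    Member order is preserved and the B-factor column carries the stored
    per-atom values (pLDDT for predictions).
    """
    if len(ensemble) == 0:
        raise ValidationError("cannot write an empty ensemble")
    path = Path(path)
    st = _to_gemmi(ensemble)
    text = st.make_pdb_string()
    if len(ensemble) == 1:
        # gemmi omits MODEL records for a single model; downstream ensemble
        # consumers expect them, so wrap the coordinate block explicitly.
        lines = text.splitlines()
        first = next(i for i, l in enumerate(lines) if l.startswith(("ATOM", "HETATM")))
        last = max(
            i for i, l in enumerate(lines) if l.startswith(("ATOM", "HETATM", "TER"))
        )
        lines.insert(last + 1, "ENDMDL")
        lines.insert(first, "MODEL        1")
        text = "\n".join(lines) + "\n"
    path.write_text(text)
    return path


def residue_plddt(residue: Residue) -> float:
    """Per-residue confidence: the CA B-factor, or the mean over atoms if CA is absent."""
    if not residue.atoms:
        raise EmptyResidueError(f"residue {residue.key} has no atoms")
    ca = residue.atom("CA")
    if ca is not None:
        return float(ca.bfactor)
    return float(np.mean([a.bfactor for a in residue.atoms]))
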