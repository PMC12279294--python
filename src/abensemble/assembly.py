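"""Heavy/light chain assembly and the backbone steric clash filter.

Generative heavy-chain models are combined with a separately predicted light
chain to form full antibody models.  Because the H3 loop is sampled without
knowledge of the light chain, some conformations run straight into it; such
models are detected by a simple hard-sphere criterion — two backbone heavy
atoms clash when their distance is **strictly lower** than a fixed fraction
(default 0.63) of the sum of their van der Waals radii — and models with
more than ``max_clashes`` (default 1) backbone clashes are removed.

The default radii are a standard van der Waals set (C 1.70, N 1.55, O 1.52,
S 1.80 angstrom) and can be overridden from a YAML config.  Pairs within one
residue and between sequence-adjacent residues of the same chain are never
counted: covalent geometry is not a clash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structure import Ensemble, Structure

__all__ = [
    "RadiiTable",
    "Clash",
    "ClashReport",
    "DEFAULT_RADII",
    "merge_chains",
    "count_backbone_clashes",
    "filter_clashed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius (angstrom)."""

    radii: dict[str, float] = field(
        default_factory=lambda: {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    )

    def __post_init__(self) -> None:
        missing = {"C", "N", "O", "S"} - set(self.radii)
        if missing:
            raise ValidationError(f"radii table must cover C, N, O, S; missing {sorted(missing)}")
        if any(r <= 0 for r in self.radii.values()):
            raise ValidationError("all radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise LookupError(f"element {element!r} missing from radii table") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RadiiTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(radii={str(k): float(v) for k, v in data.items()})


DEFAULT_RADII = RadiiTable()


@dataclass(frozen=True)
class Clash:
    atom_a: str
    atom_b: str
    distance: float
    threshold: float


@dataclass
class ClashReport:
    model_label: str
    clashes: list[Clash]

    def __post_init__(self) -> None:
        for c in self.clashes:
            if not c.distance < c.threshold:
                raise ValidationError(f"reported pair {c} is not below its threshold")

    @property
    def count(self) -> int:
        return len(self.clashes)


def merge_chains(
    heavy: Structure,
    light: Structure,
    heavy_id: str = "H",
    light_id: str = "L",
) -> Structure:
    """Combine a heavy-chain and a light-chain model into one structure.

    Each source must hold exactly one chain; it is relabelled to ``heavy_id``
    / ``light_id``.  Coordinates and residue numbering are untouched.
    """
    if heavy_id == light_id:
        raise ValidationError(f"heavy and light chain ids collide: {heavy_id!r}")
    parts = []
    for src, new_id in ((heavy, heavy_id), (light, light_id)):
        if len(src.chains) != 1:
            raise ValidationError(
                f"model {src.model_id!r} must hold exactly one chain to merge, "
                f"has {[c.id for c in src.chains]}"
            )
        chain = src.copy().chains[0]
        chain.id = new_id
        for res in chain.residues:
            res.chain_id = new_id
        parts.append(chain)
    return Structure(
        model_id=f"{heavy.model_id}+{light.model_id}",
        chains=parts,
        source=f"merged({heavy.source},{light.source})",
    )


def _atom_table(structure: Structure, radii: RadiiTable, backbone_only: bool):
    """Flat arrays describing every (backbone) heavy atom of the structure."""
    ids, coords, rad, chain_idx, res_ord = [], [], [], [], []
    for c_i, chain in enumerate(structure.chains):
        for r_i, res in enumerate(chain.residues):
            atoms = res.backbone() if backbone_only else res.atoms
            for a in atoms:
                ids.append(f"{chain.id}/{res.seq_id}{res.insertion_code}/{a.name}")
                coords.append(a.coord)
                rad.append(radii.radius(a.element))
                chain_idx.append(c_i)
                res_ord.append(r_i)
    return (
        ids,
        np.asarray(coords, float),
        np.asarray(rad, float),
        np.asarray(chain_idx),
        np.asarray(res_ord),
    )


def count_backbone_clashes(
    structure: Structure,
    radii: RadiiTable = DEFAULT_RADII,
    fraction: float = 0.63,
    chain_pair: tuple[str, str] | None = None,
    backbone_only: bool = True,
) -> ClashReport:
    """Count steric clashes between backbone heavy atoms.

    An unordered atom pair clashes when its distance is strictly lower than
    ``fraction * (r_a + r_b)``.  Pairs within one residue, and between
    sequence-adjacent residues of the same chain, are excluded.  When
    ``chain_pair`` is given only pairs spanning those two chains are tested.
    The scan uses a k-d tree pruned at the largest possible threshold, so it
    is exact with respect to the all-pairs definition.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    ids, coords, rad, chain_idx, res_ord = _atom_table(structure, radii, backbone_only)
    chain_ids = [c.id for c in structure.chains]
    pair_sel = None
    if chain_pair is not None:
        for cid in chain_pair:
            if cid not in chain_ids:
                raise KeyError(f"chain {cid!r} not in model {structure.model_id!r}")
        pair_sel = (chain_ids.index(chain_pair[0]), chain_ids.index(chain_pair[1]))
    clashes: list[Clash] = []
    if len(coords) >= 2:
        tree = cKDTree(coords)
        rmax = 2.0 * float(rad.max()) * fraction
        for i, j in sorted(map(tuple, tree.query_pairs(r=rmax, output_type="ndarray"))):
            same_chain = chain_idx[i] == chain_idx[j]
            if same_chain and abs(int(res_ord[i]) - int(res_ord[j])) <= 1:
                continue
            if pair_sel is not None and {chain_idx[i], chain_idx[j]} != set(pair_sel):
                continue
            threshold = fraction * (rad[i] + rad[j])
            distance = float(np.linalg.norm(coords[i] - coords[j]))
            if distance < threshold:
                clashes.append(Clash(ids[i], ids[j], distance, float(threshold)))
    return ClashReport(model_label=structure.model_id, clashes=clashes)


def filter_clashed(
    ensemble: Ensemble,
    radii: RadiiTable = DEFAULT_RADII,
    fraction: float = 0.63,
    max_clashes: float = 1,
    chain_pair: tuple[str, str] | None = None,
) -> tuple[Ensemble, list[ClashReport]]:
    """Drop ensemble members with more than ``max_clashes`` backbone clashes.

    Surviving members keep their original order; the reports cover every
    member, kept or removed.  ``max_clashes=math.inf`` keeps everything.
    """
    reports = [
        count_backbone_clashes(m, radii=radii, fraction=fraction, chain_pair=chain_pair)
        for m in ensemble.members
    ]
    keep = [i for i, rep in enumerate(reports) if rep.count <= max_clashes]
    if not keep:
        logger.warning(
            "all %d members exceeded %s backbone clashes; ensemble is empty",
            len(ensemble), max_clashes,
        )
    return ensemble.subset(keep), reports


def clash_report_frame(reports: Sequence[ClashReport], max_clashes: float = 1):
    """Tabular clash summary (member, clash count, kept flag)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "member": [r.model_label for r in reports],
            "clashes": [r.count for r in reports],
            "kept": [r.count <= max_clashes for r in reports],
        }
    )
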