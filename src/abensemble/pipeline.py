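"""End-to-end ensemble preparation: truncate -> cluster -> assemble -> filter.

``run_prepare`` turns a large heavy-chain model ensemble plus one light
chain model into a small, clash-free, structurally diverse multi-model PDB
ready for ensemble docking, and writes a manifest that is sufficient to
replay the run.  Defaults are the pipeline's operating point: keep the first
100 models, cluster to K=20 with complete linkage on the H3 loop RMSD,
then drop assembled models with more than one backbone clash at the
0.63-of-summed-radii criterion.  The ``af2-baseline`` preset is the same
reduction at n=25, K=5, matching the conventional treatment of a 5-seed
AlphaFold2 run.

Energy minimization of the assembled models is deliberately left to the
downstream docking suite; the manifest records ``"minimization":
"external"`` so the gap is explicit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly import RadiiTable, clash_report_frame, filter_clashed, merge_chains
from .cluster import reduce_ensemble
from .errors import DataError, ValidationError
from .geometry import RegionDefinition, loop_rmsd
from .structure import Ensemble, Structure, read_ensemble, read_structure, write_ensemble
from .triage import loop_mean_plddt

__all__ = ["PipelineConfig", "RunManifest", "run_prepare", "run_report"]

logger = logging.getLogger(__name__)

PRESETS: dict[str, dict] = {
    # conventional AlphaFold2 treatment: 25 models (5 seeds x 5) -> 5 centers
    "af2-baseline": {"n_models": 25, "k_clusters": 5},
}


@dataclass
class PipelineConfig:
    """Operating parameters of the preparation pipeline (defaults = standard run)."""

    loop: str = "H3"
    plddt_threshold: float = 80.0
    n_models: int = 100
    k_clusters: int = 20
    linkage: str = "complete"
    clash_fraction: float = 0.63
    max_clashes: float = 1
    heavy_chain_id: str = "H"
    light_chain_id: str = "L"
    seed: int = 0
    radii: RadiiTable = field(default_factory=RadiiTable)

    def __post_init__(self) -> None:
        if self.k_clusters < 1 or self.n_models < self.k_clusters:
            raise ValidationError("need 1 <= k_clusters <= n_models")
        if not 0 <= self.plddt_threshold <= 100:
            raise ValidationError("plddt_threshold must be in [0, 100]")

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        try:
            base = PRESETS[name]
        except KeyError:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
        return cls(**{**base, **overrides})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radii"] = dict(self.radii.radii)
        d["max_clashes"] = None if math.isinf(self.max_clashes) else self.max_clashes
        return d


@dataclass
class RunManifest:
    """Replayable record of one prepare run."""

    config: dict
    input_hashes: dict[str, str]
    counts: dict[str, int]
    version: str = __version__
    minimization: str = "external"
    timestamp: str = ""

    def __post_init__(self) -> None:
        stages = ["input", "truncated", "clustered", "filtered"]
        vals = [self.counts[s] for s in stages if s in self.counts]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValidationError(f"stage counts must be non-increasing, got {self.counts}")

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def equivalent(self, other: "RunManifest") -> bool:
        """Equality modulo timestamps."""
        a, b = dataclasses.asdict(self), dataclasses.asdict(other)
        a.pop("timestamp"), b.pop("timestamp")
        return a == b


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_prepare(
    heavy_ensemble: str | Path,
    light_model: str | Path,
    regions: RegionDefinition,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[Path, RunManifest]:
    """Prepare a docking-ready antibody ensemble from a heavy-chain ensemble.

    Stages: truncate to the first ``n_models`` members (ensemble order) ->
    cluster to ``k_clusters`` centers on framework-aligned loop RMSD ->
    merge each center with the light chain -> remove models with more than
    ``max_clashes`` inter-chain backbone clashes -> write the multi-model
    PDB, per-member TSV logs and the manifest.

    Returns the output ensemble path and the manifest.  An ensemble left
    empty by the clash filter raises :class:`DataError`.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ensemble = read_ensemble(heavy_ensemble)
    light = read_structure(light_model)
    n_input = len(ensemble)
    if n_input < config.k_clusters:
        raise DataError(
            f"stage truncate: {n_input} input models < k_clusters={config.k_clusters}"
        )
    head = ensemble.subset(range(min(config.n_models, n_input)))

    reduced, assignment = reduce_ensemble(
        head, regions, loop=config.loop, k=config.k_clusters,
        linkage=config.linkage, return_assignment=True,
    )
    merged = Ensemble(
        members=[
            merge_chains(m, light, config.heavy_chain_id, config.light_chain_id)
            for m in reduced.members
        ],
        labels=list(reduced.labels),
    )
    kept, reports = filter_clashed(
        merged,
        radii=config.radii,
        fraction=config.clash_fraction,
        max_clashes=config.max_clashes,
        chain_pair=(config.heavy_chain_id, config.light_chain_id),
    )
    clash_df = clash_report_frame(reports, config.max_clashes)
    clash_df.to_csv(outdir / "clash_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "member": list(assignment.membership),
            "cluster": [assignment.membership[m] for m in assignment.membership],
            "is_center": [
                assignment.centers[assignment.membership[m]] == m
                for m in assignment.membership
            ],
        }
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config=config.to_dict(),
        input_hashes={
            "heavy_ensemble": _sha256(heavy_ensemble),
            "light_model": _sha256(light_model),
        },
        counts={
            "input": n_input,
            "truncated": len(head),
            "clustered": len(reduced),
            "filtered": len(kept),
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    if len(kept) == 0:
        raise DataError(
            "stage clash-filter: every clustered model exceeded the clash limit; "
            f"see {outdir / 'clash_report.tsv'}"
        )
    out_path = outdir / "prepared_ensemble.pdb"
    write_ensemble(kept, out_path)
    logger.info("prepared %d/%d models -> %s", len(kept), n_input, out_path)
    return out_path, manifest


def run_report(
    outdir: str | Path,
    regions: RegionDefinition,
    reference: Structure | None = None,
) -> pd.DataFrame:
    """Per-model summary of a prepare run (pLDDT, triage class, cluster, clashes).

    With a reference heavy chain the framework-aligned loop RMSD of each
    kept model is added, plus a ``best_center_rmsd`` column holding the
    minimum over kept models.
    """
    outdir = Path(outdir)
    missing = [
        str(p)
        for p in (outdir / "manifest.json", outdir / "prepared_ensemble.pdb",
                  outdir / "clash_report.tsv", outdir / "clusters.tsv")
        if not p.exists()
    ]
    if missing:
        raise DataError(f"missing stage outputs: {missing}")
    manifest = RunManifest.read(outdir / "manifest.json")
    config = manifest.config
    kept = read_ensemble(outdir / "prepared_ensemble.pdb")
    clash_df = pd.read_csv(outdir / "clash_report.tsv", sep="\t")
    clash_kept = clash_df[clash_df["kept"]].reset_index(drop=True)
    clusters_df = pd.read_csv(outdir / "clusters.tsv", sep="\t")
    center_cluster = {
        row["member"]: int(row["cluster"])
        for _, row in clusters_df.iterrows()
        if row["is_center"]
    }
    rows = []
    for i, member in enumerate(kept.members):
        plddt = loop_mean_plddt(member, regions, config["loop"])
        label = str(clash_kept.loc[i, "member"])
        heavy_label = label.split("+")[0]
        rows.append(
            {
                "member": label,
                "loop_mean_plddt": plddt,
                "triage": "confident" if plddt >= config["plddt_threshold"] else "difficult",
                "cluster": center_cluster.get(heavy_label, -1),
                "clashes": int(clash_kept.loc[i, "clashes"]),
            }
        )
    df = pd.DataFrame(rows)
    if reference is not None:
        rmsds = [
            loop_rmsd(m, reference, regions, config["loop"]) for m in kept.members
        ]
        df["loop_rmsd"] = rmsds
        df["best_center_rmsd"] = min(rmsds)
    return df
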