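"""pLDDT-based triage of antibody models.

Structure predictors emit a per-residue confidence (pLDDT, 0-100) that for
antibodies is a strong — and strongly anti-correlated — proxy for H3 loop
accuracy.  Models whose loop mean pLDDT falls strictly below a threshold
(default 80) are flagged *difficult*: these are the cases where a single
predicted conformation cannot be trusted and a diverse generative ensemble
is worth the cost.  Models at or above the threshold are *confident*.

The complementary split by realized accuracy uses a loop-RMSD threshold
(default 3.0 angstrom): *right* means best loop RMSD strictly below it.
Both boundary conventions mirror the strict inequalities of the triage
definitions and are asserted by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError
from .geometry import RegionDefinition
from .structure import Ensemble, Structure, residue_plddt

__all__ = [
    "TriageResult",
    "AccuracySplit",
    "loop_mean_plddt",
    "triage_models",
    "split_by_accuracy",
    "plddt_rmsd_correlation",
    "best_by_plddt",
]


@dataclass
class TriageResult:
    values: dict[str, float]
    threshold: float

    @property
    def confident(self) -> list[str]:
        return [lab for lab, v in self.values.items() if v >= self.threshold]

    @property
    def difficult(self) -> list[str]:
        return [lab for lab, v in self.values.items() if v < self.threshold]


@dataclass
class AccuracySplit:
    rmsd_threshold: float
    right: list[str]
    wrong: list[str]


def loop_mean_plddt(model: Structure, regions: RegionDefinition, loop: str = "H3") -> float:
    """Unweighted mean of per-residue pLDDT over the loop's residues."""
    keys = regions.region_keys(model, loop)
    resmap = model.residue_map()
    return float(
        np.mean([residue_plddt(resmap[(regions.chain_id, s, i)]) for s, i in keys])
    )


def triage_models(
    models: Ensemble,
    regions: RegionDefinition,
    loop: str = "H3",
    threshold: float = 80.0,
) -> TriageResult:
    """Partition models into confident (loop mean pLDDT >= threshold) and difficult.

    A value exactly equal to the threshold counts as confident: "difficult"
    is defined by a strictly lower confidence.
    """
    values = {
        lab: loop_mean_plddt(m, regions, loop) for lab, m in zip(models.labels, models.members)
    }
    return TriageResult(values=values, threshold=float(threshold))


def split_by_accuracy(
    best_rmsd_per_model: Mapping[str, float], rmsd_threshold: float = 3.0
) -> AccuracySplit:
    """Split targets into right (best loop RMSD < threshold) and wrong (the rest)."""
    if rmsd_threshold <= 0:
        raise ValueError(f"rmsd_threshold must be positive, got {rmsd_threshold}")
    right = [lab for lab, v in best_rmsd_per_model.items() if v < rmsd_threshold]
    wrong = [lab for lab, v in best_rmsd_per_model.items() if v >= rmsd_threshold]
    return AccuracySplit(rmsd_threshold=float(rmsd_threshold), right=right, wrong=wrong)


def plddt_rmsd_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between loop mean pLDDT and loop RMSD.

    For well-behaved predictors this is strongly negative: low confidence
    goes with large loop errors.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise UndefinedMetricError("need at least 3 (plddt, rmsd) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise UndefinedMetricError("correlation undefined: zero variance in one coordinate")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)


def best_by_plddt(models: Ensemble, regions: RegionDefinition, loop: str = "H3") -> str:
    """Label of the member with the highest loop mean pLDDT (ties: ensemble order)."""
    values = [loop_mean_plddt(m, regions, loop) for m in models.members]
    return models.labels[int(np.argmax(values))]
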