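"""Recording-inclusion rules and the percentile-based maturity cutoff.

A cell enters the genotype analysis only if: the initial seal was at
least 1 GOhm; series resistance never exceeded 20 MOhm and changed by
less than 30 % over the recording; the recording started no more than
7 h after slice preparation; and the input resistance is at or below the
maturity cutoff (550 MOhm by default, the 95th percentile of a reference
population of mature granule cells). Boundary semantics: R_in exactly at
the cutoff and R_s exactly at 20 MOhm pass; an R_s change of exactly
30 % fails (the rule is "changed less than 30 %").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .passive_props import PassiveProperties
from .synth_ephys import CellRecording

__all__ = ["InclusionCriteria", "InclusionDecision", "check_cell",
           "compute_rin_cutoff", "qc_report"]


@dataclass(frozen=True)
class InclusionCriteria:
    seal_min_GOhm: float = 1.0
    Rs_max_MOhm: float = 20.0
    Rs_change_max_pct: float = 30.0
    Rin_max_MOhm: float = 550.0
    max_hours_post_slice: float = 7.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class InclusionDecision:
    included: bool
    failed_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.included != (len(self.failed_rules) == 0):
            raise ValueError("included must match failed_rules being empty")


def check_cell(
    cell: CellRecording,
    props: PassiveProperties,
    rs_change_pct: float | None,
    criteria: InclusionCriteria = InclusionCriteria(),
) -> InclusionDecision:
    """Evaluate all five inclusion rules for one cell.

    Missing metadata makes the corresponding rule not-evaluable and the
    cell is excluded with that rule named.
    """
    failed: list[str] = []
    if cell.seal_GOhm is None:
        failed.append("seal:not-evaluable")
    elif cell.seal_GOhm < criteria.seal_min_GOhm:
        failed.append("seal")
    if props.R_s > criteria.Rs_max_MOhm:  # "did not exceed": boundary passes
        failed.append("Rs")
    if rs_change_pct is None:
        failed.append("Rs_change:not-evaluable")
    elif rs_change_pct >= criteria.Rs_change_max_pct:  # "< 30 %": boundary fails
        failed.append("Rs_change")
    if props.R_in > criteria.Rin_max_MOhm:  # "<= 550": boundary passes
        failed.append("Rin")
    if cell.time_since_slice_h is None:
        failed.append("time_post_slice:not-evaluable")
    elif cell.time_since_slice_h > criteria.max_hours_post_slice:
        failed.append("time_post_slice")
    return InclusionDecision(included=not failed, failed_rules=failed)


def compute_rin_cutoff(rin_sample: Sequence[float], percentile: float = 95.0) -> float:
    """Empirical percentile of a reference R_in sample (MOhm).

    Uses the linear-interpolation percentile definition. The pipeline's
    default cutoff of 550 MOhm was derived from a reference population of
    mature granule cells that is not shipped; this function recomputes
    the cutoff for any new reference sample of at least 20 cells.
    """
    arr = np.asarray(rin_sample, dtype=float)
    if arr.size < 20:
        raise ValueError(f"reference sample of {arr.size} cells; >= 20 required")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(arr, percentile, method="linear"))


def qc_report(
    decisions: Sequence[tuple[str, InclusionDecision]]
) -> pd.DataFrame:
    """QC table: cell_id, included, failed_rules (semicolon-joined)."""
    return pd.DataFrame(
        {
            "cell_id": [cid for cid, _ in decisions],
            "included": [d.included for _, d in decisions],
            "failed_rules": [";".join(d.failed_rules) for _, d in decisions],
        }
    )
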