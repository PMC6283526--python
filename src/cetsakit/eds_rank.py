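"""Euclidean distance score (EDS) ranking for duplicate melt designs.

For a protein measured in a 2 control + 2 treatment melt design, the
pairwise Euclidean distance between two melting curves is taken in the
10-dimensional fold-change space.  The score

    EDS = sum(ED inter-treatment) / (K * sum(ED inter-replicate)),  K = 10

contrasts the apparent shift (every control x treatment pair, 4 pairs)
against the replicate reproducibility (within-condition pairs, 2 pairs); a
large EDS means a reproducible and significant thermal shift.  The constant
K only rescales and never changes the ranking; it is exposed as
``denom_const`` because the canonical value is a typographic convention.

Ranking order: infinite scores (perfectly reproducible shift, zero
within-condition distance) first, finite scores descending, the degenerate
0/0 case (four identical curves: no shift, no noise) at the bottom of the
scored set, and proteins without a complete 2+2 design last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .melt_normalize import FoldChangeCurve

#: minimum shared (pairwise non-missing) points for a valid curve distance
MIN_SHARED_POINTS = 8


@dataclass
class CurveQuad:
    """One protein's control and treatment melting-curve replicates."""

    protein_id: str
    control_curves: List[FoldChangeCurve]
    treatment_curves: List[FoldChangeCurve]

    def __post_init__(self) -> None:
        grids = [c.x_values for c in self.control_curves + self.treatment_curves]
        for g in grids[1:]:
            if not np.array_equal(g, grids[0]):
                raise ContractError("all curves of a CurveQuad must share one grid")


@dataclass
class EDSResult:
    protein_id: str
    ed_inter_treatment_sum: float
    ed_inter_replicate_sum: float
    eds: Optional[float]  # None for undefined; math.inf for the infinite flag
    n_runs: int
    reason: str = ""
    flags: List[str] = field(default_factory=list)

    @property
    def is_infinite(self) -> bool:
        return self.eds is not None and math.isinf(self.eds)


def pairwise_ed(curve1: FoldChangeCurve, curve2: FoldChangeCurve) -> float:
    """Euclidean distance between two melting curves in 10-space.

    Points missing in either curve are dropped pairwise; fewer than 8 shared
    points make the distance undefined (ContractError; callers exclude the
    protein with a reason).
    """
    if not np.array_equal(curve1.x_values, curve2.x_values):
        raise ContractError("pairwise_ed requires identical x grids")
    shared = np.isfinite(curve1.fold_changes) & np.isfinite(curve2.fold_changes)
    if shared.sum() < MIN_SHARED_POINTS:
        raise ContractError("fewer_than_8_shared_points")
    diff = curve1.fold_changes[shared] - curve2.fold_changes[shared]
    return float(np.sqrt(np.dot(diff, diff)))


def compute_eds(quad: CurveQuad, denom_const: float = 10.0) -> EDSResult:
    """EDS for one protein; see module docstring for pair enumeration."""
    n_runs = len(quad.control_curves) + len(quad.treatment_curves)
    if len(quad.control_curves) < 2 or len(quad.treatment_curves) < 2:
        return EDSResult(quad.protein_id, math.nan, math.nan, None,
                         n_runs, reason="incomplete_design")
    try:
        inter_treat = sum(
            pairwise_ed(a, b)
            for a, b in product(quad.control_curves, quad.treatment_curves))
        inter_rep = sum(
            pairwise_ed(a, b) for cond in (quad.control_curves, quad.treatment_curves)
            for a, b in combinations(cond, 2))
    except ContractError:
        return EDSResult(quad.protein_id, math.nan, math.nan, None,
                         n_runs, reason="insufficient_shared_points")

    if inter_rep == 0.0:
        if inter_treat == 0.0:
            # four identical curves: no shift, no noise
            return EDSResult(quad.protein_id, 0.0, 0.0, None, n_runs,
                             reason="degenerate_identical_curves",
                             flags=["zero_over_zero"])
        return EDSResult(quad.protein_id, inter_treat, 0.0, math.inf, n_runs,
                         flags=["infinite"])
    return EDSResult(quad.protein_id, inter_treat, inter_rep,
                     inter_treat / (denom_const * inter_rep), n_runs)


def _rank_key(r: EDSResult):
    if r.eds is not None and math.isinf(r.eds):
        cat = 0
    elif r.eds is not None:
        cat = 1
    elif r.reason == "degenerate_identical_curves":
        cat = 2
    else:
        cat = 3  # undefined (incomplete design / too few shared points)
    eds = r.eds if (r.eds is not None and math.isfinite(r.eds)) else 0.0
    it = r.ed_inter_treatment_sum if math.isfinite(r.ed_inter_treatment_sum) else 0.0
    return (cat, -eds, -it, r.protein_id)


def rank_by_eds(results: Sequence[EDSResult]) -> List[EDSResult]:
    """Descending-EDS order: infinite first (by inter-treatment sum), then
    finite descending, degenerate 0/0 next, undefined last.  Stable under
    input permutation (protein id is the final tie-break)."""
    return sorted(results, key=_rank_key)


def eds_table(results: Sequence[EDSResult]) -> pd.DataFrame:
    rows = []
    for rank, r in enumerate(rank_by_eds(results), start=1):
        rows.append({
            "rank": rank,
            "protein_id": r.protein_id,
            "eds": (np.inf if r.is_infinite else
                    (np.nan if r.eds is None else r.eds)),
            "ed_inter_treatment_sum": r.ed_inter_treatment_sum,
            "ed_inter_replicate_sum": r.ed_inter_replicate_sum,
            "n_runs": r.n_runs,
            "reason": r.reason,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows, columns=[
        "rank", "protein_id", "eds", "ed_inter_treatment_sum",
        "ed_inter_replicate_sum", "n_runs", "reason", "flags"])
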