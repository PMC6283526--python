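"""Fold-change computation and run-level normalization.

Melt runs use the two-stage scheme: (1) the per-temperature medians of the
fold changes of *all* quantified proteins are fitted with an LL.4 sigmoid
representing the average melting trend of the proteome, and a fitting-factor
vector is formed as fitted/raw median per temperature; (2) a scaling factor
(1 / fitted median at the 37 degC reference) rescales the vector so the
normalized reference median is exactly 1.  Applying the resulting ten
normalization factors aligns every run onto a common proteome melting trend.

ITDR/ITTR runs instead use median-to-1 normalization: each channel is scaled
so its median fold change across proteins is exactly 1 (channel-wise by
default; a single global factor is available as a config switch since the
source description is ambiguous on this point).  Under either scheme a
non-responsive protein is flat at 1, which is what the downstream baseline
band presumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curve_models import LL4Fit, fit_ll4, ll4_eval
from .errors import ContractError, DataError
from .quant_io import ChannelMap, N_CHANNELS, ProteinQuant

logger = logging.getLogger(__name__)

#: minimum proteins before run-level normalization is attempted
MIN_PROTEINS_FOR_NORMALIZATION = 100
#: a melt-trend fit below this R^2 is treated as failed (flat, non-melting run)
MIN_MELT_FIT_R2 = 0.5


@dataclass
class FoldChangeCurve:
    """Per-protein fold changes on an ordered 10-point x grid.

    The reference entry is exactly 1 by construction; NaN marks missing
    channels, which propagate through normalization untouched.
    """

    protein_id: str
    x_values: np.ndarray
    fold_changes: np.ndarray
    x_kind: str
    run_id: str
    treatment: str
    replicate: int
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        if self.fold_changes.shape != (N_CHANNELS,):
            raise DataError("fold_changes must have length 10")

    @property
    def n_usable(self) -> int:
        return int(np.isfinite(self.fold_changes).sum())


@dataclass(frozen=True)
class ExclusionRecord:
    protein_id: str
    run_id: str
    reason: str


@dataclass
class NormalizationFactors:
    """Ten per-channel factors for one run plus their provenance."""

    run_id: str
    factors: np.ndarray
    fitted_medians: np.ndarray
    raw_medians: np.ndarray
    scaling_factor: float
    fit: Optional[LL4Fit] = None
    warnings: List[str] = field(default_factory=list)

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.factors, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "run_id": self.run_id,
            "channel": np.arange(N_CHANNELS),
            "raw_median": self.raw_medians,
            "fitted_median": self.fitted_medians,
            "factor": self.factors,
            "scaling_factor": self.scaling_factor,
        })


def fold_changes(q: ProteinQuant, cm: ChannelMap) -> FoldChangeCurve:
    """Fold changes of one protein relative to the run's reference channel.

    Raises DataError("zero_reference") when the reference abundance is
    missing or zero; batch callers catch this into an ExclusionRecord.
    """
    ref = q.abundances[cm.reference_index]
    if not np.isfinite(ref) or ref <= 0:
        raise DataError("zero_reference")
    fc = q.abundances / ref
    fc[cm.reference_index] = 1.0  # exact by construction
    return FoldChangeCurve(
        protein_id=q.protein_id,
        x_values=cm.x_array,
        fold_changes=fc,
        x_kind=cm.x_kind,
        run_id=cm.run_id,
        treatment=cm.treatment,
        replicate=cm.replicate,
        reference_index=cm.reference_index,
    )


def run_fold_changes(
    records: Iterable[ProteinQuant], cm: ChannelMap
) -> Tuple[List[FoldChangeCurve], List[ExclusionRecord]]:
    """fold_changes over a whole run, collecting exclusions instead of raising."""
    curves, excluded = [], []
    for q in records:
        try:
            curves.append(fold_changes(q, cm))
        except DataError as exc:
            excluded.append(ExclusionRecord(q.protein_id, cm.run_id, str(exc)))
    return curves, excluded


def _fc_matrix(curves: Sequence[FoldChangeCurve]) -> np.ndarray:
    return np.vstack([c.fold_changes for c in curves])


def derive_melt_normalization(
    curves: Sequence[FoldChangeCurve],
    min_proteins: int = MIN_PROTEINS_FOR_NORMALIZATION,
) -> NormalizationFactors:
    """Fitting-factor vector + scaling factor for one melt run.

    Medians are taken over all quantified proteins (not a curated subset).
    If the proteome-median sigmoid fit fails or is degenerate, identity
    factors are returned with a warning so the run is flagged, not dropped.
    """
    if len(curves) < min_proteins:
        raise DataError(
            f"melt normalization needs >= {min_proteins} proteins, got {len(curves)}")
    run_id = curves[0].run_id
    if any(c.run_id != run_id for c in curves):
        raise ContractError("curves from multiple runs passed to derive_melt_normalization")
    x = curves[0].x_values
    ref = curves[0].reference_index
    raw_medians = np.nanmedian(_fc_matrix(curves), axis=0)

    fit = fit_ll4(x, raw_medians)
    warnings: List[str] = []
    if (not fit.converged) or fit.r_squared < MIN_MELT_FIT_R2 or np.any(
            ll4_eval(fit.params, x) <= 0):
        warnings.append("median_fit_failed_identity_factors")
        logger.warning("run %s: proteome-median sigmoid fit failed; "
                       "normalization skipped", run_id)
        return NormalizationFactors(
            run_id=run_id,
            factors=np.ones(N_CHANNELS),
            fitted_medians=raw_medians.copy(),
            raw_medians=raw_medians,
            scaling_factor=1.0,
            fit=fit,
            warnings=warnings,
        )
    fitted = ll4_eval(fit.params, x)
    scaling = 1.0 / fitted[ref]
    factors = scaling * fitted / raw_medians
    return NormalizationFactors(
        run_id=run_id,
        factors=factors,
        fitted_medians=fitted,
        raw_medians=raw_medians,
        scaling_factor=float(scaling),
        fit=fit,
        warnings=warnings,
    )


def apply_normalization(curve: FoldChangeCurve, nf: NormalizationFactors) -> FoldChangeCurve:
    """Multiply a curve by its run's per-channel factors (missing stays missing)."""
    if curve.run_id != nf.run_id:
        raise ContractError(
            f"normalization factors for run {nf.run_id!r} applied to run {curve.run_id!r}")
    return replace(curve, fold_changes=curve.fold_changes * nf.factors)


def normalize_melt_run(
    curves: Sequence[FoldChangeCurve],
    min_proteins: int = MIN_PROTEINS_FOR_NORMALIZATION,
) -> Tuple[List[FoldChangeCurve], NormalizationFactors]:
    nf = derive_melt_normalization(curves, min_proteins=min_proteins)
    return [apply_normalization(c, nf) for c in curves], nf


def normalize_itdr(
    curves: Sequence[FoldChangeCurve],
    min_proteins: int = MIN_PROTEINS_FOR_NORMALIZATION,
    mode: str = "per_channel",
) -> Tuple[List[FoldChangeCurve], NormalizationFactors]:
    """Median-to-1 normalization of an ITDR/ITTR run.

    mode="per_channel": each channel scaled so its median across proteins is
    exactly 1 (reference untouched, already 1).  mode="global": one common
    factor from the pooled non-reference median.
    """
    if len(curves) < min_proteins:
        raise DataError(
            f"ITDR normalization needs >= {min_proteins} proteins, got {len(curves)}")
    run_id = curves[0].run_id
    if any(c.run_id != run_id for c in curves):
        raise ContractError("curves from multiple runs passed to normalize_itdr")
    ref = curves[0].reference_index
    mat = _fc_matrix(curves)
    warnings: List[str] = []

    if mode == "per_channel":
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channels
            medians = np.nanmedian(mat, axis=0)
        factors = np.ones(N_CHANNELS)
        for i in range(N_CHANNELS):
            if i == ref:
                continue
            if not np.isfinite(medians[i]) or medians[i] <= 0:
                warnings.append(f"channel_{i}_all_missing_factor_1")
                logger.warning("run %s: channel %d has no usable values; factor 1",
                               run_id, i)
            else:
                factors[i] = 1.0 / medians[i]
    elif mode == "global":
        pooled = mat[:, [i for i in range(N_CHANNELS) if i != ref]]
        med = np.nanmedian(pooled)
        factors = np.full(N_CHANNELS, 1.0 / med if np.isfinite(med) and med > 0 else 1.0)
        factors[ref] = 1.0
        medians = np.nanmedian(mat, axis=0)
    else:
        raise ContractError(f"unknown ITDR normalization mode {mode!r}")

    nf = NormalizationFactors(
        run_id=run_id,
        factors=factors,
        fitted_medians=np.ones(N_CHANNELS),
        raw_medians=np.where(np.isfinite(medians), medians, np.nan),
        scaling_factor=1.0,
        warnings=warnings,
    )
    return [apply_normalization(c, nf) for c in curves], nf


def normalization_report(factors: Iterable[NormalizationFactors], path) -> None:
    """CSV report: per run raw/fitted medians, factors and scaling factor."""
    pd.concat([nf.to_frame() for nf in factors], ignore_index=True).to_csv(
        path, index=False)
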