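"""ITDR/ITTR hit selection.

The selection chain for a dose-response (or time-response) experiment:

1. *Baseline band*: pool the fold changes of all quantified proteins at the
   lowest three dose groups and take median +/- 2.5 * MAD (MAD scaled by the
   normal-consistency constant 1.4826) as the experiment-wise technical
   fluctuation band.  Fold changes at the reference channel are 1 by
   construction and carry no variance information, so they are excluded
   from the pool by default.
2. *Effect*: at least one of the highest three dose points must show a >=30%
   change beyond the band (multiplicative by default: FC >= 1.3 * upper for
   stabilization, FC <= lower / 1.3 for destabilization).
3. *Fit quality*: sigmoidal fit with R^2 > 0.8.
4. *Evidence*: at least 3 PSMs.

A protein passing all four is a stabilized/destabilized hit; its minimal
dose threshold (MDT) is the dose where the fitted curve crosses the band
edge, clipped into the measured dose range.  The AUC summary (mean excess
fold change over the log10 dose axis) supports the AUC-vs-R^2 overview plot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .curve_models import LL4Fit, ll4_eval, ll4_invert
from .errors import DataError
from .melt_normalize import FoldChangeCurve

logger = logging.getLogger(__name__)

MAD_NORMAL_CONSTANT = 1.4826


@dataclass(frozen=True)
class HitCriteria:
    """Thresholds of the selection chain (defaults are the published ones)."""

    mad_multiplier: float = 2.5
    effect_factor: float = 1.3
    effect_mode: str = "multiplicative"  # or "additive" (+/- 0.3)
    r2_min: float = 0.8
    psm_min: int = 3
    n_low: int = 3
    n_high: int = 3
    mad_constant: float = MAD_NORMAL_CONSTANT
    abundance_tolerance: float = 0.10


@dataclass(frozen=True)
class BaselineBand:
    """Pooled baseline variance band: median +/- multiplier * scaled MAD."""

    pooled_median: float
    mad: float
    lower: float
    upper: float
    n_values: int

    @property
    def degenerate(self) -> bool:
        return self.mad == 0.0


@dataclass
class HitCall:
    """Outcome of the full criteria chain for one protein in one run."""

    protein_id: str
    treatment: str
    direction: str  # stabilized | destabilized | none
    mdt: Optional[float]
    max_effect_fc: float
    r_squared: float
    psm_count: int
    pass_baseline: bool
    pass_30pct: bool
    pass_r2: bool
    pass_psm: bool
    auc: float
    replicate: int = 1
    flags: List[str] = field(default_factory=list)

    @property
    def is_hit(self) -> bool:
        return self.direction != "none"

    def as_record(self) -> dict:
        return {
            "protein_id": self.protein_id, "treatment": self.treatment,
            "direction": self.direction, "mdt": self.mdt,
            "r_squared": self.r_squared, "max_effect_fc": self.max_effect_fc,
            "auc": self.auc, "psm_count": self.psm_count,
            "pass_baseline": self.pass_baseline, "pass_30pct": self.pass_30pct,
            "pass_r2": self.pass_r2, "pass_psm": self.pass_psm,
            "flags": ";".join(self.flags),
        }


def pseudo_dose_grid(x: np.ndarray) -> np.ndarray:
    """Map zero doses to a pseudo-dose so the grid is log-scale usable.

    The pseudo-dose is (lowest nonzero x) / (largest successive ratio of the
    nonzero ladder), i.e. zero sits one ladder step below the lowest dose.
    """
    x = np.asarray(x, dtype=float)
    if np.all(x > 0):
        return x.copy()
    nz = np.unique(x[x > 0])
    if nz.size < 2:
        raise DataError("need >= 2 nonzero doses to infer a pseudo-dose")
    step = np.max(nz[1:] / nz[:-1])
    out = x.copy()
    out[x <= 0] = nz[0] / step
    return out


def baseline_band(
    curves: Sequence[FoldChangeCurve],
    n_low: int = 3,
    mad_multiplier: float = 2.5,
    mad_constant: float = MAD_NORMAL_CONSTANT,
    min_pool: int = 30,
    exclude_reference: bool = True,
) -> BaselineBand:
    """Baseline variance band from the lowest ``n_low`` dose groups.

    Pools across all proteins (and as many replicate runs as are passed in).
    By-construction reference entries (exactly 1, zero variance) are dropped
    from the pool by default.
    """
    values: List[np.ndarray] = []
    for c in curves:
        order = np.argsort(c.x_values, kind="stable")
        low_idx = order[:n_low]
        if exclude_reference:
            low_idx = low_idx[low_idx != c.reference_index]
        v = c.fold_changes[low_idx]
        values.append(v[np.isfinite(v)])
    pooled = np.concatenate(values) if values else np.empty(0)
    if pooled.size < min_pool:
        raise DataError(
            f"baseline band needs >= {min_pool} pooled values, got {pooled.size}; "
            "provide more proteins or runs")
    med = float(np.median(pooled))
    mad = float(mad_constant * np.median(np.abs(pooled - med)))
    half = mad_multiplier * mad
    return BaselineBand(pooled_median=med, mad=mad,
                        lower=med - half, upper=med + half,
                        n_values=int(pooled.size))


def auc_summary(curve: FoldChangeCurve) -> float:
    """Mean excess fold change over the log10 x axis (flat-at-1 -> 0).

    Trapezoidal integral of (fold change - 1) over log10(pseudo-dose),
    divided by the log10 span, using only the usable points.
    """
    ok = np.isfinite(curve.fold_changes)
    if ok.sum() < 2:
        return 0.0
    lx = np.log10(pseudo_dose_grid(curve.x_values))
    order = np.argsort(lx[ok], kind="stable")
    lxo = lx[ok][order]
    y = (curve.fold_changes[ok] - 1.0)[order]
    span = lxo[-1] - lxo[0]
    if span <= 0:
        return 0.0
    return float(np.trapezoid(y, lxo) / span)


def compute_mdt(
    fit: LL4Fit,
    band: BaselineBand,
    x_range: Tuple[float, float],
    direction: str,
) -> Tuple[Optional[float], List[str]]:
    """Minimal dose threshold: fitted-curve / band-edge intersection.

    Stabilized hits cross the upper band edge, destabilized the lower one.
    The crossing is clipped into [lowest nonzero dose, highest dose]; a
    curve already beyond the edge at the lowest dose is 'saturated' and
    reports the lowest dose; no crossing in range -> None.  A degenerate
    band (MAD 0) falls back to median * (1 +/- 0.01) and is flagged.
    """
    flags: List[str] = []
    if not fit.converged or fit.params is None or direction == "none":
        return None, flags
    lo, hi = float(x_range[0]), float(x_range[1])
    if band.degenerate:
        flags.append("degenerate_band")
        edge = band.pooled_median * (1.01 if direction == "stabilized" else 0.99)
    else:
        edge = band.upper if direction == "stabilized" else band.lower

    f_lo = ll4_eval(fit.params, lo)
    f_hi = ll4_eval(fit.params, hi)
    if direction == "stabilized":
        if min(f_lo, f_hi) >= edge:
            flags.append("saturated")
            return lo, flags
        if max(f_lo, f_hi) <= edge:
            return None, flags
    else:
        if max(f_lo, f_hi) <= edge:
            flags.append("saturated")
            return lo, flags
        if min(f_lo, f_hi) >= edge:
            return None, flags
    x = ll4_invert(fit.params, edge)
    if x is None or not math.isfinite(x):
        return None, flags
    return float(min(max(x, lo), hi)), flags


def call_hit(
    curve: FoldChangeCurve,
    fit: LL4Fit,
    band: BaselineBand,
    psm: int,
    criteria: HitCriteria = HitCriteria(),
) -> HitCall:
    """Apply the four-criterion chain to one normalized curve.

    Always returns a HitCall; ``direction != 'none'`` iff all four pass
    flags are true.  The call is a pure function of its inputs.
    """
    fc = curve.fold_changes
    ok = np.isfinite(fc)
    flags: List[str] = []

    pass_baseline = bool(np.any((fc[ok] < band.lower) | (fc[ok] > band.upper)))

    order = np.argsort(curve.x_values, kind="stable")
    top = [i for i in order[::-1][: criteria.n_high] if ok[i]]
    if top:
        top_fc = fc[top]
        if criteria.effect_mode == "multiplicative":
            stab_thr = criteria.effect_factor * band.upper
            destab_thr = band.lower / criteria.effect_factor
        else:  # additive interpretation of the 30% rule
            delta = criteria.effect_factor - 1.0
            stab_thr = band.upper + delta
            destab_thr = band.lower - delta
        stab = bool(np.max(top_fc) >= stab_thr)
        destab = bool(np.min(top_fc) <= destab_thr) and destab_thr > 0
        max_fc = float(top_fc[np.argmax(np.abs(np.log(np.maximum(top_fc, 1e-12))))])
    else:
        stab = destab = False
        max_fc = float("nan")
    pass_30pct = stab or destab

    pass_r2 = bool(fit.converged and fit.r_squared > criteria.r2_min)
    pass_psm = psm >= criteria.psm_min

    direction = "none"
    if pass_baseline and pass_30pct and pass_r2 and pass_psm:
        if stab and destab:
            flags.append("ambiguous_direction")
            up = abs(math.log(max(np.max(fc[top]), 1e-12)))
            down = abs(math.log(max(np.min(fc[top]), 1e-12)))
            direction = "stabilized" if up >= down else "destabilized"
        else:
            direction = "stabilized" if stab else "destabilized"

    mdt = None
    if direction != "none":
        x = pseudo_dose_grid(curve.x_values)
        nz = curve.x_values[curve.x_values > 0]
        lo = float(nz.min()) if nz.size else float(x.min())
        mdt, mdt_flags = compute_mdt(fit, band, (lo, float(x.max())), direction)
        flags.extend(mdt_flags)

    return HitCall(
        protein_id=curve.protein_id,
        treatment=curve.treatment,
        direction=direction,
        mdt=mdt,
        max_effect_fc=max_fc,
        r_squared=fit.r_squared,
        psm_count=psm,
        pass_baseline=pass_baseline,
        pass_30pct=pass_30pct,
        pass_r2=pass_r2,
        pass_psm=pass_psm,
        auc=auc_summary(curve),
        replicate=curve.replicate,
        flags=flags,
    )


def combine_replicates(calls: Sequence[HitCall]) -> Optional[HitCall]:
    """Cross-replicate hit: every technical replicate must pass, same direction.

    Returns the combined HitCall (geometric-mean MDT, mean R^2/AUC, minimum
    PSM evidence) or None when the replicate set does not support a hit.
    Proteins observed in a single replicate only are not eligible.
    """
    if len(calls) < 2:
        return None
    if any(not c.is_hit for c in calls):
        return None
    directions = {c.direction for c in calls}
    if len(directions) != 1:
        return None
    mdts = [c.mdt for c in calls if c.mdt is not None]
    mdt = float(np.exp(np.mean(np.log(mdts)))) if mdts else None
    first = calls[0]
    flags = sorted({f for c in calls for f in c.flags})
    return HitCall(
        protein_id=first.protein_id,
        treatment=first.treatment,
        direction=first.direction,
        mdt=mdt,
        max_effect_fc=float(np.mean([c.max_effect_fc for c in calls])),
        r_squared=float(np.mean([c.r_squared for c in calls])),
        psm_count=min(c.psm_count for c in calls),
        pass_baseline=True, pass_30pct=True, pass_r2=True, pass_psm=True,
        auc=float(np.mean([c.auc for c in calls])),
        replicate=0,  # 0 marks a cross-replicate consensus call
        flags=flags,
    )


@dataclass(frozen=True)
class AbundanceFlag:
    protein_id: str
    ratio: Optional[float]
    flagged: bool
    reason: str = ""


def abundance_control(
    treated: Iterable[Tuple[str, float]],
    control: Iterable[Tuple[str, float]],
    tolerance: float = 0.10,
) -> List[AbundanceFlag]:
    """37 degC abundance-change control: treated/control ratio per protein.

    Hits whose protein level itself changes more than ``tolerance`` (10%)
    during compound incubation are flagged, since a CETSA readout then
    confounds stability with expression.  Zero/missing control values are
    flagged 'unassessable'.
    """
    ctrl = dict(control)
    out: List[AbundanceFlag] = []
    for pid, t in treated:
        c = ctrl.get(pid)
        if c is None or not np.isfinite(c) or c == 0 or not np.isfinite(t):
            out.append(AbundanceFlag(pid, None, True, "unassessable"))
            continue
        ratio = t / c
        out.append(AbundanceFlag(pid, float(ratio), bool(abs(ratio - 1.0) > tolerance)))
    return out
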