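"""Four-parameter log-logistic (LL.4) model: evaluation, inversion, fitting.

The LL.4 model is the workhorse of CETSA data processing:

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with ``b`` the slope, ``c`` the lower limit, ``d`` the upper limit and ``e``
the inflection point -- the melting temperature Tm when ``x`` is temperature,
the inflection dose for isothermal dose responses, or the inflection time for
time responses.  The natural logarithm is used throughout (the drc-style
parameterization), so ``b`` is a slope on the ln-x axis.

Fitting is ordinary least squares via a damped Gauss-Newton
(Levenberg-Marquardt) iteration with box bounds enforced by projection.  The
implementation is *batched*: thousands of 10-point curves are fitted
simultaneously as stacked numpy arrays, which is what makes proteome-scale
reprocessing cheap.  ``fit_ll4`` is the single-curve convenience wrapper over
the same engine, so both paths are bit-identical.

Determinism: there is no randomness anywhere in this module.  A fixed
initializer ladder (b0 in +1, +3, -1, -3) is tried for every curve and the
start with the smallest residual sum of squares wins, ties going to the first
in ladder order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .errors import DomainError

__all__ = [
    "LL4Params",
    "LL4Fit",
    "ll4_eval",
    "ll4_invert",
    "fit_ll4",
    "fit_ll4_batch",
]

# Optimizer settings (fixed; no random restarts).
MAX_ITER = 2000
XTOL = 1e-10
FTOL = 1e-10
#: slope starting values tried for every curve, in order.
B0_LADDER = (1.0, 3.0, -1.0, -3.0)
#: hard slope bound; fold-change data never supports steeper transitions.
B_MAX = 50.0
#: lower bound for c and d (fold changes are near-1, mild undershoot allowed).
CD_FLOOR = -0.5
#: minimum usable points for a fit attempt.
MIN_POINTS = 5


@dataclass(frozen=True)
class LL4Params:
    """Parameters of the four-parameter log-logistic model.

    Attributes
    ----------
    b : float
        Slope on the ln-x axis; positive slopes give curves decreasing in x.
    c : float
        Lower limit (the b>0 high-x asymptote).
    d : float
        Upper limit.
    e : float
        Inflection point in the units of x (Tm, inflection dose, or time);
        must be positive since the model lives on ln x.
    """

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not (self.e > 0):
            raise DomainError(f"inflection e must be > 0, got {self.e!r}")
        if self.b == 0:
            raise DomainError("slope b must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e], dtype=float)


@dataclass(frozen=True)
class LL4Fit:
    """Result of a least-squares LL.4 fit.

    ``r_squared`` is 1 - SS_res/SS_tot with SS_tot taken about the observed
    mean; for SS_tot == 0 (constant data) it is defined as 0.  A fit with
    ``converged=False`` must be treated as failed by downstream hit criteria.
    """

    params: Optional[LL4Params]
    r_squared: float
    n_points: int
    converged: bool
    residual_sum_squares: float

    @property
    def tm(self) -> Optional[float]:
        """Inflection point (Tm for melts), or None for a failed fit."""
        return self.params.e if self.params is not None else None


def ll4_eval(params: LL4Params, x):
    """Evaluate the LL.4 model at ``x`` (scalar or array, all > 0)."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0) or not np.all(np.isfinite(x_arr)):
        raise DomainError("ll4_eval requires finite x > 0")
    t = params.b * (np.log(x_arr) - np.log(params.e))
    val = params.c + (params.d - params.c) * expit(-t)
    return float(val) if np.isscalar(x) or x_arr.ndim == 0 else val


def ll4_invert(params: LL4Params, y: float) -> Optional[float]:
    """Solve f(x) = y for x; None when y is outside the open range (c, d).

    Closed form: x = e * exp((1/b) * ln((d - y)/(y - c))).  The model is
    strictly monotone in x, so the solution is unique when it exists.
    """
    lo, hi = min(params.c, params.d), max(params.c, params.d)
    if not (lo < y < hi):
        return None
    ratio = (params.d - y) / (y - params.c)
    if ratio <= 0:  # numerically at an asymptote
        return None
    return float(params.e * np.exp(np.log(ratio) / params.b))


# ---------------------------------------------------------------------------
# Batched Levenberg-Marquardt engine.
#
# Internal parameterization theta = (b, c, d, le) with le = ln e: the model
# then reads f = c + (d-c)*sigmoid(-b*(lx - le)) on lx = ln x, which keeps
# the Jacobian well scaled across temperature and dose axes alike.
# ---------------------------------------------------------------------------


def _profile(theta: np.ndarray, lx: np.ndarray):
    """Model values and Jacobian for stacked parameter rows.

    theta: (M, 4) rows (b, c, d, le);  lx: (n,) log x grid.
    Returns f (M, n) and J (M, n, 4).
    """
    b = theta[:, 0:1]
    c = theta[:, 1:2]
    d = theta[:, 2:3]
    le = theta[:, 3:4]
    t = b * (lx[None, :] - le)
    s = expit(-t)                    # in (0, 1)
    f = c + (d - c) * s
    sd = s * (1.0 - s)
    J = np.empty(theta.shape[:1] + lx.shape + (4,), dtype=float)
    J[:, :, 0] = -(d - c) * sd * (lx[None, :] - le)
    J[:, :, 1] = 1.0 - s
    J[:, :, 2] = s
    J[:, :, 3] = (d - c) * sd * b
    return f, J


def _lm_minimize(lx, Y, W, theta0, lo, hi, max_iter=MAX_ITER):
    """Projected Levenberg-Marquardt for M independent curves at once.

    Y, W: (M, n) observations and 0/1 usability weights; theta0: (M, 4)
    starts; lo/hi: (M, 4) box bounds.  Returns (theta, ssr, ok) where ok
    flags numerically sound solutions.
    """
    M = theta0.shape[0]
    theta = np.clip(theta0, lo, hi)
    f, J = _profile(theta, lx)
    r = np.where(W > 0, f - Y, 0.0)
    ssr = np.einsum("mi,mi->m", r, r)
    ok = np.isfinite(ssr)
    ssr = np.where(ok, ssr, np.inf)
    lam = np.full(M, 1e-3)
    active = ok.copy()
    eye4 = np.arange(4)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ja = J[idx] * W[idx][:, :, None]
        ra = r[idx]
        JTJ = np.einsum("mik,mil->mkl", Ja, Ja)
        g = np.einsum("mik,mi->mk", Ja, ra)

        # Gradient already negligible -> done (flat/degenerate curves).
        gmax = np.abs(g).max(axis=1)
        done_now = gmax < 1e-13 * (1.0 + ssr[idx])
        if done_now.any():
            active[idx[done_now]] = False
            keep = ~done_now
            if not keep.any():
                continue
            idx, JTJ, g = idx[keep], JTJ[keep], g[keep]

        diag = JTJ[:, eye4, eye4].copy()
        np.maximum(diag, 1e-12, out=diag)
        A = JTJ.copy()
        A[:, eye4, eye4] += lam[idx] [:, None] * diag + 1e-14
        try:
            delta = np.linalg.solve(A, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            A[:, eye4, eye4] += 1e-6
            delta = np.linalg.solve(A, -g[..., None])[..., 0]

        trial = np.clip(theta[idx] + delta, lo[idx], hi[idx])
        step = trial - theta[idx]
        ft, Jt = _profile(trial, lx)
        rt = np.where(W[idx] > 0, ft - Y[idx], 0.0)
        ssr_t = np.einsum("mi,mi->m", rt, rt)
        better = np.isfinite(ssr_t) & (ssr_t < ssr[idx])

        acc = idx[better]
        if acc.size:
            small_step = np.abs(step[better]).max(axis=1) < XTOL * (
                1.0 + np.abs(trial[better]).max(axis=1)
            )
            small_gain = (ssr[acc] - ssr_t[better]) <= FTOL * np.maximum(
                ssr[acc], 1e-300
            )
            theta[acc] = trial[better]
            f[acc], J[acc] = ft[better], Jt[better]
            r[acc] = rt[better]
            ssr[acc] = ssr_t[better]
            lam[acc] = np.maximum(lam[acc] / 3.0, 1e-10)
            active[acc[small_step | small_gain]] = False

        rej = idx[~better]
        if rej.size:
            lam[rej] *= 10.0
            active[rej[lam[rej] > 1e8]] = False  # stalled at a (bounded) optimum

    ok &= np.isfinite(ssr) & np.all(np.isfinite(theta), axis=1)
    return theta, ssr, ok


def _initial_e(lx: np.ndarray, y: np.ndarray, ymid: float) -> float:
    """ln e start: linear interpolation of the first ymid crossing, else the
    point closest to ymid."""
    dy = y - ymid
    for i in range(len(y) - 1):
        if dy[i] == 0.0:
            return lx[i]
        if dy[i] * dy[i + 1] <= 0.0 and y[i + 1] != y[i]:
            frac = (ymid - y[i]) / (y[i + 1] - y[i])
            return lx[i] + frac * (lx[i + 1] - lx[i])
    return lx[int(np.argmin(np.abs(dy)))]


def _failed_fit(n: int) -> LL4Fit:
    return LL4Fit(params=None, r_squared=0.0, n_points=n, converged=False,
                  residual_sum_squares=float("nan"))


def fit_ll4_batch(
    x: Sequence[float],
    Y: np.ndarray,
    init: Optional[LL4Params] = None,
) -> list:
    """Fit many curves sharing one x grid; NaNs in ``Y`` mark missing points.

    Parameters
    ----------
    x : (n,) positive dose/temperature/time grid.
    Y : (N, n) observations, NaN = missing.
    init : optional common warm start prepended to the initializer ladder.

    Returns
    -------
    list of LL4Fit, one per row of Y.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DomainError("fit_ll4 requires finite x > 0 (map zero doses to a pseudo-dose first)")
    N, n = Y.shape
    if x.shape != (n,):
        raise DomainError("x and Y shapes disagree")

    lx = np.log(x)
    W = np.isfinite(Y).astype(float)
    npts = W.sum(axis=1).astype(int)
    fittable = npts >= MIN_POINTS

    # Bounds on (b, c, d, le): scale-aware per curve in c/d.
    le_lo, le_hi = np.log(x.min() / 10.0), np.log(x.max() * 10.0)

    fits: list = [None] * N
    rows = np.flatnonzero(fittable)
    if rows.size == 0:
        return [_failed_fit(int(k)) for k in npts]

    n_starts = len(B0_LADDER) + (1 if init is not None else 0)
    theta0 = np.empty((rows.size, n_starts, 4))
    lo = np.empty((rows.size, 4))
    hi = np.empty((rows.size, 4))
    for j, i in enumerate(rows):
        m = W[i] > 0
        yi = Y[i, m]
        c0, d0 = float(yi.min()), float(yi.max())
        e0 = _initial_e(lx[m], yi, 0.5 * (c0 + d0))
        starts = []
        if init is not None:
            starts.append([init.b, init.c, init.d, np.log(init.e)])
        for b0 in B0_LADDER:
            starts.append([b0, c0, d0, e0])
        theta0[j] = starts
        cd_hi = 3.0 * max(d0, 1e-6)
        lo[j] = [-B_MAX, CD_FLOOR, CD_FLOOR, le_lo]
        hi[j] = [B_MAX, cd_hi, cd_hi, le_hi]

    M = rows.size * n_starts
    theta, ssr, ok = _lm_minimize(
        lx,
        np.repeat(Y[rows], n_starts, axis=0),
        np.repeat(W[rows], n_starts, axis=0),
        theta0.reshape(M, 4),
        np.repeat(lo, n_starts, axis=0),
        np.repeat(hi, n_starts, axis=0),
    )
    theta = theta.reshape(rows.size, n_starts, 4)
    ssr = np.where(ok, ssr, np.inf).reshape(rows.size, n_starts)
    best = np.argmin(ssr, axis=1)  # ties -> first in ladder order

    for j, i in enumerate(rows):
        k = best[j]
        if not np.isfinite(ssr[j, k]):
            fits[i] = _failed_fit(int(npts[i]))
            continue
        b, c, d, le = theta[j, k]
        if b == 0.0:
            b = np.finfo(float).tiny  # projection artefact; keep params valid
        m = W[i] > 0
        yi = Y[i, m]
        sstot = float(np.sum((yi - yi.mean()) ** 2))
        rss = float(ssr[j, k])
        r2 = 0.0 if sstot <= 1e-300 else 1.0 - rss / sstot
        fits[i] = LL4Fit(
            params=LL4Params(b=float(b), c=float(c), d=float(d), e=float(np.exp(le))),
            r_squared=float(r2),
            n_points=int(npts[i]),
            converged=True,
            residual_sum_squares=rss,
        )

    for i in np.flatnonzero(~fittable):
        fits[i] = _failed_fit(int(npts[i]))
    return fits


def fit_ll4(x, y, init: Optional[LL4Params] = None) -> LL4Fit:
    """Least-squares LL.4 fit of a single curve (NaN = missing point)."""
    return fit_ll4_batch(x, np.asarray(y, dtype=float)[None, :], init=init)[0]
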