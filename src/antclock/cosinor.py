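"""Fixed-period cosinor fitting for circadian expression series.

The single-component cosinor model is

    y(t) = M + A * cos(2*pi*(t - phi) / tau)

with mesor M (rhythm-adjusted mean), amplitude A >= 0, acrophase phi (hour of
peak) and period tau fixed at 24 h for entrained light:dark data.  Two fitting
routes are provided:

``fit_ls``
    The closed-form least-squares solution obtained by regressing y on
    {1, cos(2*pi*t/24), sin(2*pi*t/24)}.  This is the exact optimum and serves
    as the oracle for the stochastic route.

``fit_mc``
    A seeded Monte-Carlo random search that scores candidate parameter sets by
    R^2 and averages the top-k best, mirroring how rhythm screens built on
    mass random simulation report their fit statistics.  With ``search="phase"``
    (default) candidates are random acrophases with mesor and amplitude set by
    conditional least squares; ``search="box"`` draws (M, A, phi) jointly from
    a data-driven box, which needs on the order of 10^7 draws before the top-k
    average approaches the optimum (see docs/methods.md).

Goodness of fit is summarized by R^2 and the small-sample adjusted
R^2_adj = 1 - (1 - R^2)(n - 1)/(n - k - 1) with k = 2 trigonometric
regressors, and significance by a seeded permutation test of R^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CosinorParams",
    "CosinorFit",
    "cosine_predict",
    "fit_ls",
    "fit_mc",
    "adjusted_r2",
    "fit_pvalue",
    "cosinor_ftest",
    "peak_zt",
]

DEFAULT_PERIOD = 24.0
#: Sampling grid of the standard one-day design: 7 timepoints every 4 h.
DEFAULT_ZT_GRID = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0)


@dataclass(frozen=True)
class CosinorParams:
    """Parameters of a fixed-period cosine: y(t) = M + A cos(2pi (t-phi)/tau)."""

    mesor: float
    amplitude: float
    acrophase: float
    period: float = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 <= self.acrophase < self.period):
            object.__setattr__(self, "acrophase", self.acrophase % self.period)
        if self.period <= 0:
            raise ValueError("period must be > 0")


@dataclass(frozen=True)
class CosinorFit:
    """A fitted cosinor with goodness-of-fit and phase summaries.

    ``amplitude_pt`` is the peak-minus-trough excursion of the fitted curve
    (2A for a fixed-period cosine); ``peak_zt_grid`` is the sampled ZT closest
    (circularly) to the fitted acrophase, NaN when the fit is flat.
    """

    params: CosinorParams
    r2: float
    r2_adj: float
    amplitude_pt: float
    peak_zt_continuous: float
    peak_zt_grid: float
    method: str
    n: int
    p_value: float | None = None
    n_sims: int | None = None
    top_k: int | None = None
    seed: int | None = None


def cosine_predict(params: CosinorParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the cosinor curve at time(s) ``t`` (hours)."""
    t = np.asarray(t, float)
    out = params.mesor + params.amplitude * np.cos(
        2 * np.pi * (t - params.acrophase) / params.period
    )
    return float(out) if out.ndim == 0 else out


def _design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2 * np.pi * t / period
    return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])


def _validate_series(zts: Sequence[float], y: Sequence[float], period: float):
    t = np.asarray(zts, float)
    yv = np.asarray(y, float)
    if t.shape != yv.shape or t.ndim != 1:
        raise ValueError("zts and y must be 1-d sequences of equal length")
    if t.size < 4:
        raise ValueError("cosinor fit requires at least 4 timepoints")
    if len(np.unique(np.round(t % period, 9))) < 3:
        raise ValueError("cosinor fit requires >= 3 distinct timepoints modulo the period")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(yv))):
        raise ValueError("zts and y must be finite")
    return t, yv


def _grid_peak(phi: float, zts: np.ndarray, period: float) -> float:
    """Sampled ZT (mod period) circularly nearest to phi; ties -> earlier ZT."""
    grid = np.unique(np.sort(np.asarray(zts, float) % period))
    d = np.abs((grid - phi + period / 2) % period - period / 2)
    return float(grid[int(np.argmin(d))])  # argmin takes first minimum = earlier ZT


def _fit_from_params(
    params: CosinorParams,
    t: np.ndarray,
    yv: np.ndarray,
    r2: float,
    method: str,
    **extra,
) -> CosinorFit:
    n = t.size
    return CosinorFit(
        params=params,
        r2=r2,
        r2_adj=adjusted_r2(r2, n, 2),
        amplitude_pt=2 * params.amplitude,
        peak_zt_continuous=(params.acrophase if params.amplitude > 0 else math.nan),
        peak_zt_grid=(
            _grid_peak(params.acrophase, t, params.period)
            if params.amplitude > 0
            else math.nan
        ),
        method=method,
        n=n,
        **extra,
    )


def fit_ls(
    zts: Sequence[float], y: Sequence[float], period: float = DEFAULT_PERIOD
) -> CosinorFit:
    """Closed-form least-squares cosinor fit.

    Regresses y on the intercept and the cosine/sine pair at the fixed period
    and converts the linear coefficients to polar form:
    A = hypot(beta_c, beta_s), phi = (period/2pi) atan2(beta_s, beta_c).
    A constant series has no variance to explain: returns A = 0, R^2 = 0 with
    a warning.
    """
    t, yv = _validate_series(zts, y, period)
    X = _design(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear cosinor design (degenerate ZT grid)")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        warnings.warn(
            "constant series: R^2 defined as 0", RuntimeWarning, stacklevel=2
        )
        r2 = 0.0
        params = CosinorParams(float(yv[0]), 0.0, 0.0, period)
        return _fit_from_params(params, t, yv, r2, "ls")
    r2 = 1.0 - float(resid @ resid) / sst
    amplitude = float(np.hypot(beta[1], beta[2]))
    acrophase = float((period / (2 * np.pi)) * np.arctan2(beta[2], beta[1]) % period)
    params = CosinorParams(float(beta[0]), amplitude, acrophase, period)
    return _fit_from_params(params, t, yv, r2, "ls")


def _r2_of_candidates(
    pred: np.ndarray, yv: np.ndarray, sst: float
) -> np.ndarray:
    sse = np.sum((pred - yv[None, :]) ** 2, axis=1)
    return 1.0 - sse / sst


def _circular_mean(phi: np.ndarray, period: float) -> float:
    ang = 2 * np.pi * phi / period
    return float((period / (2 * np.pi)) * np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) % period)


def fit_mc(
    zts: Sequence[float],
    y: Sequence[float],
    n_sims: int = 100_000,
    top_k: int = 400,
    seed: int = 0,
    search: str = "phase",
    period: float = DEFAULT_PERIOD,
) -> CosinorFit:
    """Monte-Carlo random-search cosinor fit.

    Draws ``n_sims`` candidate parameter sets, scores each by R^2 against the
    observed series, and averages the ``top_k`` best: arithmetic mean for
    R^2, amplitude and mesor, circular mean for the acrophase.  Deterministic
    given ``seed``.

    search="phase"
        Candidates are uniform random acrophases; mesor and amplitude are the
        conditional least-squares solution given each acrophase (amplitude
        clamped at 0).  The top-k average converges to the closed-form
        optimum already at moderate n_sims.
    search="box"
        Candidates draw (M, A, phi) jointly and uniformly from the data-driven
        box M in [min y, max y], A in [0, max y - min y], phi in [0, period).
        Faithful to a pure random search but needs very large n_sims (~1e7)
        for the top-k average to be unbiased.
    """
    if top_k < 1 or n_sims < top_k:
        raise ValueError("need n_sims >= top_k >= 1")
    if search not in ("phase", "box"):
        raise ValueError(f"unknown search mode {search!r}")
    t, yv = _validate_series(zts, y, period)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        warnings.warn("constant series: R^2 defined as 0", RuntimeWarning, stacklevel=2)
        params = CosinorParams(float(yv[0]), 0.0, 0.0, period)
        return _fit_from_params(
            params, t, yv, 0.0, "mc", n_sims=n_sims, top_k=top_k, seed=seed
        )

    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, period, n_sims)
    w = 2 * np.pi / period
    cosmat = np.cos(w * (t[None, :] - phi[:, None]))  # n_sims x n

    if search == "box":
        M = rng.uniform(yv.min(), yv.max(), n_sims)
        A = rng.uniform(0.0, yv.max() - yv.min(), n_sims)
    else:
        # conditional LS of y on {1, cos(w(t - phi))} for each candidate phi
        n = t.size
        c_mean = cosmat.mean(axis=1)
        c_center = cosmat - c_mean[:, None]
        denom = np.sum(c_center**2, axis=1)
        num = c_center @ (yv - yv.mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(denom > 0, num / denom, 0.0)
        # negative amplitude = same curve with phase shifted half a period;
        # clamp at 0 so the candidate stays in the declared box
        A = np.clip(A, 0.0, None)
        M = yv.mean() - A * c_mean

    pred = M[:, None] + A[:, None] * cosmat
    r2 = _r2_of_candidates(pred, yv, sst)
    top = np.argpartition(-r2, top_k - 1)[:top_k]
    params = CosinorParams(
        float(M[top].mean()),
        float(A[top].mean()),
        _circular_mean(phi[top], period),
        period,
    )
    return _fit_from_params(
        params,
        t,
        yv,
        float(r2[top].mean()),
        "mc",
        n_sims=n_sims,
        top_k=top_k,
        seed=seed,
    )


def adjusted_r2(r2: float, n: int, k: int = 2) -> float:
    """Small-sample adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - k - 1).

    ``k`` counts the trigonometric regressors (2 for a single-component
    cosinor); with the 7-timepoint day design n = 7.  Negative values signal
    a fit worse than the parameter count warrants.
    """
    if n <= k + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n} <= k+1={k + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _perm_r2(t: np.ndarray, Y: np.ndarray, period: float) -> np.ndarray:
    """R^2 of the LS cosinor fit for each column of Y (vectorized)."""
    X = _design(t, period)
    beta = np.linalg.pinv(X) @ Y
    resid = Y - X @ beta
    sst = np.sum((Y - Y.mean(axis=0)[None, :]) ** 2, axis=0)
    sse = np.sum(resid**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    return r2


def fit_pvalue(
    zts: Sequence[float],
    y: Sequence[float],
    observed_r2: float,
    n_perm: int = 999,
    seed: int = 0,
    period: float = DEFAULT_PERIOD,
) -> float:
    """Permutation p-value for the cosinor fit quality.

    Shuffles the series over the sampled timepoints ``n_perm`` times, refits
    by least squares, and reports the add-one estimator
    p = (1 + #{permutation R^2 >= observed R^2}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm + 1).  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t, yv = _validate_series(zts, y, period)
    rng = np.random.default_rng(seed)
    perms = np.empty((t.size, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(yv)
    r2 = _perm_r2(t, perms, period)
    # tolerance keeps exact ties (e.g. identity permutation) counted as >=
    n_ge = int(np.sum(r2 >= observed_r2 - 1e-12))
    return (1 + n_ge) / (n_perm + 1)


def cosinor_ftest(
    zts: Sequence[float], y: Sequence[float], period: float = DEFAULT_PERIOD
) -> float:
    """Parametric alternative: F-test of the cosine/sine pair vs a flat model."""
    from scipy import stats

    t, yv = _validate_series(zts, y, period)
    fit = fit_ls(t, yv, period)
    n, k = t.size, 2
    if fit.r2 >= 1.0:
        return 0.0
    f = (fit.r2 / k) / ((1 - fit.r2) / (n - k - 1))
    return float(stats.f.sf(f, k, n - k - 1))


def peak_zt(
    fit: CosinorFit, zts: Sequence[float] | None = None
) -> tuple[float, float]:
    """(continuous peak hour, nearest sampled ZT) of a fitted cosinor.

    The continuous peak is the acrophase mod the period; the grid peak is the
    sampled ZT (mod period) with the smallest circular distance to it, ties
    broken toward the earlier ZT.  A flat fit (A = 0) has no peak: both
    entries are NaN.
    """
    if fit.params.amplitude == 0:
        return (math.nan, math.nan)
    phi = fit.params.acrophase % fit.params.period
    if zts is None:
        return (phi, fit.peak_zt_grid)
    return (phi, _grid_peak(phi, np.asarray(zts, float), fit.params.period))
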