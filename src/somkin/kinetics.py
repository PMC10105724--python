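"""Multi-pool first-order SOM decomposition kinetics.

Bulk soil organic matter is modelled as ``n`` parallel pools, each decaying
exponentially at its own reference rate.  The remaining substrate at time *t* is

    S(t) = S(0) * sum_i f_i * exp(-k_i * t),        sum_i f_i = 1

with pool fractions ``f_i`` and reference decomposition rates ``k_i`` (d^-1),
ordered fast -> slow (k_1 > k_2 > k_3).  Cumulative CO2-C release and the
instantaneous mineralization flux follow by mass balance:

    R_cum(t) = S(0) * (1 - sum_i f_i * exp(-k_i t))
    R(t)     = S(0) * sum_i k_i f_i * exp(-k_i t)

Fitting an observed incubation series is a constrained nonlinear least-squares
problem; it is solved here with damped Gauss-Newton (Levenberg-Marquardt) in a
transformed, unconstrained parameter space, with deterministic multi-start over
a log-spaced rate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PoolKinetics",
    "IncubationSeries",
    "FitResult",
    "MultiPoolKineticsModel",
    "remaining_substrate",
    "cumulative_release",
    "flux_rate",
    "fit_first_order",
]

_K_LOWER = 1e-9  # rate floor (d^-1) used as the "at lower bound" sentinel


@dataclass(frozen=True)
class PoolKinetics:
    """Parameters of an ``n``-pool first-order decomposition model.

    Parameters
    ----------
    f : array-like
        Initial pool fractions, in [0, 1], summing to 1.
    k : array-like
        Reference decomposition rates in d^-1, strictly descending
        (fast pool first).  Zero rates are allowed only for explicitly
        degenerate (non-decaying) pools.
    s0 : float
        Initial substrate stock, mg C g^-1 soil; must be positive.
    """

    f: np.ndarray
    k: np.ndarray
    s0: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "k", k)
        if f.shape != k.shape or f.ndim != 1:
            raise ValueError("f and k must be 1-D vectors of equal length")
        if not 1 <= f.size <= 3:
            raise ValueError("supported pool counts are 1, 2 or 3")
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("pool fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("pool fractions must sum to 1")
        if np.any(k < 0):
            raise ValueError("decomposition rates must be non-negative")
        if np.any(np.diff(k) >= 0) and k.size > 1:
            raise ValueError("rates must be strictly descending (fast pool first)")
        if not self.s0 > 0:
            raise ValueError("initial substrate s0 must be positive")

    @property
    def n_pools(self) -> int:
        return int(self.f.size)


@dataclass
class IncubationSeries:
    """An incubation CO2-C release time series.

    ``times`` are days since incubation start (strictly increasing, >= 0);
    ``cumulative`` is cumulative C release in mg C g^-1 soil.  ``flux`` is the
    optional instantaneous rate.  ``meta`` carries the measured-variable tag,
    incubation temperature (degC), moisture (% WHC) and duration (d).
    """

    times: np.ndarray
    cumulative: np.ndarray
    flux: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.times.shape != self.cumulative.shape:
            raise ValueError("times and cumulative must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(self.cumulative < 0):
            raise ValueError("cumulative release must be non-negative")
        if self.flux is not None:
            self.flux = np.asarray(self.flux, dtype=float)
            if self.flux.shape != self.times.shape:
                raise ValueError("flux must match times in length")

    @property
    def duration(self) -> float:
        return float(self.meta.get("duration", self.times[-1]))


@dataclass
class FitResult:
    """Outcome of a constrained multi-pool NLS fit."""

    params: PoolKinetics
    rss: float
    r2: float
    rmse: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    n_starts_used: int
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def remaining_substrate(params: PoolKinetics, t):
    """Substrate remaining at time ``t`` (mg C g^-1 soil)."""
    t = _check_t(t)
    out = params.s0 * np.exp(-np.multiply.outer(t, params.k)) @ params.f
    return out if out.ndim else float(out)


def cumulative_release(params: PoolKinetics, t):
    """Cumulative C release at time ``t``; remaining + cumulative == s0."""
    t = _check_t(t)
    out = params.s0 * (1.0 - np.exp(-np.multiply.outer(t, params.k)) @ params.f)
    return out if out.ndim else float(out)


def flux_rate(params: PoolKinetics, t):
    """Instantaneous mineralization rate dR_cum/dt (mg C g^-1 soil d^-1)."""
    t = _check_t(t)
    out = params.s0 * np.exp(-np.multiply.outer(t, params.k)) @ (params.k * params.f)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# unconstrained reparameterization
#
# rates:     log k_1 = a_0;  log k_{i+1} = log k_i - softplus(a_{i+1})
#            (cumulative softplus gaps keep k strictly descending and positive)
# fractions: stick-breaking on logits b_i
# s0:        log-parameter when fitted
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


def _theta_to_params(theta, n_pools, s0_fixed):
    logk = np.empty(n_pools)
    logk[0] = theta[0]
    for i in range(1, n_pools):
        logk[i] = logk[i - 1] - _softplus(theta[i]) - 1e-8
    # clamp to a physically meaningless but finite range so intermediate
    # optimizer excursions cannot overflow
    k = np.exp(np.clip(logk, -60.0, 10.0))
    f = np.empty(n_pools)
    rem = 1.0
    for i in range(n_pools - 1):
        f[i] = rem * _sigmoid(theta[n_pools + i])
        rem -= f[i]
    f[-1] = rem
    s0 = s0_fixed if s0_fixed is not None else float(np.exp(theta[-1]))
    return f, k, s0


def _params_to_theta(f, k, s0, s0_fixed):
    n = len(k)
    theta = [np.log(k[0])]
    for i in range(1, n):
        gap = max(np.log(k[i - 1]) - np.log(k[i]), 1e-6)
        theta.append(float(np.log(np.expm1(gap))))
    rem = 1.0
    for i in range(n - 1):
        fi = min(max(f[i], 1e-6), rem - 1e-6)
        p = fi / rem
        theta.append(float(np.log(p / (1 - p))))
        rem -= fi
    if s0_fixed is None:
        theta.append(float(np.log(s0)))
    return np.array(theta)


def _start_grid(n_pools, n_starts, k_lo=1e-6, k_hi=1.0):
    """Deterministic multi-start points: descending rate combinations from a
    log-spaced grid, fractions at the simplex centroid."""
    if n_pools == 1:
        ks = np.geomspace(k_lo, k_hi, n_starts)
        return [np.array([k]) for k in ks]
    # choose grid size so the number of descending combinations >= n_starts
    from itertools import combinations

    m = n_pools
    while True:
        grid = np.geomspace(k_lo, k_hi, m)
        combos = list(combinations(range(m), n_pools))
        if len(combos) >= n_starts or m > 24:
            break
        m += 1
    # spread selection evenly over the combination list
    idx = np.unique(np.linspace(0, len(combos) - 1, n_starts).round().astype(int))
    starts = []
    for j in idx:
        sel = combos[j]
        starts.append(grid[list(sel)][::-1].copy())  # descending
    return starts


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class MultiPoolKineticsModel:
    """Constrained NLS fitter for 1/2/3-pool first-order decomposition models.

    scikit-learn style: ``fit(t, y)`` estimates pool fractions, rates and
    (optionally) the initial stock from a cumulative-release (default) or flux
    series; fitted values live in trailing-underscore attributes.

    Parameters
    ----------
    n_pools : {1, 2, 3}
        Number of parallel SOM pools.
    target : {"cumulative", "flux"}
        Which observable the residuals are formed on.
    s0 : float or None
        Initial substrate stock.  Fixed when given; fitted otherwise.
    n_starts : int
        Multi-start count over the log-spaced rate grid (deterministic).
    max_iter : int
        Iteration cap per start.
    tol : float
        Relative RSS-change convergence tolerance.
    """

    def __init__(self, n_pools=2, target="cumulative", s0=None, n_starts=24,
                 max_iter=500, tol=1e-10):
        self.n_pools = n_pools
        self.target = target
        self.s0 = s0
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("n_pools", "target", "s0", "n_starts", "max_iter", "tol")}

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core ---------------------------------------------------------------

    def fit(self, t, y):
        """Fit the model to times ``t`` (d) and observations ``y``.

        ``y`` is cumulative release (mg C g^-1 soil) unless
        ``target="flux"``.
        """
        if self.n_pools not in (1, 2, 3):
            raise ValueError("n_pools must be 1, 2 or 3")
        if self.target not in ("cumulative", "flux"):
            raise ValueError("target must be 'cumulative' or 'flux'")
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:  # sklearn-style X
            t = t.ravel()
        n = t.size
        if n < 2 * self.n_pools + 1:
            raise ValueError(
                f"need at least {2 * self.n_pools + 1} observations "
                f"for a {self.n_pools}-pool fit")

        flags = []
        if self.target == "cumulative":
            if np.all(y == 0):
                flags.append("degenerate_input:all_zero")
            elif np.any(np.diff(y) < 0):
                flags.append("degenerate_input:non_monotone")

        s0_fixed = self.s0
        fit_s0 = s0_fixed is None
        # initial stock guess: assume roughly half the stock respired by the end
        s0_init = max(2.0 * y.max(), 1e-6) if self.target == "cumulative" else \
            max(y[0] * 50.0, 1e-6)

        def model(theta):
            f, k, s0 = _theta_to_params(theta, self.n_pools, s0_fixed)
            e = np.exp(-np.multiply.outer(t, k))
            if self.target == "cumulative":
                return s0 * (1.0 - e @ f)
            return s0 * (e @ (k * f))

        def resid(theta):
            return model(theta) - y

        tss = float(np.sum((y - y.mean()) ** 2))
        best = None
        n_used = 0
        f0 = np.full(self.n_pools, 1.0 / self.n_pools)
        for k_start in _start_grid(self.n_pools, self.n_starts):
            n_used += 1
            theta0 = _params_to_theta(f0, k_start, s0_init, s0_fixed)
            try:
                sol = least_squares(
                    resid, theta0, method="lm",
                    max_nfev=self.max_iter * (len(theta0) + 1),
                    ftol=self.tol, xtol=1e-14, gtol=1e-14)
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
            # early exit on an essentially perfect fit
            if rss <= max(1e-20, 1e-16 * max(tss, 1.0)):
                break

        if best is None:
            raise RuntimeError(
                f"no start converged for n_pools={self.n_pools}; "
                f"{n_used} starts attempted")

        rss, sol = best
        f, k, s0 = _theta_to_params(sol.x, self.n_pools, s0_fixed)
        if np.any(k < _K_LOWER):
            flags.append("k_at_lower_bound")
            k = np.maximum(k, _K_LOWER)
            k = _strictly_descending(k)
        dur = t[-1]
        if dur * k[-1] < 0.05:
            flags.append("identifiability:slow_pool_underexpressed")

        order = np.argsort(-k)
        params = PoolKinetics(f=f[order], k=k[order], s0=s0)

        rmse = float(np.sqrt(rss / n))
        r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
        p = len(sol.x)
        if rss > 0:
            aic = n * np.log(rss / n) + 2 * p
            bic = n * np.log(rss / n) + p * np.log(n)
        else:
            aic = bic = -np.inf
            warnings.warn("zero residual sum of squares; AIC/BIC are -inf")

        self.params_ = params
        self.f_, self.k_, self.s0_ = params.f, params.k, params.s0
        self.result_ = FitResult(
            params=params, rss=rss, r2=float(r2), rmse=rmse, aic=float(aic),
            bic=float(bic), n_obs=n, converged=bool(sol.success),
            n_starts_used=n_used, flags=flags)
        return self

    def predict(self, t):
        """Model value (cumulative or flux, matching ``target``) at ``t``."""
        t = np.asarray(t, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        if self.target == "cumulative":
            return cumulative_release(self.params_, t)
        return flux_rate(self.params_, t)


def _strictly_descending(k):
    k = k.copy()
    for i in range(1, len(k)):
        if k[i] >= k[i - 1]:
            k[i] = k[i - 1] * (1 - 1e-9)
    return k


def fit_first_order(series: IncubationSeries, n_pools: int,
                    target: str = "cumulative", s0: float | None = None,
                    n_starts: int = 24) -> FitResult:
    """Fit an ``n_pools``-pool first-order model to an incubation series.

    Thin functional wrapper over :class:`MultiPoolKineticsModel`.
    """
    y = series.cumulative if target == "cumulative" else series.flux
    if y is None:
        raise ValueError("series has no flux data")
    m = MultiPoolKineticsModel(n_pools=n_pools, target=target, s0=s0,
                               n_starts=n_starts)
    m.fit(series.times, y)
    return m.result_


def fit_all_pool_counts(series: IncubationSeries, **kw):
    """Fit 1-, 2- and 3-pool models to one series; returns {n_pools: FitResult}."""
    return {n: fit_first_order(series, n, **kw) for n in (1, 2, 3)}
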