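"""Linear-nonlinear (LN) tuning model and the tabulated "oracle" comparator.

The LN model predicts a neuron's mean response to stimulus ``i`` as

    r_i = a * f( sum_j w_j x_ij + h )

with one weight ``w_j`` per stimulus element, a baseline drive ``h``, an
amplitude ``a >= 0``, and the static nonlinearity

    f(x) = (x/2) * (1 + erf(x / sqrt(2))) + exp(-x**2 / 2) / sqrt(2*pi)

i.e. a rectified-linear function smoothed by a unit Gaussian — equivalently
the expectation E[max(0, x + Z)] with Z ~ N(0, 1).  Because ``f`` is convex
and strictly increasing, a strongly negative ``h`` (a high threshold) makes
the model respond supra-linearly to specific element combinations while
staying nearly silent to each element alone: the generative account of
combination-selective neurons.

For an ``n``-element space the LN model has ``n + 2`` free parameters
(7 for the five-whisker experiment); the oracle has one parameter per
condition (31), copying the training tuning curve verbatim, and serves as a
noise ceiling: with trial noise present the 7-parameter model can beat it
on held-out data whenever the LN form holds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special, stats


@dataclass(frozen=True)
class LNParams:
    """Parameters of one neuron's LN model.

    ``noise_sd`` is the SD of the additive Gaussian trial noise; it is used
    only when simulating, never fit.
    """

    w: np.ndarray
    h: float
    a: float
    noise_sd: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if not np.all(np.isfinite(w)) or not np.isfinite(self.h) or not np.isfinite(self.a):
            raise ValueError("LN parameters must be finite")
        if self.a < 0:
            raise ValueError("amplitude a must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_free(self) -> int:
        """Number of fitted parameters: the weights plus h and a."""
        return self.w.size + 2


@dataclass(frozen=True)
class FitReport:
    params: LNParams
    train_sse: float
    converged: bool
    n_restarts_used: int
    test_r2_glm: float = np.nan
    test_r2_oracle: float = np.nan


def static_nonlinearity(x):
    """Smoothed ReLU: (x/2)(1+erf(x/sqrt(2))) + exp(-x^2/2)/sqrt(2*pi).

    Equivalently E[max(0, x + Z)] with Z ~ N(0,1).  For x <= 0 the two terms
    nearly cancel, so the direct form loses all precision (and can even go
    negative) below x ~ -6; there the scaled complementary error function is
    used instead, keeping the result strictly positive for all finite x.
    Vectorized; returns a scalar for scalar input.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xa = np.atleast_1d(x)
    out = np.empty_like(xa)
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
    pos = xa > 0
    xp = xa[pos]
    out[pos] = 0.5 * xp * (1.0 + special.erf(xp / np.sqrt(2.0))) + np.exp(-0.5 * xp * xp) * inv_sqrt2pi
    xn = xa[~pos]
    # f(x) = exp(-x^2/2) * [1/sqrt(2*pi) + (x/2) erfcx(-x/sqrt(2))] for x <= 0
    bracket = inv_sqrt2pi + 0.5 * xn * special.erfcx(-xn / np.sqrt(2.0))
    out[~pos] = np.exp(-0.5 * xn * xn) * np.maximum(bracket, 0.0)
    return float(out[0]) if scalar else out


def ln_predict(p: LNParams, design: np.ndarray) -> np.ndarray:
    """Noise-free LN prediction for every row (condition) of the design matrix."""
    design = np.asarray(design, dtype=float)
    return p.a * static_nonlinearity(design @ p.w + p.h)


def oracle_predict(train_tuning: np.ndarray) -> np.ndarray:
    """The oracle model's prediction: the training tuning curve itself."""
    return np.asarray(train_tuning, dtype=float).copy()


def oracle_n_params(train_tuning: np.ndarray) -> int:
    """One free parameter per stimulus condition."""
    return np.asarray(train_tuning).size


def r_squared(pred: np.ndarray, test: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST about the test mean.

    May be negative (prediction worse than the test-set mean); negative values
    are meaningful for the oracle comparison and are not clipped.  NaN entries
    in either vector are dropped pairwise; fewer than 3 shared finite points or
    zero test variance gives NaN.
    """
    pred = np.asarray(pred, dtype=float)
    test = np.asarray(test, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(test)
    if ok.sum() < 3:
        return np.nan
    p, t = pred[ok], test[ok]
    sst = np.sum((t - t.mean()) ** 2)
    if sst == 0:
        return np.nan
    return 1.0 - np.sum((p - t) ** 2) / sst


def _sse_and_grad(theta, design, target):
    n = design.shape[1]
    w, h, a = theta[:n], theta[n], theta[n + 1]
    drive = design @ w + h
    f = static_nonlinearity(drive)
    resid = a * f - target
    sse = float(resid @ resid)
    # d f / d drive = Phi(drive)
    dfd = stats.norm.cdf(drive)
    common = 2.0 * resid * a * dfd
    grad = np.empty(n + 2)
    grad[:n] = design.T @ common
    grad[n] = common.sum()
    grad[n + 1] = float(2.0 * resid @ f)
    return sse, grad


def fit_ln(
    train_tuning: np.ndarray,
    design: np.ndarray,
    n_restarts: int = 10,
    seed=None,
) -> FitReport:
    """Fit the LN model to a training tuning curve by bounded quasi-Newton descent.

    Minimizes the squared error between predicted and measured training tuning
    with L-BFGS-B, amplitude bounded below at 0, from multiple seeded starts
    (an OLS-based start plus random perturbations with h in {-2, 0}); the best
    restart is kept.  ``n_restarts=1`` reproduces the minimal single-start
    procedure.
    """
    target = np.asarray(train_tuning, dtype=float)
    design = np.asarray(design, dtype=float)
    ok = np.isfinite(target)
    if ok.sum() < design.shape[1] + 2:
        raise ValueError("need at least as many finite tuning values as parameters")
    X, y = design[ok], target[ok]
    n = design.shape[1]
    rng = np.random.default_rng(seed)

    # OLS initialization for the weights (with intercept), amplitude from data scale
    Xi = np.column_stack([X, np.ones(len(X))])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    a0 = max(float(np.nanmax(y)), 1e-3)
    w_scale = max(float(np.abs(beta[:n]).max()), 0.1)

    starts = [np.concatenate([beta[:n] / max(a0, 1e-9), [beta[n] / max(a0, 1e-9)], [a0]])]
    for i in range(max(0, n_restarts - 1)):
        h0 = -2.0 if i % 2 == 0 else 0.0
        w0 = rng.normal(scale=w_scale / max(a0, 1e-9), size=n)
        starts.append(np.concatenate([w0, [h0], [a0]]))

    bounds = [(None, None)] * (n + 1) + [(0.0, None)]
    best = None
    n_used = 0
    for theta0 in starts[: max(1, n_restarts)]:
        n_used += 1
        res = optimize.minimize(
            _sse_and_grad,
            theta0,
            args=(X, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return FitReport(
            params=LNParams(w=np.zeros(n), h=0.0, a=0.0),
            train_sse=np.inf,
            converged=False,
            n_restarts_used=n_used,
        )
    params = LNParams(w=best.x[:n], h=float(best.x[n]), a=float(max(best.x[n + 1], 0.0)))
    return FitReport(
        params=params,
        train_sse=float(best.fun),
        converged=bool(best.success or best.fun < np.inf),
        n_restarts_used=n_used,
    )


def evaluate_fit(report: FitReport, design, test_tuning, train_tuning) -> FitReport:
    """Attach held-out R-squared for the LN fit and the oracle to a report."""
    pred = ln_predict(report.params, design)
    return replace(
        report,
        test_r2_glm=r_squared(pred, test_tuning),
        test_r2_oracle=r_squared(oracle_predict(train_tuning), test_tuning),
    )


def compare_models(reports, oracle_r2_thresh: float = 0.5):
    """Population-level LN-vs-oracle comparison on held-out tuning curves.

    Restricts to neurons whose oracle test R-squared exceeds
    ``oracle_r2_thresh`` (reliably measured neurons), computes per-neuron
    delta R-squared = R2(LN) - R2(oracle), and tests its median against zero
    with a two-sided Wilcoxon signed-rank test.

    Returns a dict with keys ``delta_r2`` (array over passing neurons), ``n``,
    ``median_delta_r2`` and ``p`` (NaN when fewer than 6 neurons pass).
    """
    delta = np.array(
        [
            r.test_r2_glm - r.test_r2_oracle
            for r in reports
            if np.isfinite(r.test_r2_oracle) and r.test_r2_oracle > oracle_r2_thresh
        ]
    )
    out = {
        "delta_r2": delta,
        "n": int(delta.size),
        "median_delta_r2": float(np.median(delta)) if delta.size else np.nan,
        "p": np.nan,
    }
    if delta.size >= 6 and np.any(delta != 0):
        out["p"] = float(stats.wilcoxon(delta).pvalue)
    return out
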