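"""Raw fluorescence -> neuropil-corrected -> ΔF/F -> deconvolved event rates.

An ROI's recorded signal R_i(t) mixes the cell's somatic fluorescence with a
neuropil background N_i(t) measured from a surrounding annulus:

    F_i(t) = R_i(t) - k_i * N_i(t)

The contamination coefficient k_i is constant per ROI and chosen as the
largest value that keeps the true signal nonnegative:

    k_i = min_t R_i(t) / N_i(t),  clamped to [0, 1]

ΔF/F uses either a catch-trial baseline (mean F over the last second of the
inter-trial interval following each no-stimulus trial, averaged over catch
trials) or a sliding low-percentile baseline (20th percentile, 3000-frame
window) for recordings whose transients overlap between trials; the latter
case is then deconvolved into a nonnegative event rate by solving

    min_{e >= 0}  || dff - kernel ⊗ e ||^2 + λ Σ e

with a single-exponential calcium kernel.  Event rates are scaled so that an
event train whose reconvolution has time-averaged ΔF/F of 1 has
time-averaged rate 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

#: frames with neuropil at or below this level are excluded from the min-ratio
NEUROPIL_EPS = 1e-9


class DegenerateTraceError(ValueError):
    """Raised when a per-neuron trace operation has no valid frames."""


@dataclass
class RawTraceSet:
    """Per-ROI raw fluorescence ``R`` and neuropil ``N`` (neuron x time)."""

    R: np.ndarray
    N: np.ndarray
    frame_rate_hz: float

    def __post_init__(self):
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.N = np.atleast_2d(np.asarray(self.N, dtype=float))
        if self.R.shape != self.N.shape:
            raise ValueError(f"R and N shapes differ: {self.R.shape} vs {self.N.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_neurons(self) -> int:
        return self.R.shape[0]

    @property
    def n_frames(self) -> int:
        return self.R.shape[1]


@dataclass
class CorrectedTraceSet:
    F: np.ndarray
    k: np.ndarray
    frame_rate_hz: float
    degenerate: np.ndarray = None  # per-neuron flag: no valid neuropil frames

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.F.shape[0], dtype=bool)


@dataclass
class DffTraceSet:
    dff: np.ndarray
    f0: np.ndarray  # per-neuron scalar (catch scheme) or neuron x time (percentile)
    scheme: str
    frame_rate_hz: float
    invalid: np.ndarray = None  # per-neuron flag: nonpositive baseline

    def __post_init__(self):
        if self.invalid is None:
            self.invalid = np.zeros(self.dff.shape[0], dtype=bool)


@dataclass
class EventRateSet:
    rates: np.ndarray
    kernel_tau_s: float
    frame_rate_hz: float


def contamination_coefficient(R_i, N_i, eps: float = NEUROPIL_EPS) -> float:
    """Per-neuron neuropil contamination: min over valid frames of R/N, clamped to [0, 1].

    Frames with N <= eps are excluded; if no frame is valid a
    :class:`DegenerateTraceError` is raised.  A negative minimum (negative R)
    clamps to 0 with a warning.
    """
    R_i = np.asarray(R_i, dtype=float)
    N_i = np.asarray(N_i, dtype=float)
    if R_i.shape != N_i.shape:
        raise ValueError("R and N must have the same length")
    valid = N_i > eps
    if not np.any(valid):
        raise DegenerateTraceError("neuropil trace has no frames above eps")
    k = float(np.min(R_i[valid] / N_i[valid]))
    if k < 0:
        warnings.warn("negative min R/N ratio; clamping contamination coefficient to 0")
        return 0.0
    return min(k, 1.0)


def neuropil_correct(raw: RawTraceSet, eps: float = NEUROPIL_EPS) -> CorrectedTraceSet:
    """Subtract k*N from each ROI; neurons with no valid neuropil frames are
    flagged degenerate and passed through uncorrected (F = R, k = 0)."""
    n = raw.n_neurons
    F = np.empty_like(raw.R)
    k = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            k[i] = contamination_coefficient(raw.R[i], raw.N[i], eps=eps)
            F[i] = raw.R[i] - k[i] * raw.N[i]
        except DegenerateTraceError:
            degenerate[i] = True
            F[i] = raw.R[i]
            k[i] = 0.0
    return CorrectedTraceSet(F=F, k=k, frame_rate_hz=raw.frame_rate_hz, degenerate=degenerate)


def dff_catch_baseline(corrected: CorrectedTraceSet, trial_table, window_s: float = 1.0) -> DffTraceSet:
    """ΔF/F with f0 from the tail of the inter-trial interval after catch trials.

    For each catch trial, the baseline window is the last ``window_s`` of the
    following ITI; f0 is the mean F over those frames, averaged across catch
    trials.  Neurons with f0 <= 0 are flagged invalid (dff set to NaN).
    """
    fr = corrected.frame_rate_hz
    win = max(1, int(round(window_s * fr)))
    catch = trial_table.df[trial_table.df["is_catch"]]
    if len(catch) == 0:
        raise ValueError("trial table contains no catch trials")
    stim_frames = int(round(trial_table.stim_duration_s * fr))
    iti_frames = int(round(trial_table.iti_s * fr))
    T = corrected.F.shape[1]
    frames = []
    for onset in catch["onset_frame"].to_numpy():
        end = int(onset) + stim_frames + iti_frames
        if end > T:
            continue  # incomplete trailing ITI
        frames.append(np.arange(end - win, end))
    if not frames:
        raise ValueError("no catch trial has a complete post-trial ITI inside the trace")
    # mean per catch trial, then across catch trials
    per_trial = np.stack([corrected.F[:, f].mean(axis=1) for f in frames], axis=1)
    f0 = per_trial.mean(axis=1)
    invalid = ~(f0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (corrected.F - f0[:, None]) / f0[:, None]
    dff[invalid] = np.nan
    return DffTraceSet(dff=dff, f0=f0, scheme="catch_iti", frame_rate_hz=fr, invalid=invalid)


def dff_percentile_baseline(
    corrected: CorrectedTraceSet, window_frames: int = 3000, percentile: float = 20
) -> DffTraceSet:
    """ΔF/F against a sliding low-percentile baseline (centered window,
    truncated at the edges; type-7 linear-interpolation quantiles).

    If the trace is shorter than the window, a single global percentile is
    used and a warning logged.
    """
    F = corrected.F
    T = F.shape[1]
    if T <= window_frames:
        warnings.warn("trace shorter than percentile window; using a global percentile")
        f0 = np.percentile(F, percentile, axis=1, keepdims=True) * np.ones((1, T))
    else:
        f0 = np.empty_like(F)
        for i in range(F.shape[0]):
            s = pd.Series(F[i])
            f0[i] = (
                s.rolling(window=window_frames, center=True, min_periods=1)
                .quantile(percentile / 100.0, interpolation="linear")
                .to_numpy()
            )
    invalid = ~(f0.min(axis=1) > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (F - f0) / f0
    dff[invalid] = np.nan
    return DffTraceSet(dff=dff, f0=f0, scheme="sliding_percentile", frame_rate_hz=corrected.frame_rate_hz, invalid=invalid)


def _kernel_decay(tau_s: float, frame_rate_hz: float) -> float:
    return float(np.exp(-1.0 / (tau_s * frame_rate_hz)))


def _convolve_kernel(e: np.ndarray, alpha: float) -> np.ndarray:
    """kernel ⊗ e with kernel alpha**j (unit peak), via an AR(1) filter."""
    return signal.lfilter([1.0], [1.0, -alpha], e)


def _correlate_kernel(r: np.ndarray, alpha: float) -> np.ndarray:
    """Adjoint of :func:`_convolve_kernel` (time-reversed filtering)."""
    return signal.lfilter([1.0], [1.0, -alpha], r[::-1])[::-1]


def deconvolve(
    dff: DffTraceSet,
    kernel_tau_s: float = 1.5,
    sparsity_weight: float = 0.01,
) -> EventRateSet:
    """Nonnegative sparse deconvolution of ΔF/F into event rates.

    Solves ``min_{e>=0} ||dff - kernel⊗e||² + λ·Σe`` per neuron (the L1 term
    is linear on the nonnegative orthant, so the bounded problem is smooth)
    with L-BFGS-B; the exponential kernel has decay ``exp(-1/(tau*fr))`` per
    frame.  Rates are normalized by the kernel's geometric sum so that unit
    time-averaged ΔF/F maps to unit time-averaged rate.
    """
    if kernel_tau_s <= 0:
        raise ValueError("kernel_tau_s must be positive")
    alpha = _kernel_decay(kernel_tau_s, dff.frame_rate_hz)
    kernel_sum = 1.0 / (1.0 - alpha)
    out = np.zeros_like(dff.dff)
    for i in range(dff.dff.shape[0]):
        y = dff.dff[i]
        if not np.all(np.isfinite(y)):
            out[i] = np.nan
            continue
        if np.allclose(y, 0):
            continue

        def objective(e):
            resid = _convolve_kernel(e, alpha) - y
            val = float(resid @ resid) + sparsity_weight * float(e.sum())
            grad = 2.0 * _correlate_kernel(resid, alpha) + sparsity_weight
            return val, grad

        e0 = np.clip(np.diff(y, prepend=0.0), 0, None)
        res = optimize.minimize(
            objective,
            e0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * y.size,
            options={"maxiter": 300},
        )
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError(
                f"deconvolution failed to converge for neuron {i}: {res.message} "
                f"(nit={res.nit}, fun={res.fun})"
            )
        out[i] = res.x * kernel_sum
    return EventRateSet(rates=out, kernel_tau_s=kernel_tau_s, frame_rate_hz=dff.frame_rate_hz)


def reconvolve(events: EventRateSet) -> np.ndarray:
    """Predicted ΔF/F from an event-rate set (inverse of the normalization)."""
    alpha = _kernel_decay(events.kernel_tau_s, events.frame_rate_hz)
    e = events.rates * (1.0 - alpha)
    return np.stack([_convolve_kernel(e[i], alpha) for i in range(e.shape[0])])
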