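"""Per-trial scalar responses, trial filtering, outlier removal, responsiveness.

A trial's response is the mean ΔF/F (or deconvolved event rate) over the
stimulus window.  Analysis trials are filtered by behavioural state (running
above 10 cm/s for the awake tactile experiment; stationary below 1 cm/s for
the anesthetized/visual variant), outliers are removed per neuron x condition
by the median rule (further than 2.3 x IQR from the median), and a stimulus
is called significant for a neuron when its mean response is positive and a
two-sample t-test against the catch-trial responses survives
Benjamini-Hochberg correction across the stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stimuli import StimulusSpace


@dataclass
class ResponseMatrix:
    """Neuron x trial scalar responses plus masks and condition labels.

    ``condition_ids`` indexes into ``space.conditions`` (catch last);
    ``inlier_mask`` marks per-neuron-per-trial outlier-free responses;
    ``state_mask`` marks trials meeting the behavioural-state criterion.
    """

    values: np.ndarray
    condition_ids: np.ndarray
    space: StimulusSpace
    inlier_mask: np.ndarray = None
    state_mask: np.ndarray = None
    signal_kind: str = "dff"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.condition_ids = np.asarray(self.condition_ids, dtype=int)
        if self.inlier_mask is None:
            self.inlier_mask = np.isfinite(self.values)
        if self.state_mask is None:
            self.state_mask = np.ones(self.values.shape[1], dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def catch_id(self) -> int:
        return len(self.space.conditions) - 1 if self.space.has_catch else -1

    def usable(self, neuron: int) -> np.ndarray:
        """Trials usable for analysis: inlier, state-selected, finite."""
        return self.inlier_mask[neuron] & self.state_mask & np.isfinite(self.values[neuron])

    def trials_of(self, neuron: int, condition_id: int, subset=None) -> np.ndarray:
        sel = (self.condition_ids == condition_id) & self.usable(neuron)
        if subset is not None:
            sel = sel & subset
        return self.values[neuron, sel]


@dataclass
class SignificanceTable:
    pvals: np.ndarray  # neuron x non-catch conditions
    rejected: np.ndarray  # BH-corrected significance, same shape
    means: np.ndarray  # raw condition means, same shape
    significant: np.ndarray  # rejected AND mean > 0
    responsive: np.ndarray  # per neuron: any significant condition
    neuron_class: list  # per neuron: single | multi | combination | none
    untestable: np.ndarray  # conditions with too few trials


def trial_responses(trace_matrix, frame_rate_hz, trial_table, space, window_s=1.0, signal_kind="dff") -> ResponseMatrix:
    """Average each neuron's trace over every trial's stimulus window.

    The window is ``round(window_s * frame_rate)`` frames (half away from
    zero, minimum 1) starting at the trial's onset frame.  Trials whose
    window runs past the end of the trace are flagged invalid (NaN).
    """
    traces = np.atleast_2d(np.asarray(trace_matrix, dtype=float))
    n_frames = traces.shape[1]
    win = max(1, int(np.floor(window_s * frame_rate_hz + 0.5)))
    onsets = trial_table.onset_frames.astype(int)
    values = np.full((traces.shape[0], len(onsets)), np.nan)
    for t, onset in enumerate(onsets):
        if onset < 0 or onset + win > n_frames:
            continue
        values[:, t] = traces[:, onset : onset + win].mean(axis=1)
    return ResponseMatrix(
        values=values,
        condition_ids=trial_table.condition_ids(space),
        space=space,
        signal_kind=signal_kind,
    )


def state_filter(trial_table, mode: str = "running", thresh: float = None) -> np.ndarray:
    """Per-trial behavioural-state flags.

    ``running``: mean trial speed above ``thresh`` (default 10 cm/s).
    ``stationary``: max absolute speed below ``thresh`` (default 1 cm/s).
    """
    speed = trial_table.run_speed
    if mode == "running":
        thresh = 10.0 if thresh is None else thresh
        flags = speed > thresh
    elif mode == "stationary":
        thresh = 1.0 if thresh is None else thresh
        flags = np.abs(speed) < thresh
    else:
        raise ValueError(f"unknown state mode {mode!r}")
    if not np.any(flags):
        warnings.warn(f"state filter '{mode}' selected no trials")
    return flags


def median_rule_outliers(values, factor: float = 2.3) -> np.ndarray:
    """Inlier flags by the median rule: keep |v - median| <= factor * IQR.

    Quantiles use linear interpolation between order statistics (type 7).
    With fewer than 4 values the rule is not applied (all inliers, warning).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("median rule needs >= 4 values; keeping all as inliers")
        return np.ones(v.size, dtype=bool)
    med = np.median(v)
    q75, q25 = np.percentile(v, [75, 25])
    return np.abs(v - med) <= factor * (q75 - q25)


def apply_outlier_rule(resp: ResponseMatrix, factor: float = 2.3) -> ResponseMatrix:
    """Flag outlier responses independently per neuron x condition (in place on a copy)."""
    inlier = resp.inlier_mask.copy()
    for cid in np.unique(resp.condition_ids):
        sel = np.flatnonzero((resp.condition_ids == cid) & resp.state_mask)
        for i in range(resp.n_neurons):
            vals = resp.values[i, sel]
            ok = np.isfinite(vals)
            if ok.sum() >= 4:
                flags = median_rule_outliers(vals[ok], factor=factor)
                inlier[i, sel[ok]] &= flags
            inlier[i, sel[~ok]] = False
    return ResponseMatrix(
        values=resp.values,
        condition_ids=resp.condition_ids,
        space=resp.space,
        inlier_mask=inlier,
        state_mask=resp.state_mask,
        signal_kind=resp.signal_kind,
    )


def speed_outlier_filter(trial_table, state_mask, factor: float = 2.3) -> np.ndarray:
    """Drop running trials whose speed is a median-rule outlier among running trials."""
    mask = state_mask.copy()
    idx = np.flatnonzero(mask)
    if idx.size >= 4:
        keep = median_rule_outliers(trial_table.run_speed[idx], factor=factor)
        mask[idx[~keep]] = False
    return mask


def bh_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    rejected, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected


def responsiveness(resp: ResponseMatrix, alpha: float = 0.05) -> SignificanceTable:
    """Significance of every neuron x stimulus pair against catch trials.

    Per condition: Welch two-sample t-test of that condition's usable
    responses against all usable catch responses; significant iff the raw
    condition mean is positive AND the test survives BH correction within the
    neuron's family of non-catch stimuli.  Conditions with fewer than 2
    usable trials get p = 1 and are flagged untestable.
    """
    space = resp.space
    if not space.has_catch:
        raise ValueError("responsiveness requires catch trials in the stimulus space")
    non_catch = space.non_catch
    catch_id = resp.catch_id
    n, m = resp.n_neurons, len(non_catch)
    pvals = np.ones((n, m))
    means = np.full((n, m), np.nan)
    untestable = np.zeros((n, m), dtype=bool)
    cond_id_of = [space.index(c) for c in non_catch]

    # nan-masked usable values, then a vectorized Welch t-test per condition
    usable = resp.inlier_mask & resp.state_mask[None, :] & np.isfinite(resp.values)
    V = np.where(usable, resp.values, np.nan)

    def _group_stats(cid):
        sub = V[:, resp.condition_ids == cid]
        cnt = np.sum(np.isfinite(sub), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=1)
            var = np.nanvar(sub, axis=1, ddof=1)
        return cnt, mean, var

    n0, m0, s0 = _group_stats(catch_id)
    for j, cid in enumerate(cond_id_of):
        n1, m1, s1 = _group_stats(cid)
        means[:, j] = m1
        bad = (n1 < 2) | (n0 < 2)
        untestable[:, j] = bad
        ok = ~bad
        if not np.any(ok):
            continue
        se2 = s1[ok] / n1[ok] + s0[ok] / n0[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1[ok] - m0[ok]) / np.sqrt(se2)
            df = se2**2 / (
                (s1[ok] / n1[ok]) ** 2 / (n1[ok] - 1) + (s0[ok] / n0[ok]) ** 2 / (n0[ok] - 1)
            )
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[~np.isfinite(p)] = 1.0
        pvals[ok, j] = p
    rejected = np.zeros_like(pvals, dtype=bool)
    for i in range(n):
        rejected[i] = bh_adjust(pvals[i], alpha=alpha)
    significant = rejected & (means > 0)
    responsive = significant.any(axis=1)
    classes = [classify_neuron(significant[i], space) for i in range(n)]
    return SignificanceTable(
        pvals=pvals,
        rejected=rejected,
        means=means,
        significant=significant,
        responsive=responsive,
        neuron_class=classes,
        untestable=untestable,
    )


def classify_neuron(sig_flags, space: StimulusSpace) -> str:
    """Partition a neuron by its significant stimuli.

    ``single``: exactly one single-element stimulus significant;
    ``multi``: two or more single-element stimuli significant;
    ``combination``: no single-element stimulus but at least one
    multi-element stimulus significant; ``none`` otherwise.
    """
    flags = np.asarray(sig_flags, dtype=bool)
    if flags.size != len(space.non_catch):
        raise ValueError("need one flag per non-catch condition")
    n_single = int(flags[space.singleton_indices].sum())
    n_multi = int(flags[space.multi_indices].sum()) if len(space.multi_indices) else 0
    if n_single >= 2:
        return "multi"
    if n_single == 1:
        return "single"
    if n_multi >= 1:
        return "combination"
    return "none"
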