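"""Tuning curves, the linear-difference statistic, cross-validated population
matrices, and the per-neuron supra-linearity bootstrap test.

The *linear difference* for a multi-element stimulus s is

    LD(s) = r(s) - sum_{j in s} r({j})

on catch-subtracted tuning values r: positive LD is supra-linear summation,
negative is sub-linear.  Population displays are cross-validated: trials are
partitioned (halves or thirds, balanced per condition and optionally on
pupil covariates), neurons are gated on split reliability (Pearson r > 0.5
between partition tuning curves), row order comes from the training
partition's preferred stimulus, and displayed values come only from the
held-out partition — so a bright diagonal cannot arise from selecting on
noise.  The supra-linearity test bootstraps, over held-out trials, the
difference between the top-ranked stimulus's LD and the mean LD of the other
multi-element stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .responses import ResponseMatrix
from .stimuli import Condition, StimulusSpace, singleton_components


@dataclass
class TuningCurve:
    """Catch-subtracted mean responses over the non-catch conditions."""

    values: np.ndarray
    space: StimulusSpace
    ci_low: np.ndarray = None
    ci_high: np.ndarray = None
    n_trials: np.ndarray = None

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class PopulationMatrix:
    """Neurons x conditions display matrix with cross-validation metadata."""

    matrix: np.ndarray
    row_neurons: np.ndarray  # original neuron indices
    row_pref: np.ndarray  # preferred condition index (into space.non_catch)
    space: StimulusSpace
    columns: str  # "conditions" (31) or "multis" (26)
    scheme: str
    r_thresh: float
    normalized: bool
    seed: object = None


@dataclass
class SupraLinearityResult:
    ld_top: float
    ld_nontop_mean: float
    label: str  # supra | sub | ns
    p_supra: float
    p_sub: float
    top_condition: Condition = None
    reason: str = ""


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

def _condition_trial_values(resp: ResponseMatrix, neuron: int, subset=None):
    """List of usable trial-response arrays per non-catch condition, plus catch."""
    space = resp.space
    per_cond = [
        resp.trials_of(neuron, space.index(c), subset=subset) for c in space.non_catch
    ]
    catch = resp.trials_of(neuron, resp.catch_id, subset=subset)
    return per_cond, catch


def bootstrap_mean_diff_ci(cond_values, catch_values, n_boot=1000, alpha=0.05, rng=None):
    """Percentile bootstrap CI for mean(cond) - mean(catch).

    Trials are resampled with replacement within each group; the catch mean
    is re-drawn per replicate so its uncertainty propagates into the CI.
    """
    rng = np.random.default_rng(rng)
    cond_values = np.asarray(cond_values, dtype=float)
    catch_values = np.asarray(catch_values, dtype=float)
    if cond_values.size == 0 or catch_values.size == 0:
        return np.nan, np.nan
    idx_c = rng.integers(cond_values.size, size=(n_boot, cond_values.size))
    idx_0 = rng.integers(catch_values.size, size=(n_boot, catch_values.size))
    diffs = cond_values[idx_c].mean(axis=1) - catch_values[idx_0].mean(axis=1)
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def tuning_curve(resp: ResponseMatrix, neuron: int, n_boot: int = 1000, seed=None, subset=None, ci: bool = True) -> TuningCurve:
    """Catch-subtracted tuning curve with percentile-bootstrap 95% CIs.

    ``subset`` restricts to a boolean trial mask (used for partition-wise
    curves).  Conditions with zero usable trials get NaN values.
    """
    space = resp.space
    per_cond, catch = _condition_trial_values(resp, neuron, subset=subset)
    catch_mean = catch.mean() if catch.size else np.nan
    m = len(per_cond)
    values = np.full(m, np.nan)
    lo = np.full(m, np.nan)
    hi = np.full(m, np.nan)
    counts = np.array([v.size for v in per_cond])
    rng = np.random.default_rng(seed)
    for j, vals in enumerate(per_cond):
        if vals.size == 0:
            continue
        values[j] = vals.mean() - catch_mean
        if ci and catch.size:
            lo[j], hi[j] = bootstrap_mean_diff_ci(vals, catch, n_boot=n_boot, rng=rng)
    return TuningCurve(values=values, space=space, ci_low=lo, ci_high=hi, n_trials=counts)


def preferred_stimulus(t: TuningCurve) -> Condition:
    """Argmax condition; ties resolve to the smaller subset earlier in canonical order."""
    v = t.values
    if not np.any(np.isfinite(v)):
        raise ValueError("tuning curve has no finite values")
    best = np.nanmax(v)
    idx = int(np.flatnonzero(v == best)[0])  # canonical order already sorts ties
    return t.space.non_catch[idx]


def principal_whisker(resp: ResponseMatrix, neuron: int, subset=None) -> int:
    """Element with the largest coefficient in a per-element linear fit.

    Ordinary least squares of single-trial responses on per-element presence
    indicators plus an intercept; ties resolve to the lower element index.
    """
    space = resp.space
    sel = resp.usable(neuron)
    if subset is not None:
        sel = sel & subset
    ids = resp.condition_ids[sel]
    y = resp.values[neuron, sel]
    X = np.zeros((y.size, space.n_elements))
    for row, cid in enumerate(ids):
        for j in space.conditions[cid].mask:
            X[row, j] = 1.0
    for j in range(space.n_elements):
        col = X[:, j]
        if col.min() == col.max():
            raise ValueError(
                f"element {j} is {'always' if col.min() > 0 else 'never'} present "
                "among usable trials; per-element fit is rank deficient"
            )
    Xi = np.column_stack([X, np.ones(y.size)])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    coefs = beta[: space.n_elements]
    # ties (to within numerical precision) resolve to the lower element index
    tol = 1e-9 * max(1.0, float(np.abs(coefs).max()))
    return int(np.flatnonzero(coefs >= coefs.max() - tol)[0])


# ---------------------------------------------------------------------------
# linear difference
# ---------------------------------------------------------------------------

def linear_difference(t: TuningCurve) -> np.ndarray:
    """LD over multi-element conditions: observed minus sum of singleton values.

    Returns a vector aligned with ``t.space.multis``; entries whose
    components include a missing singleton are NaN.
    """
    space = t.space
    singleton_value = {}
    for c in space.singletons:
        singleton_value[next(iter(c.mask))] = t.values[space.non_catch.index(c)]
    out = np.full(len(space.multis), np.nan)
    for j, c in enumerate(space.multis):
        obs = t.values[space.non_catch.index(c)]
        parts = [singleton_value[e] for e in sorted(c.mask)]
        if np.isfinite(obs) and np.all(np.isfinite(parts)):
            out[j] = obs - np.sum(parts)
    return out


def ld_coefficients(space: StimulusSpace) -> np.ndarray:
    """Matrix C (multis x conditions-incl-catch) with LD = C @ condition_means.

    On raw (non-catch-subtracted) condition means mu,
    LD(s) = mu_s - sum_j mu_{j} + (|s| - 1) mu_catch.
    """
    n_all = len(space.conditions)
    non_catch = list(space.non_catch)
    C = np.zeros((len(space.multis), n_all))
    catch_col = n_all - 1
    for r, c in enumerate(space.multis):
        C[r, space.index(c)] = 1.0
        for comp in singleton_components(c):
            C[r, space.index(comp)] -= 1.0
        C[r, catch_col] += len(c.mask) - 1
    return C


# ---------------------------------------------------------------------------
# trial partitioning and reliability
# ---------------------------------------------------------------------------

def partition_trials(trial_table, n_parts: int, balance_keys=None, seed=None, state_mask=None) -> np.ndarray:
    """Assign trials to ``n_parts`` partitions, balanced per condition.

    Within each condition the per-part counts differ by at most one.  When
    ``balance_keys`` name covariate columns (e.g. pupil diameter/location),
    a seeded greedy swap refinement minimizes the spread of covariate means
    across parts.  Trials outside ``state_mask`` get label -1.
    """
    if n_parts not in (2, 3):
        raise ValueError("n_parts must be 2 or 3")
    df = trial_table.df
    n = len(df)
    rng = np.random.default_rng(seed)
    labels = np.full(n, -1, dtype=int)
    usable = np.ones(n, dtype=bool) if state_mask is None else np.asarray(state_mask, bool)
    for bits in df["condition_bits"].unique():
        idx = np.flatnonzero((df["condition_bits"] == bits).to_numpy() & usable)
        if idx.size < n_parts:
            raise ValueError(
                f"condition {bits} has {idx.size} usable trials; need >= {n_parts}"
            )
        rng.shuffle(idx)
        labels[idx] = np.arange(idx.size) % n_parts
    if balance_keys:
        cov = np.column_stack(
            [df[k].to_numpy(dtype=float) for k in balance_keys if k in df.columns]
        )
        if cov.size:
            labels = _refine_balance(labels, cov, df["condition_bits"].to_numpy(), n_parts, rng)
    return labels


def _balance_cost(labels, cov, n_parts):
    means = np.stack([cov[labels == p].mean(axis=0) for p in range(n_parts)])
    scale = cov[labels >= 0].std(axis=0) + 1e-12
    return float(((means.max(axis=0) - means.min(axis=0)) / scale).sum())


def _refine_balance(labels, cov, cond_bits, n_parts, rng, n_iter=300):
    labels = labels.copy()
    cost = _balance_cost(labels, cov, n_parts)
    usable = np.flatnonzero(labels >= 0)
    for _ in range(n_iter):
        i, j = rng.choice(usable, size=2, replace=False)
        if labels[i] == labels[j] or cond_bits[i] != cond_bits[j]:
            continue  # swaps within a condition keep per-condition counts exact
        labels[i], labels[j] = labels[j], labels[i]
        new_cost = _balance_cost(labels, cov, n_parts)
        if new_cost < cost:
            cost = new_cost
        else:
            labels[i], labels[j] = labels[j], labels[i]
    return labels


def reliability(t_a: TuningCurve, t_b: TuningCurve) -> float:
    """Pearson correlation between two tuning curves over shared finite conditions."""
    a, b = t_a.values, t_b.values
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared finite conditions")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# cross-validated population matrices
# ---------------------------------------------------------------------------

def _curves_by_part(resp, neuron, labels, parts):
    return [
        tuning_curve(resp, neuron, ci=False, subset=(labels == p)) for p in parts
    ]


def population_matrices(
    resp: ResponseMatrix,
    labels: np.ndarray,
    scheme: str = "halves",
    r_thresh: float = 0.5,
    normalize: bool = True,
    seed=None,
):
    """Cross-validated tuning and linear-difference population matrices.

    ``halves``: reliability and stimulus preference from part 0, display from
    part 1.  ``thirds``: reliability between parts 0 and 1, preference from
    parts 0+1 pooled, display strictly from part 2 (no display data enters
    selection or sorting).

    Rows are neurons passing the reliability gate, ordered by the training
    partition's preferred stimulus (canonical condition order); displayed
    rows are optionally normalized by their maximum absolute value.
    Returns ``(tuning_matrix, ld_matrix)`` as :class:`PopulationMatrix`.
    """
    if scheme == "halves":
        rel_parts, pref_subset, disp_part = (0, 1), (0,), 1
    elif scheme == "thirds":
        rel_parts, pref_subset, disp_part = (0, 1), (0, 1), 2
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    space = resp.space
    rows_t, rows_ld, keep, prefs = [], [], [], []
    for i in range(resp.n_neurons):
        ca, cb = _curves_by_part(resp, i, labels, rel_parts)
        try:
            r = reliability(ca, cb)
        except ValueError:
            continue
        if not np.isfinite(r) or r <= r_thresh:
            continue
        pref_mask = np.isin(labels, pref_subset)
        train_curve = tuning_curve(resp, i, ci=False, subset=pref_mask)
        if not np.any(np.isfinite(train_curve.values)):
            continue
        pref = preferred_stimulus(train_curve)
        disp_curve = tuning_curve(resp, i, ci=False, subset=(labels == disp_part))
        ld = linear_difference(disp_curve)
        keep.append(i)
        prefs.append(space.non_catch.index(pref))
        rows_t.append(disp_curve.values)
        rows_ld.append(ld)
    if not keep:
        import warnings

        warnings.warn("no neuron passed the reliability gate; population matrix is empty")
        empty = np.zeros((0, len(space.non_catch)))
        pm = PopulationMatrix(empty, np.array([], int), np.array([], int), space, "conditions", scheme, r_thresh, normalize, seed)
        pml = PopulationMatrix(np.zeros((0, len(space.multis))), np.array([], int), np.array([], int), space, "multis", scheme, r_thresh, normalize, seed)
        return pm, pml
    keep = np.array(keep)
    prefs = np.array(prefs)
    order = np.lexsort((keep, prefs))
    T = np.stack(rows_t)[order]
    L = np.stack(rows_ld)[order]
    if normalize:
        T = _row_normalize(T)
        L = _row_normalize(L)
    meta = dict(space=space, scheme=scheme, r_thresh=r_thresh, normalized=normalize, seed=seed)
    pm_t = PopulationMatrix(T, keep[order], prefs[order], columns="conditions", **meta)
    pm_l = PopulationMatrix(L, keep[order], prefs[order], columns="multis", **meta)
    return pm_t, pm_l


def _row_normalize(M):
    M = M.copy()
    denom = np.nanmax(np.abs(M), axis=1)
    denom[~(denom > 0)] = 1.0
    return M / denom[:, None]


def sorted_linear_difference(resp: ResponseMatrix, labels, scheme: str = "halves", r_thresh: float = 0.5):
    """Per-rank mean held-out LD across neurons preferring a multi-element stimulus.

    For each reliable neuron whose training-partition preferred stimulus is
    multi-element, the 26 multi-element conditions are ranked by descending
    training-partition response and the held-out LD is read out at each rank;
    ranks are averaged across neurons.  Returns ``(rank_means, n_neurons)``.
    """
    if scheme == "halves":
        rel_parts, pref_subset, disp_part = (0, 1), (0,), 1
    elif scheme == "thirds":
        rel_parts, pref_subset, disp_part = (0, 1), (0, 1), 2
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    space = resp.space
    multi_idx = space.multi_indices
    curves = []
    for i in range(resp.n_neurons):
        ca, cb = _curves_by_part(resp, i, labels, rel_parts)
        try:
            r = reliability(ca, cb)
        except ValueError:
            continue
        if not np.isfinite(r) or r <= r_thresh:
            continue
        pref_mask = np.isin(labels, pref_subset)
        train_curve = tuning_curve(resp, i, ci=False, subset=pref_mask)
        if not np.any(np.isfinite(train_curve.values)):
            continue
        if not preferred_stimulus(train_curve).is_multi:
            continue
        disp_curve = tuning_curve(resp, i, ci=False, subset=(labels == disp_part))
        ld = linear_difference(disp_curve)
        rank_order = np.argsort(-train_curve.values[multi_idx], kind="stable")
        curves.append(ld[rank_order])
    if not curves:
        return np.full(len(multi_idx), np.nan), 0
    return np.nanmean(np.stack(curves), axis=0), len(curves)


# ---------------------------------------------------------------------------
# supra-linearity bootstrap test
# ---------------------------------------------------------------------------

def supralinearity_test(
    resp: ResponseMatrix,
    neuron: int,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    n_boot: int = 10000,
    alpha: float = 0.01,
    seed=None,
) -> SupraLinearityResult:
    """Bootstrap test for selective supra-linear summation at the top stimulus.

    The top-ranked stimulus is the training partition's preferred condition
    and must be multi-element.  On the held-out partition the statistic is

        D = LD(top) - mean_{other multi s} LD(s)

    Trials are resampled with replacement within each condition;
    ``p_supra`` is the fraction of replicates with D <= 0 and ``p_sub`` the
    fraction with D >= 0; the label is supra/sub when the corresponding
    one-sided p falls below ``alpha``.
    """
    space = resp.space
    rng = np.random.default_rng(seed)
    train_curve = tuning_curve(resp, neuron, ci=False, subset=train_mask)
    if not np.any(np.isfinite(train_curve.values)):
        return SupraLinearityResult(np.nan, np.nan, "ns", np.nan, np.nan, reason="no training data")
    top = preferred_stimulus(train_curve)
    if not top.is_multi:
        return SupraLinearityResult(
            np.nan, np.nan, "ns", np.nan, np.nan, top_condition=top,
            reason="training-preferred stimulus is not multi-element",
        )
    C = ld_coefficients(space)
    top_row = list(space.multis).index(top)
    w = np.full(len(space.multis), -1.0 / (len(space.multis) - 1))
    w[top_row] = 1.0
    contrast = w @ C  # D as a linear functional of the 32 condition means

    groups, means = [], np.full(len(space.conditions), np.nan)
    for cid in range(len(space.conditions)):
        vals = resp.trials_of(neuron, cid, subset=test_mask)
        groups.append(vals)
        if vals.size:
            means[cid] = vals.mean()
    needed = np.flatnonzero(contrast != 0)
    if any(groups[c].size < 2 for c in needed):
        return SupraLinearityResult(
            np.nan, np.nan, "ns", np.nan, np.nan, top_condition=top,
            reason="insufficient held-out trials in a required condition",
        )
    test_curve = tuning_curve(resp, neuron, ci=False, subset=test_mask)
    ld = linear_difference(test_curve)
    ld_top = float(ld[top_row])
    ld_nontop = float(np.nanmean(np.delete(ld, top_row)))

    boot_means = np.zeros((n_boot, len(space.conditions)))
    for cid in needed:
        vals = groups[cid]
        idx = rng.integers(vals.size, size=(n_boot, vals.size))
        boot_means[:, cid] = vals[idx].mean(axis=1)
    D_boot = boot_means @ contrast
    p_supra = float(np.mean(D_boot <= 0))
    p_sub = float(np.mean(D_boot >= 0))
    if p_supra < alpha:
        label = "supra"
    elif p_sub < alpha:
        label = "sub"
    else:
        label = "ns"
    return SupraLinearityResult(
        ld_top=ld_top,
        ld_nontop_mean=ld_nontop,
        label=label,
        p_supra=p_supra,
        p_sub=p_sub,
        top_condition=top,
    )
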