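"""Surrogate-data controls: does detected supra-linearity reflect signal?

Selecting reliable neurons and sorting by preferred stimulus could, in
principle, manufacture an apparent diagonal of supra-linearity out of noise.
Two surrogate constructions test this.  In both, multi-element responses are
replaced by exact linear sums of the single-element responses, so any true
nonlinearity is removed:

* ``noise_only`` — independent Gaussian noise is added to each trial
  partition, matched to the empirical across-partition SD of the base data.
  If the analysis is honest, no diagonal appears and the supra-linearity
  flag rate stays at its nominal false-positive level.
* ``signal_plus_noise`` — additionally, one shared Gaussian
  stimulus-dependent vector per neuron (SD matched to the SD across
  conditions of the neuron's original tuning) is added identically to all
  partitions.  A reproducible stimulus-dependent deviation from linearity is
  thereby present, and the diagonal should reappear.

True deviation from linearity is then necessary and sufficient for the
analysis to report supra-linearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .responses import ResponseMatrix
from .stimuli import StimulusSpace, singleton_components
from .tuning import (
    TuningCurve,
    linear_difference,
    population_matrices,
    supralinearity_test,
    tuning_curve,
)


@dataclass(frozen=True)
class SurrogateSpec:
    mode: str  # "noise_only" | "signal_plus_noise"
    n_parts: int = 2
    pooled_sd: bool = False  # pool the noise SD across conditions instead of per-condition
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("noise_only", "signal_plus_noise"):
            raise ValueError(f"unknown surrogate mode {self.mode!r}")
        if self.n_parts not in (2, 3):
            raise ValueError("n_parts must be 2 or 3")


@dataclass
class DiagonalReport:
    mode: str
    enrichment: float
    frac_supra_flagged: float
    per_session_top_vs_nontop: list
    n_neurons_gated: int
    n_neurons_tested: int


def _sd_debias(n_parts: int) -> float:
    """1/c4: corrects the downward bias of the sample SD at tiny n.

    With only 2-3 partitions the sample SD underestimates the true SD
    (E[s] = c4 * sigma); generating noise at sigma-hat/c4 makes the
    surrogate's expected *sample* across-partition SD match the empirical one.
    """
    n = n_parts
    c4 = np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2))
    return 1.0 / c4


def linearize_tuning(t: TuningCurve) -> TuningCurve:
    """Replace every multi-element value by the sum of its singleton values."""
    space = t.space
    singles = {}
    for c in space.singletons:
        v = t.values[space.non_catch.index(c)]
        if not np.isfinite(v):
            raise ValueError(f"singleton {c} value is missing; cannot linearize")
        singles[next(iter(c.mask))] = v
    values = t.values.copy()
    for c in space.multis:
        values[space.non_catch.index(c)] = sum(singles[e] for e in c.mask)
    return TuningCurve(values=values, space=space, n_trials=t.n_trials)


def _linearize_condition_means(mu, space: StimulusSpace):
    """Linearize raw (non-catch-subtracted) condition means, catch entry last."""
    mu = np.asarray(mu, dtype=float)
    out = mu.copy()
    catch = mu[-1]
    for c in space.multis:
        i = space.index(c)
        out[i] = catch + sum(mu[space.index(s)] - catch for s in singleton_components(c))
    return out


def build_surrogate(partition_curves, base_curve: TuningCurve, spec: SurrogateSpec, rng=None):
    """Curve-level surrogate: per-partition tuning curves with linearized signal.

    ``partition_curves`` is an (n_parts, n_conditions) array of the neuron's
    base tuning computed per partition; the across-partition SD per condition
    sets the independent noise amplitude.  Returns an array of the same shape.
    """
    rng = np.random.default_rng(rng)
    P = np.asarray(partition_curves, dtype=float)
    if P.ndim != 2 or P.shape[0] != spec.n_parts:
        raise ValueError("partition_curves must be (n_parts, n_conditions)")
    sd = P.std(axis=0, ddof=1)
    if spec.pooled_sd:
        sd = np.full_like(sd, np.nanmean(sd))
    if not np.all(np.isfinite(sd)):
        raise ValueError("across-partition SD undefined for some condition")
    sd = sd * _sd_debias(spec.n_parts)
    lin = linearize_tuning(base_curve).values
    out = lin[None, :] + rng.normal(size=P.shape) * sd[None, :]
    if spec.mode == "signal_plus_noise":
        sig_sd = float(np.nanstd(base_curve.values, ddof=1))
        shared = rng.normal(scale=sig_sd, size=P.shape[1])
        out = out + shared[None, :]
    return out


def surrogate_responses(resp: ResponseMatrix, labels: np.ndarray, spec: SurrogateSpec, seed=None) -> ResponseMatrix:
    """Trial-level surrogate with the same partition-mean statistics.

    Each neuron's trial responses are replaced by a linearized signal plus
    noise.  The independent partition noise is realized at the trial level
    with SD sigma_c * sqrt(n_trials-in-partition), so each partition *mean*
    carries the matched across-partition SD sigma_c while the trial-level
    bootstrap remains meaningful.  In ``signal_plus_noise`` mode a shared
    stimulus-dependent offset (per neuron) is added to every partition alike.
    Catch trials are regenerated around the base catch mean.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    space = resp.space
    n_cond = len(space.conditions)
    parts = [p for p in np.unique(labels) if p >= 0]
    values = np.full_like(resp.values, np.nan)
    new_inlier = np.zeros_like(resp.inlier_mask)
    for i in range(resp.n_neurons):
        # base per-partition condition means and their across-partition SD
        part_means = np.full((len(parts), n_cond), np.nan)
        for pi, p in enumerate(parts):
            for cid in range(n_cond):
                vals = resp.trials_of(i, cid, subset=(labels == p))
                if vals.size:
                    part_means[pi, cid] = vals.mean()
        sd = np.nanstd(part_means, axis=0, ddof=1) * _sd_debias(len(parts))
        if spec.pooled_sd:
            sd = np.full_like(sd, np.nanmean(sd))
        mu = np.nanmean(part_means, axis=0)
        lin_mu = _linearize_condition_means(mu, space)
        shared = np.zeros(n_cond)
        if spec.mode == "signal_plus_noise":
            base = tuning_curve(resp, i, ci=False)
            sig_sd = float(np.nanstd(base.values, ddof=1))
            shared[:-1] = rng.normal(scale=sig_sd, size=n_cond - 1)
        for pi, p in enumerate(parts):
            part_noise_scale = sd  # SD of the partition mean
            for cid in range(n_cond):
                sel = np.flatnonzero(
                    (resp.condition_ids == cid) & (labels == p) & resp.usable(i)
                )
                if sel.size == 0:
                    continue
                trial_sd = part_noise_scale[cid] * np.sqrt(sel.size)
                if not np.isfinite(trial_sd):
                    continue
                values[i, sel] = (
                    lin_mu[cid] + shared[cid] + rng.normal(scale=trial_sd, size=sel.size)
                )
                new_inlier[i, sel] = True
    return ResponseMatrix(
        values=values,
        condition_ids=resp.condition_ids,
        space=space,
        inlier_mask=new_inlier,
        state_mask=resp.state_mask,
        signal_kind=resp.signal_kind,
    )


def diagonal_enrichment(ld_matrix) -> float:
    """Mean (over neurons) of LD at the train-preferred multi-element stimulus
    minus the mean LD over the neuron's other multi-element stimuli.

    Operates on a multi-column :class:`~combicode.tuning.PopulationMatrix`
    (normalized or not); rows whose preferred stimulus is single-element are
    skipped.  Returns NaN for an empty matrix.
    """
    M = ld_matrix.matrix
    if M.shape[0] == 0:
        return np.nan
    space = ld_matrix.space
    multis = list(space.multis)
    non_catch = list(space.non_catch)
    contribs = []
    for row in range(M.shape[0]):
        pref_cond = non_catch[ld_matrix.row_pref[row]]
        if not pref_cond.is_multi:
            continue
        j = multis.index(pref_cond)
        others = np.delete(M[row], j)
        if np.isfinite(M[row, j]) and np.any(np.isfinite(others)):
            contribs.append(M[row, j] - np.nanmean(others))
    return float(np.mean(contribs)) if contribs else np.nan


def surrogate_battery(
    resp: ResponseMatrix,
    labels: np.ndarray,
    modes=("noise_only", "signal_plus_noise"),
    scheme: str = "halves",
    r_thresh: float = 0.5,
    n_boot: int = 1000,
    alpha: float = 0.01,
    n_sessions: int = 5,
    seed: int = 0,
) -> dict:
    """Run the full cross-validated analysis on each surrogate mode.

    For each mode: build surrogate trial responses, gate neurons on split
    reliability, build the normalized LD population matrix, run the
    supra-linearity bootstrap on every gated neuron, and summarize as a
    :class:`DiagonalReport`.  Neurons are grouped into ``n_sessions``
    pseudo-sessions for the per-session top-vs-nontop means.  Seed-
    deterministic end to end.
    """
    n_parts = len([p for p in np.unique(labels) if p >= 0])
    if scheme == "halves":
        train_parts, test_part = (0,), 1
    else:
        train_parts, test_part = (0, 1), 2
    reports = {}
    for m, mode in enumerate(modes):
        spec = SurrogateSpec(mode=mode, n_parts=n_parts, seed=seed + 1000 * (m + 1))
        surr = surrogate_responses(resp, labels, spec)
        _, pm_ld = population_matrices(surr, labels, scheme=scheme, r_thresh=r_thresh, seed=seed)
        enrich = diagonal_enrichment(pm_ld)
        train_mask = np.isin(labels, train_parts)
        test_mask = labels == test_part
        n_supra = 0
        tested = 0
        top_vs_nontop = []
        session_of = pm_ld.row_neurons % max(1, n_sessions)
        per_session = {s: [] for s in range(max(1, n_sessions))}
        for row, neuron in enumerate(pm_ld.row_neurons):
            res = supralinearity_test(
                surr, int(neuron), train_mask, test_mask,
                n_boot=n_boot, alpha=alpha, seed=seed + 17 * int(neuron) + m,
            )
            if res.reason:
                continue
            tested += 1
            if res.label == "supra":
                n_supra += 1
            per_session[int(session_of[row])].append(res.ld_top - res.ld_nontop_mean)
        top_vs_nontop = [float(np.mean(v)) for v in per_session.values() if v]
        reports[mode] = DiagonalReport(
            mode=mode,
            enrichment=enrich,
            frac_supra_flagged=(n_supra / tested) if tested else np.nan,
            per_session_top_vs_nontop=top_vs_nontop,
            n_neurons_gated=int(pm_ld.matrix.shape[0]),
            n_neurons_tested=tested,
        )
    return reports
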