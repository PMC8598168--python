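"""Synthetic imaging sessions with known ground truth.

Generates populations of model neurons (labeled-line, combination-selective
LN, or tabulated tuning), a pseudo-randomized trial sequence over all element
combinations plus catch trials, per-trial response amplitudes with Gaussian
trial-to-trial noise, and raw two-channel fluorescence traces (ROI + neuropil
with known contamination), so the full analysis chain can be validated
against known tuning.

The default configuration mirrors the awake five-whisker experiment: 32
conditions (31 combinations + catch) x 20 trials, 1 s stimulus windows, 2 s
inter-trial intervals, 15.45 Hz frames, a GCaMP6s-like single-exponential
calcium kernel (tau = 1.5 s, instantaneous rise), and lognormal running
speeds (median 30 cm/s) with a 10% admixture of slow trials so the
running-trial filter is exercised.  Trial noise is Gaussian and homoscedastic
per neuron, matching the LN model's noise term.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .lnmodel import LNParams, ln_predict
from .stimuli import Condition, StimulusSpace, design_matrix, enumerate_conditions
from .traces import RawTraceSet

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SessionConfig:
    n_neurons: int = 100
    n_elements: int = 5
    trials_per_condition: int = 20
    stim_duration_s: float = 1.0
    iti_s: float = 2.0
    frame_rate_hz: float = 15.45
    kernel_tau_s: float = 1.5
    baseline_f0: float = 100.0
    neuropil_baseline: float = 40.0
    neuropil_sd: float = 0.5
    neuropil_slow_amp: float = 0.1  # fractional amplitude of the shared slow background
    trial_noise_sd: float = 0.15  # response (ΔF/F) units, per-neuron default
    run_speed_median: float = 30.0  # cm/s, lognormal median for running trials
    run_speed_sigma: float = 0.3  # lognormal shape
    slow_trial_frac: float = 0.1  # fraction of trials below the running threshold
    include_pupil: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_neurons",
            "n_elements",
            "trials_per_condition",
            "stim_duration_s",
            "iti_s",
            "frame_rate_hz",
            "kernel_tau_s",
            "baseline_f0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SessionConfig.{name} must be positive")

    @property
    def stim_frames(self) -> int:
        return max(1, int(round(self.stim_duration_s * self.frame_rate_hz)))

    @property
    def iti_frames(self) -> int:
        return max(1, int(round(self.iti_s * self.frame_rate_hz)))

    def space(self) -> StimulusSpace:
        return enumerate_conditions(self.n_elements, include_catch=True)


@dataclass
class GroundTruthNeuron:
    """Generative description of one synthetic neuron."""

    kind: str  # "ln" or "tabulated"
    trial_noise_sd: float
    contamination_k_true: float
    ln_params: LNParams = None
    tabulated_tuning: np.ndarray = None

    def __post_init__(self):
        if self.kind not in ("ln", "tabulated"):
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if (self.ln_params is None) == (self.tabulated_tuning is None):
            raise ValueError("exactly one of ln_params / tabulated_tuning must be set")
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be >= 0")
        if not 0 <= self.contamination_k_true <= 1:
            raise ValueError("contamination_k_true must be in [0, 1]")

    def tuning(self, space: StimulusSpace) -> np.ndarray:
        """Noise-free mean *evoked* response per non-catch condition.

        For LN neurons the spontaneous level a*f(h) (the model's output with
        no element present) is subtracted, since trial amplitudes are evoked
        ΔF/F changes relative to the no-stimulus condition and catch trials
        carry amplitude 0 by construction.
        """
        if self.kind == "ln":
            from .lnmodel import static_nonlinearity

            p = self.ln_params
            spont = p.a * static_nonlinearity(p.h)
            return ln_predict(p, design_matrix(space)) - spont
        return np.asarray(self.tabulated_tuning, dtype=float)


@dataclass
class TrialTable:
    """Per-trial metadata: condition, onset frame, running speed, pupil covariates."""

    df: pd.DataFrame
    stim_duration_s: float
    iti_s: float

    def __post_init__(self):
        onsets = self.df["onset_frame"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def onset_frames(self) -> np.ndarray:
        return self.df["onset_frame"].to_numpy()

    @property
    def run_speed(self) -> np.ndarray:
        return self.df["run_speed"].to_numpy()

    @property
    def is_catch(self) -> np.ndarray:
        return self.df["is_catch"].to_numpy()

    def conditions(self) -> list:
        return [Condition.from_bitstring(b) for b in self.df["condition_bits"]]

    def condition_ids(self, space: StimulusSpace) -> np.ndarray:
        """Index of each trial's condition in ``space.conditions`` (catch last)."""
        lookup = {c: i for i, c in enumerate(space.conditions)}
        return np.array([lookup[c] for c in self.conditions()])

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class SyntheticSession:
    config: SessionConfig
    trial_table: TrialTable
    raw: RawTraceSet
    truth: list
    true_trial_amplitudes: np.ndarray

    def space(self) -> StimulusSpace:
        return self.config.space()


def _class_counts(n: int, proportions) -> list:
    """Largest-remainder apportionment of n into len(proportions) classes."""
    p = np.asarray(proportions, dtype=float)
    raw = p * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def sample_population(
    cfg: SessionConfig,
    mixture=(0.5, 0.5, 0.0),
    seed=None,
    tabulated_tuning=None,
) -> list:
    """Draw ground-truth neurons from a mixture of response classes.

    ``mixture`` gives proportions of (labeled-line, combination-selective LN,
    tabulated) neurons and must sum to 1.  Labeled-line neurons carry a single
    positive weight with h ~ 0; combination-selective neurons carry 2-3
    positive weights with a strongly negative baseline drive h so that only
    specific multi-element stimuli cross threshold (supra-linear summation by
    construction).  Tabulated neurons copy rows of ``tabulated_tuning``
    (defaults to random nonnegative curves).
    """
    p = np.asarray(mixture, dtype=float)
    if p.size != 3 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("mixture must be 3 nonnegative proportions summing to 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_ll, n_comb, n_tab = _class_counts(cfg.n_neurons, p)
    n_el = cfg.n_elements
    neurons = []
    for _ in range(n_ll):
        w = np.zeros(n_el)
        w[rng.integers(n_el)] = rng.uniform(1.5, 3.0)
        neurons.append(
            GroundTruthNeuron(
                kind="ln",
                ln_params=LNParams(w=w, h=0.0, a=float(rng.uniform(0.5, 1.5)), noise_sd=cfg.trial_noise_sd),
                trial_noise_sd=cfg.trial_noise_sd,
                contamination_k_true=float(rng.uniform(0.3, 0.8)),
            )
        )
    for _ in range(n_comb):
        m = int(rng.integers(2, min(4, n_el + 1)))
        members = rng.choice(n_el, size=m, replace=False)
        w = np.zeros(n_el)
        # weights large enough that dropping any one member stays well below
        # threshold: single elements evoke essentially nothing
        w[members] = rng.uniform(2.0, 3.0, size=m)
        h = -float(w.sum()) + float(rng.uniform(0.3, 0.7))
        neurons.append(
            GroundTruthNeuron(
                kind="ln",
                ln_params=LNParams(w=w, h=h, a=float(rng.uniform(1.0, 2.0)), noise_sd=cfg.trial_noise_sd),
                trial_noise_sd=cfg.trial_noise_sd,
                contamination_k_true=float(rng.uniform(0.3, 0.8)),
            )
        )
    n_cond = 2**n_el - 1
    for j in range(n_tab):
        if tabulated_tuning is not None:
            curve = np.asarray(tabulated_tuning)[j % len(tabulated_tuning)]
        else:
            curve = np.abs(rng.normal(scale=0.5, size=n_cond))
        neurons.append(
            GroundTruthNeuron(
                kind="tabulated",
                tabulated_tuning=np.asarray(curve, dtype=float),
                trial_noise_sd=cfg.trial_noise_sd,
                contamination_k_true=float(rng.uniform(0.3, 0.8)),
            )
        )
    rng.shuffle(neurons)
    return neurons


def simulate_trials(pop, cfg: SessionConfig, seed=None):
    """Pseudo-randomized trial sequence and noisy per-trial response amplitudes.

    Every condition (including catch) appears exactly ``trials_per_condition``
    times; per-trial amplitude = mean tuning value + N(0, trial_noise_sd),
    with catch amplitude pure noise.  Running speeds are lognormal with a
    slow-trial admixture; pupil covariates (if enabled) are Gaussian random
    walks across trials.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    space = cfg.space()
    n_cond = len(space.conditions)
    cond_ids = np.repeat(np.arange(n_cond), cfg.trials_per_condition)
    rng.shuffle(cond_ids)
    n_trials = cond_ids.size

    trial_len = cfg.stim_frames + cfg.iti_frames
    onsets = cfg.iti_frames + np.arange(n_trials) * trial_len

    speeds = np.exp(rng.normal(np.log(cfg.run_speed_median), cfg.run_speed_sigma, size=n_trials))
    slow = rng.random(n_trials) < cfg.slow_trial_frac
    speeds[slow] = rng.uniform(2.0, 8.0, size=slow.sum())

    data = {
        "trial": np.arange(n_trials),
        "condition_bits": [space.conditions[i].bitstring(cfg.n_elements) for i in cond_ids],
        "is_catch": np.array([space.conditions[i].is_catch for i in cond_ids]),
        "onset_frame": onsets,
        "run_speed": speeds,
    }
    if cfg.include_pupil:
        for name in ("pupil_diameter", "pupil_x", "pupil_y"):
            data[name] = np.cumsum(rng.normal(scale=0.05, size=n_trials)) + rng.normal()
    table = TrialTable(df=pd.DataFrame(data), stim_duration_s=cfg.stim_duration_s, iti_s=cfg.iti_s)

    tuning = np.stack([nrn.tuning(space) for nrn in pop])  # neuron x non-catch
    mean_amp = np.zeros((len(pop), n_trials))
    non_catch_map = {space.index(c): j for j, c in enumerate(space.non_catch)}
    for t, ci in enumerate(cond_ids):
        if not space.conditions[ci].is_catch:
            mean_amp[:, t] = tuning[:, non_catch_map[ci]]
    noise_sd = np.array([nrn.trial_noise_sd for nrn in pop])
    amplitudes = mean_amp + rng.normal(size=mean_amp.shape) * noise_sd[:, None]
    return table, amplitudes


def _dff_shape_drive(amplitudes, onsets, stim_frames, n_frames):
    """Impulse drive whose AR(1)-filtered output is the boxcar⊗kernel ΔF/F."""
    drive = np.zeros((amplitudes.shape[0], n_frames))
    for t, onset in enumerate(onsets):
        drive[:, onset : onset + stim_frames] += amplitudes[:, t : t + 1]
    return drive


def render_traces(
    trial_amplitudes, trial_table: TrialTable, cfg: SessionConfig, seed=None, k_true=None
) -> RawTraceSet:
    """Forward model: amplitudes -> raw two-channel fluorescence.

    True ΔF/F is each trial's amplitude shaped as a boxcar over the stimulus
    window convolved with an exponential kernel (decay ``kernel_tau_s``,
    instantaneous rise, unit steady-state gain).  Somatic fluorescence is
    ``baseline_f0 * (1 + dff)``; the neuropil channel is a shared slow
    background plus per-neuron white noise; the recorded ROI channel adds
    ``contamination_k_true x neuropil``.  All fluorescence is clipped at 0.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    amplitudes = np.asarray(trial_amplitudes, dtype=float)
    if not np.all(np.isfinite(amplitudes)):
        raise ValueError("trial amplitudes must be finite")
    onsets = trial_table.onset_frames.astype(int)
    n_frames = int(onsets[-1] + cfg.stim_frames + cfg.iti_frames)
    alpha = float(np.exp(-1.0 / (cfg.kernel_tau_s * cfg.frame_rate_hz)))
    drive = _dff_shape_drive(amplitudes, onsets, cfg.stim_frames, n_frames)
    # scale by (1-alpha) so a sustained boxcar saturates at its amplitude
    dff_true = signal.lfilter([1.0 - alpha], [1.0, -alpha], drive, axis=1)
    F_true = cfg.baseline_f0 * (1.0 + dff_true)

    t = np.arange(n_frames)
    slow = cfg.neuropil_baseline * cfg.neuropil_slow_amp * np.sin(2 * np.pi * t / max(n_frames, 2))
    background = cfg.neuropil_baseline + slow
    N = background[None, :] + rng.normal(scale=cfg.neuropil_sd, size=F_true.shape)
    if k_true is None:
        k_true = np.zeros(F_true.shape[0])
    k_true = np.asarray(k_true, dtype=float)
    R = F_true + k_true[:, None] * N
    return RawTraceSet(R=np.clip(R, 0, None), N=np.clip(N, 0, None), frame_rate_hz=cfg.frame_rate_hz)


def generate_session(cfg: SessionConfig, mixture=(0.5, 0.5, 0.0), seed=None, tabulated_tuning=None) -> SyntheticSession:
    """Sample a population, simulate its trials, and render raw traces."""
    base = cfg.seed if seed is None else seed
    pop = sample_population(cfg, mixture=mixture, seed=base, tabulated_tuning=tabulated_tuning)
    table, amplitudes = simulate_trials(pop, cfg, seed=base + 1)
    k_true = np.array([n_.contamination_k_true for n_ in pop])
    raw = render_traces(amplitudes, table, cfg, seed=base + 2, k_true=k_true)
    return SyntheticSession(
        config=cfg, trial_table=table, raw=raw, truth=pop, true_trial_amplitudes=amplitudes
    )


def window_attenuation(cfg: SessionConfig) -> float:
    """Mean of the rendered boxcar⊗kernel shape over the stimulus window.

    The trial-response extraction averages ΔF/F over the stimulus window, so a
    rendered amplitude A is recovered as A times this factor.  Computed by
    rendering a unit amplitude through the same filter used by
    :func:`render_traces`.
    """
    alpha = float(np.exp(-1.0 / (cfg.kernel_tau_s * cfg.frame_rate_hz)))
    drive = np.zeros(cfg.stim_frames)
    drive[:] = 1.0
    shape = signal.lfilter([1.0 - alpha], [1.0, -alpha], drive)
    return float(shape.mean())


# ---------------------------------------------------------------------------
# session container I/O (HDF5 + trials.tsv mirror)
# ---------------------------------------------------------------------------

def write_session(session: SyntheticSession, path):
    """Write a session to an HDF5 container (groups /traces, /trials, /truth)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config_json"] = json.dumps(asdict(session.config))
        g = f.create_group("traces")
        g.create_dataset("R", data=session.raw.R)
        g.create_dataset("N", data=session.raw.N)
        g.attrs["frame_rate_hz"] = session.raw.frame_rate_hz
        g = f.create_group("trials")
        df = session.trial_table.df
        for col in df.columns:
            vals = df[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)
        g.attrs["columns"] = json.dumps(list(df.columns))
        g.attrs["stim_duration_s"] = session.trial_table.stim_duration_s
        g.attrs["iti_s"] = session.trial_table.iti_s
        g = f.create_group("truth")
        pop = session.truth
        n_el = session.config.n_elements
        kinds = np.array([p.kind for p in pop], dtype="S")
        g.create_dataset("kind", data=kinds)
        W = np.full((len(pop), n_el), np.nan)
        h = np.full(len(pop), np.nan)
        a = np.full(len(pop), np.nan)
        n_cond = 2**n_el - 1
        tab = np.full((len(pop), n_cond), np.nan)
        for i, p in enumerate(pop):
            if p.kind == "ln":
                W[i], h[i], a[i] = p.ln_params.w, p.ln_params.h, p.ln_params.a
            else:
                tab[i] = p.tabulated_tuning
        g.create_dataset("w", data=W)
        g.create_dataset("h", data=h)
        g.create_dataset("a", data=a)
        g.create_dataset("tabulated_tuning", data=tab)
        g.create_dataset("trial_noise_sd", data=np.array([p.trial_noise_sd for p in pop]))
        g.create_dataset("contamination_k_true", data=np.array([p.contamination_k_true for p in pop]))
        f.create_dataset("true_trial_amplitudes", data=session.true_trial_amplitudes)


def read_session(path) -> SyntheticSession:
    """Read a session container written by :func:`write_session`.

    Raises an informative I/O error naming any missing block, and a version
    error on schema mismatch.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise IOError(f"cannot open session file {path}: {e}") from e
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise IOError(
                f"session schema version mismatch in {path}: "
                f"found {version!r}, expected {SCHEMA_VERSION}"
            )
        for block in ("traces", "trials", "truth", "true_trial_amplitudes"):
            if block not in f:
                raise IOError(f"session file {path} is missing block '/{block}'")
        cfg = SessionConfig(**json.loads(f.attrs["config_json"]))
        g = f["traces"]
        for ds in ("R", "N"):
            if ds not in g:
                raise IOError(f"session file {path} is missing dataset '/traces/{ds}'")
        raw = RawTraceSet(R=g["R"][()], N=g["N"][()], frame_rate_hz=float(g.attrs["frame_rate_hz"]))
        g = f["trials"]
        cols = json.loads(g.attrs["columns"])
        data = {}
        for col in cols:
            vals = g[col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            data[col] = vals
        table = TrialTable(
            df=pd.DataFrame(data),
            stim_duration_s=float(g.attrs["stim_duration_s"]),
            iti_s=float(g.attrs["iti_s"]),
        )
        g = f["truth"]
        pop = []
        kinds = g["kind"][()].astype(str)
        for i, kind in enumerate(kinds):
            if kind == "ln":
                pop.append(
                    GroundTruthNeuron(
                        kind="ln",
                        ln_params=LNParams(
                            w=g["w"][i],
                            h=float(g["h"][i]),
                            a=float(g["a"][i]),
                            noise_sd=float(g["trial_noise_sd"][i]),
                        ),
                        trial_noise_sd=float(g["trial_noise_sd"][i]),
                        contamination_k_true=float(g["contamination_k_true"][i]),
                    )
                )
            else:
                pop.append(
                    GroundTruthNeuron(
                        kind="tabulated",
                        tabulated_tuning=g["tabulated_tuning"][i],
                        trial_noise_sd=float(g["trial_noise_sd"][i]),
                        contamination_k_true=float(g["contamination_k_true"][i]),
                    )
                )
        amps = f["true_trial_amplitudes"][()]
    return SyntheticSession(config=cfg, trial_table=table, raw=raw, truth=pop, true_trial_amplitudes=amps)
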