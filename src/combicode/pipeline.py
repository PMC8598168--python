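"""End-to-end reproducible runs: simulate -> preprocess -> respond -> tune ->
fit LN -> surrogate controls, with every artifact stamped by seed and config.

`run_pipeline` executes the stages on a synthetic session (or one loaded from
an HDF5 container) and writes TSV/JSON artifacts plus the resolved
configuration; `report` renders the population matrices, the sorted
linear-difference curve, the supra/sub scatter, and the model-comparison
summary as PNG figures.  Reruns with the same config and seed produce
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lnmodel import compare_models, evaluate_fit, fit_ln
from .responses import apply_outlier_rule, responsiveness, speed_outlier_filter, state_filter, trial_responses
from .stimuli import design_matrix
from .synth import SessionConfig, generate_session, read_session
from .traces import dff_catch_baseline, neuropil_correct
from .tuning import (
    linear_difference,
    partition_trials,
    population_matrices,
    sorted_linear_difference,
    supralinearity_test,
    tuning_curve,
)
from .validation import surrogate_battery


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    input_path: str = None  # read an HDF5 session instead of simulating
    outdir: str = "combicode_run"
    mixture: tuple = (0.5, 0.5, 0.0)
    state_mode: str = "running"
    alpha: float = 0.05
    scheme: str = "halves"
    r_thresh: float = 0.5
    n_boot_ci: int = 1000
    n_boot_test: int = 2000
    supra_alpha: float = 0.01
    run_surrogates: bool = True
    run_ln_fits: bool = True
    seed: int = 0

    def validate(self):
        if self.scheme not in ("halves", "thirds"):
            raise ConfigError(f"RunConfig.scheme must be 'halves' or 'thirds', got {self.scheme!r}")
        if self.state_mode not in ("running", "stationary"):
            raise ConfigError(f"RunConfig.state_mode must be 'running' or 'stationary', got {self.state_mode!r}")
        for name in ("alpha", "supra_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"RunConfig.{name} must be in (0, 1), got {v}")
        return self

    def to_dict(self):
        d = asdict(self)
        d["mixture"] = list(self.mixture)
        return d


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate"
        if cfg.input_path:
            session = read_session(cfg.input_path)
        else:
            session = generate_session(cfg.session, mixture=cfg.mixture, seed=cfg.seed)
        space = session.space()
        session.trial_table.to_tsv(out / "trials.tsv")

        stage = "preprocess"
        corrected = neuropil_correct(session.raw)
        dff = dff_catch_baseline(corrected, session.trial_table)

        stage = "respond"
        resp = trial_responses(
            dff.dff, dff.frame_rate_hz, session.trial_table, space,
            window_s=session.config.stim_duration_s,
        )
        resp.state_mask = state_filter(session.trial_table, mode=cfg.state_mode)
        resp.state_mask = speed_outlier_filter(session.trial_table, resp.state_mask)
        resp = apply_outlier_rule(resp)
        sig = responsiveness(resp, alpha=cfg.alpha)
        sig_rows = []
        labels31 = space.labels()[:-1]
        for i in range(resp.n_neurons):
            for j, lab in enumerate(labels31):
                sig_rows.append(
                    dict(neuron=i, condition=lab, mean=sig.means[i, j], p=sig.pvals[i, j],
                         significant=bool(sig.significant[i, j]))
                )
        _write_tsv(pd.DataFrame(sig_rows), out / "significance.tsv")
        _write_tsv(
            pd.DataFrame({"neuron": range(resp.n_neurons), "class": sig.neuron_class,
                          "responsive": sig.responsive}),
            out / "neuron_classes.tsv",
        )

        stage = "tune"
        parts = partition_trials(
            session.trial_table,
            n_parts=2 if cfg.scheme == "halves" else 3,
            balance_keys=("pupil_diameter", "pupil_x", "pupil_y"),
            seed=cfg.seed + 11,
            state_mask=resp.state_mask,
        )
        curves = [tuning_curve(resp, i, n_boot=cfg.n_boot_ci, seed=cfg.seed + i) for i in range(resp.n_neurons)]
        tun_rows = []
        for i, c in enumerate(curves):
            ld = linear_difference(c)
            multis = list(space.multis)
            for j, lab in enumerate(labels31):
                cond = space.non_catch[j]
                tun_rows.append(
                    dict(neuron=i, condition=lab, value=c.values[j],
                         ci_low=c.ci_low[j], ci_high=c.ci_high[j],
                         ld=ld[multis.index(cond)] if cond.is_multi else np.nan)
                )
        _write_tsv(pd.DataFrame(tun_rows), out / "tuning.tsv")

        pm_t, pm_ld = population_matrices(resp, parts, scheme=cfg.scheme, r_thresh=cfg.r_thresh, seed=cfg.seed)
        np.savetxt(out / "population_tuning.tsv", pm_t.matrix, delimiter="\t")
        np.savetxt(out / "population_ld.tsv", pm_ld.matrix, delimiter="\t")
        rank_means, n_multi_pref = sorted_linear_difference(resp, parts, scheme=cfg.scheme, r_thresh=cfg.r_thresh)
        _write_tsv(
            pd.DataFrame({"rank": np.arange(1, rank_means.size + 1), "mean_ld": rank_means}),
            out / "sorted_ld.tsv",
        )

        stage = "supralinearity"
        if cfg.scheme == "halves":
            train_mask, test_mask = parts == 0, parts == 1
        else:
            train_mask, test_mask = np.isin(parts, (0, 1)), parts == 2
        supra_rows = []
        for row, neuron in enumerate(pm_ld.row_neurons):
            r = supralinearity_test(
                resp, int(neuron), train_mask, test_mask,
                n_boot=cfg.n_boot_test, alpha=cfg.supra_alpha, seed=cfg.seed + 31 * int(neuron),
            )
            supra_rows.append(
                dict(neuron=int(neuron), ld_top=r.ld_top, ld_nontop_mean=r.ld_nontop_mean,
                     label=r.label, p_supra=r.p_supra, p_sub=r.p_sub, reason=r.reason)
            )
        _write_tsv(pd.DataFrame(supra_rows), out / "supralinearity.tsv")

        stage = "fit-ln"
        comparison = None
        if cfg.run_ln_fits:
            X = design_matrix(space)
            reports = []
            fit_rows = []
            for i in range(resp.n_neurons):
                train_c = tuning_curve(resp, i, ci=False, subset=train_mask)
                test_c = tuning_curve(resp, i, ci=False, subset=test_mask)
                if np.isfinite(train_c.values).sum() < space.n_elements + 2:
                    continue
                rep = fit_ln(train_c.values, X, seed=cfg.seed + i)
                rep = evaluate_fit(rep, X, test_c.values, train_c.values)
                reports.append(rep)
                fit_rows.append(
                    dict(neuron=i, **{f"w{j}": rep.params.w[j] for j in range(space.n_elements)},
                         h=rep.params.h, a=rep.params.a, train_sse=rep.train_sse,
                         test_r2_glm=rep.test_r2_glm, test_r2_oracle=rep.test_r2_oracle)
                )
            _write_tsv(pd.DataFrame(fit_rows), out / "ln_fits.tsv")
            comp = compare_models(reports)
            comparison = dict(
                n=comp["n"], median_delta_r2=comp["median_delta_r2"],
                p=None if np.isnan(comp["p"]) else comp["p"],
                oracle_r2_thresh=0.5, seed=cfg.seed,
            )
            (out / "model_comparison.json").write_text(json.dumps(comparison, indent=2))

        stage = "surrogate"
        if cfg.run_surrogates:
            reps = surrogate_battery(
                resp, parts, scheme=cfg.scheme, r_thresh=cfg.r_thresh,
                n_boot=max(500, cfg.n_boot_test // 2), alpha=cfg.supra_alpha, seed=cfg.seed + 101,
            )
            payload = {
                mode: dict(
                    enrichment=None if np.isnan(r.enrichment) else r.enrichment,
                    frac_supra_flagged=None if np.isnan(r.frac_supra_flagged) else r.frac_supra_flagged,
                    per_session_top_vs_nontop=r.per_session_top_vs_nontop,
                    n_neurons_gated=r.n_neurons_gated,
                    n_neurons_tested=r.n_neurons_tested,
                )
                for mode, r in reps.items()
            }
            (out / "surrogates.json").write_text(json.dumps(payload, indent=2))

        resolved = cfg.to_dict()
        resolved["code_version"] = __version__
        (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    except ConfigError:
        raise
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
    return out


def report(outdir, figdir=None) -> Path:
    """Render figures from a pipeline output directory (PNG, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    figdir = Path(figdir) if figdir else out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    warnings = []

    def _panel(fname, draw):
        fig, ax = plt.subplots(figsize=(5, 4))
        draw(ax)
        fig.tight_layout()
        fig.savefig(figdir / fname, dpi=120)
        plt.close(fig)

    for name, title in (("population_tuning.tsv", "Cross-validated tuning"),
                        ("population_ld.tsv", "Cross-validated linear difference")):
        p = out / name
        if not p.exists():
            warnings.append(f"missing {name}")
            continue
        M = np.loadtxt(p, delimiter="\t", ndmin=2)

        def draw(ax, M=M, title=title):
            if M.size == 0:
                ax.text(0.5, 0.5, "zero neurons passed the reliability gate", ha="center")
            else:
                ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1, interpolation="nearest")
            ax.set_xlabel("condition (canonical order)")
            ax.set_ylabel("neuron (sorted by preferred stimulus)")
            ax.set_title(title)

        _panel(name.replace(".tsv", ".png"), draw)

    p = out / "sorted_ld.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")

        def draw(ax):
            ax.axhline(0, color="gray", lw=0.5)
            ax.plot(df["rank"], df["mean_ld"], "o-")
            ax.set_xlabel("stimulus rank (training partition)")
            ax.set_ylabel("mean held-out linear difference")
            ax.set_title("Sorted linear difference")

        _panel("sorted_ld.png", draw)
    else:
        warnings.append("missing sorted_ld.tsv")

    p = out / "supralinearity.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")

        def draw(ax):
            colors = {"supra": "crimson", "sub": "royalblue", "ns": "lightgray"}
            for lab, sub in df.groupby("label"):
                ax.scatter(sub["ld_nontop_mean"], sub["ld_top"], s=12,
                           c=colors.get(lab, "k"), label=lab)
            lim = np.nanmax(np.abs(df[["ld_top", "ld_nontop_mean"]].to_numpy())) if len(df) else 1
            ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.5)
            ax.set_xlabel("mean LD, non-top stimuli")
            ax.set_ylabel("LD, top-ranked stimulus")
            ax.legend(fontsize=8)
            ax.set_title("Selective supra-linearity")

        _panel("supralinearity.png", draw)
    else:
        warnings.append("missing supralinearity.tsv")

    (figdir / "report.json").write_text(json.dumps({"warnings": warnings}, indent=2))
    return figdir
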