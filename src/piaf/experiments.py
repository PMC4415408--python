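"""Named experiment presets, a config loader, and end-to-end runners.

Each preset reproduces one of the stock simulation studies: single-method
tracking demonstrations, the process-noise sweep, the PIAF-vs-RLS and
PIAF-vs-Kalman comparisons, and the three-architecture comparison in which
the closed Kalman↔RLS feedback loop stagnates (the self-delusional loop).
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import ValidationError

from . import evaluation as ev
from .evaluation import ExperimentConfig, MseCurves

logger = logging.getLogger(__name__)

__all__ = ["PRESETS", "run_preset", "load_config", "save_config"]

SCHEMA_VERSION = 1

_BASE = dict(sigma_s=2.0, w=1.0, T=50)

#: Preset catalog.  `variants` is a list of (label, config-overrides); every
#: variant of a preset shares the same seed so methods are compared on
#: identical simulated episodes where the regime and noise match.
PRESETS: dict[str, dict] = {
    "fig4": {
        "doc": "Single-method tracking demonstrations, with/without process "
        "noise, both control regimes.",
        "common": dict(_BASE, method="piaf", N=1000, n_runs=100),
        "variants": [
            ("a_sin_p0", dict(control="sinusoidal", sigma_p=0.0)),
            ("b_sin_p0.1", dict(control="sinusoidal", sigma_p=0.1)),
            ("c_rand_p0", dict(control="gaussian", sigma_p=0.0)),
            ("d_rand_p0.1", dict(control="gaussian", sigma_p=0.1)),
        ],
    },
    "fig5": {
        "doc": "PIAF accuracy across process-noise levels, sinusoidal control.",
        "common": dict(_BASE, method="piaf", control="sinusoidal", N=10_000,
                       n_runs=1000),
        "variants": [
            (f"sp{sp}", dict(sigma_p=sp))
            for sp in (0.0, 0.001, 0.01, 0.1, 0.2, 0.5, 1.0)
        ],
    },
    "fig6": {
        "doc": "Weight learning: PIAF vs independence-assuming RLS, both regimes.",
        "common": dict(_BASE, sigma_p=0.1, N=10_000, n_runs=1000),
        "variants": [
            ("piaf_sin", dict(method="piaf", control="sinusoidal")),
            ("rls_sin", dict(method="rls", control="sinusoidal")),
            ("piaf_rand", dict(method="piaf", control="gaussian")),
            ("rls_rand", dict(method="rls", control="gaussian")),
        ],
    },
    "fig7": {
        "doc": "State tracking: PIAF vs the Kalman filter that knows w.",
        "common": dict(_BASE, sigma_p=0.01, N=10_000, n_runs=1000,
                       thresholds=[0.1]),
        "variants": [
            ("piaf_sin", dict(method="piaf", control="sinusoidal")),
            ("kalman_sin", dict(method="kalman", control="sinusoidal")),
            ("piaf_rand", dict(method="piaf", control="gaussian")),
            ("kalman_rand", dict(method="kalman", control="gaussian")),
        ],
    },
    "fig9": {
        "doc": "Three architectures (PIAF, RLS→Kalman, Kalman↔RLS), both regimes.",
        "common": dict(_BASE, sigma_p=0.01, N=100_000, n_runs=300,
                       thresholds=[10**-1.5, 1e-2, 10**-2.5, 1e-3]),
        "variants": [
            ("piaf_sin", dict(method="piaf", control="sinusoidal")),
            ("rls_to_kalman_sin", dict(method="rls_to_kalman",
                                       control="sinusoidal")),
            ("kalman_rls_loop_sin", dict(method="kalman_rls_loop",
                                         control="sinusoidal")),
            ("piaf_rand", dict(method="piaf", control="gaussian")),
            ("rls_to_kalman_rand", dict(method="rls_to_kalman",
                                        control="gaussian")),
            ("kalman_rls_loop_rand", dict(method="kalman_rls_loop",
                                          control="gaussian")),
        ],
    },
    "fig10": {
        "doc": "Individual runs of the three architectures, sinusoidal control; "
        "stagnation onset and endpoint spread of the feedback loop.",
        "common": dict(_BASE, sigma_p=0.01, control="sinusoidal", N=100_000,
                       n_runs=50, thresholds=[1e-3]),
        "variants": [
            ("piaf", dict(method="piaf")),
            ("rls_to_kalman", dict(method="rls_to_kalman")),
            ("kalman_rls_loop", dict(method="kalman_rls_loop")),
        ],
    },
}


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config from a flat YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    try:
        return ExperimentConfig(**raw)
    except ValidationError as err:
        fields = ", ".join(
            ".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: check field(s) {fields}") from err


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def _summary_for(
    label: str, cfg: ExperimentConfig, curves: MseCurves, per_run
) -> dict:
    cal = ev.variance_calibration(curves)
    early = slice(9, min(3000, cfg.N))
    late_start = int(0.8 * cfg.N)
    entry = {
        "label": label,
        "method": cfg.method,
        "control": cfg.control,
        "sigma_p": cfg.sigma_p,
        "n_runs": cfg.n_runs,
        "N": cfg.N,
        "final_mse_w": float(curves.mse_w[-1]),
        "final_mse_z": float(curves.mse_z[-1]),
        "plateau_mse_z": ev.plateau_mse(curves.mse_z),
        "plateau_mse_w": ev.plateau_mse(np.maximum(curves.mse_w, 1e-300)),
        "crossings_w": {
            str(t): float(ev.first_crossing(curves.mse_w, t)) for t in cfg.thresholds
        },
        "calibration_z_max_early": float(np.nanmax(cal["ratio_z"].values[early])),
        "calibration_z_late": float(np.nanmean(cal["ratio_z"].values[late_start:])),
    }
    if per_run is not None:
        finals = [
            ev.plateau_mse(np.maximum(per_run.se_w[:, k], 1e-300))
            for k in range(per_run.se_w.shape[1])
        ]
        entry["per_run_final_w_mse_p90_over_p10"] = float(
            np.percentile(finals, 90) / max(np.percentile(finals, 10), 1e-300)
        )
    return entry


def run_preset(
    name: str,
    overrides: dict | None = None,
    out_dir="results",
    seed: int | None = None,
    plots: bool = False,
) -> dict:
    """Execute a named preset: one Monte-Carlo curve set per variant.

    Writes one CSV of replicate-averaged curves per variant plus a
    machine-readable ``summary.json`` (crossings, speedups vs PIAF where a
    PIAF variant with matching regime exists, plateau ratios, calibration
    extrema, stagnation statistics).  ``overrides`` (e.g. ``{"n_runs": 100}``)
    apply to every variant; an unknown key is rejected.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    preset = copy.deepcopy(PRESETS[name])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    overrides = dict(overrides or {})
    if seed is not None:
        overrides["seed"] = seed
    allowed = set(ExperimentConfig.model_fields)
    for key in overrides:
        if key not in allowed:
            raise KeyError(f"invalid override key {key!r}")

    results: dict[str, tuple[ExperimentConfig, MseCurves]] = {}
    entries = []
    t0 = time.perf_counter()
    for label, var in preset["variants"]:
        cfg = ExperimentConfig(**{**preset["common"], **var, **overrides})
        logger.info("preset %s / %s: %s", name, label,
                    cfg.model_dump(exclude={"thresholds"}))
        need_per_run = cfg.method in ("rls_to_kalman", "kalman_rls_loop")
        if need_per_run:
            curves, per_run = ev.mse_curves(cfg, return_per_run=True)
        else:
            curves, per_run = ev.mse_curves(cfg), None
        curves.to_csv(out_dir / f"{name}_{label}.csv")
        results[label] = (cfg, curves)
        entries.append(_summary_for(label, cfg, curves, per_run))

    # pairwise comparisons against the PIAF variant of the same regime
    speedups = []
    plateau_ratios = []
    piaf_by_control = {
        cfg.control: curves for (cfg, curves) in results.values()
        if cfg.method == "piaf"
    }
    for label, (cfg, curves) in results.items():
        if cfg.method == "piaf" or cfg.control not in piaf_by_control:
            continue
        ref = piaf_by_control[cfg.control]
        for t in cfg.thresholds:
            speedups.append(
                {
                    "slow": label,
                    "fast": f"piaf ({cfg.control})",
                    "channel": "mse_w",
                    "threshold": t,
                    "factor": float(ev.speedup_factor(curves.mse_w, ref.mse_w, t)),
                }
            )
        try:
            plateau_ratios.append(
                {
                    "label": label,
                    "channel": "mse_z",
                    "ratio_vs_piaf": float(
                        ev.plateau_mse(curves.mse_z) / ev.plateau_mse(ref.mse_z)
                    ),
                }
            )
        except ValueError:
            pass

    summary = {
        "schema_version": SCHEMA_VERSION,
        "preset": name,
        "doc": preset["doc"],
        "overrides": overrides,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "curves": entries,
        "speedups": speedups,
        "plateau_ratios": plateau_ratios,
    }
    with open(out_dir / f"{name}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    if plots:
        _plot_preset(name, results, out_dir)
    return summary


def _plot_preset(name, results, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for channel in ("mse_w", "mse_z"):
        fig, ax = plt.subplots(figsize=(7, 5))
        for label, (cfg, curves) in results.items():
            y = getattr(curves, channel)
            if np.all(y <= 0):
                continue
            ax.loglog(curves.iteration, np.maximum(y, 1e-300), label=label)
        ax.set_xlabel("iteration")
        ax.set_ylabel(channel)
        ax.set_title(f"{name}: {channel}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"{name}_{channel}.png", dpi=110)
        plt.close(fig)
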