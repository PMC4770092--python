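"""End-to-end pipeline: simulate → detect → rates → Bell fits → energies.

The pipeline exists to exercise the full analysis chain on synthetic
passive-mode data with known ground truth and produce one
machine-readable JSON report.  Every stochastic step derives its seed
deterministically from the global seed, so a config runs to a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np

from . import __version__
from .detect import extract_dwells, fit_hmm, viterbi_path
from .elasticity import DEFAULT_DNA, TetherModel
from .energetics import dG_from_rates
from .kinetics import (
    extrapolate_zero_force,
    fit_bell_global_closing,
    fit_bell_global_opening,
    rates_from_dwells,
)
from .synthetic import TraceSimConfig, render_trace, simulate_state_path

DEFAULT_CONFIG = {
    "seed": 1,
    "ligand": "AP5A",
    "concentration_unit": "nM",
    "concentrations": [100.0, 300.0],
    "trap_separations": [380.0, 397.0, 412.0, 427.0],
    "duration_s": 6.0,
    "k_close_per_conc": 0.18,
    "delta_x_close": -0.1,
    "k_open": 1.0,
    "delta_x_open": 1.5,
    "contraction_nm": 1.6,
    "trap_k1": 0.3,
    "trap_k2": 0.3,
    "noise_amplitude_nm": 0.4,
    "noise_corner_hz": 5000.0,
    "sampling_rate_hz": 150000.0,
    "average_to_hz": 30000.0,
    "detect_method": "hmm",  # "hmm" | "truth"
    "bootstrap": 200,
}


def load_config(path) -> dict:
    """Parse a ``key = value`` config file (values JSON where possible)."""
    config = dict(DEFAULT_CONFIG)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key = key.strip()
        value = value.strip()
        try:
            config[key] = json.loads(value)
        except (json.JSONDecodeError, ValueError):
            config[key] = value
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _condition_seed(global_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([int(global_seed), index]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns the JSON-serialisable report.

    Stage failures are recorded (with the exception text) and
    downstream stages are skipped.
    """
    config = {**DEFAULT_CONFIG, **config}
    report: dict = {
        "software": {"name": "lidforce", "version": __version__},
        "config": config,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "stages": {},
        "warnings": [],
    }
    tether = TetherModel(
        dna=DEFAULT_DNA,
        trap_stiffness_1=float(config["trap_k1"]),
        trap_stiffness_2=float(config["trap_k2"]),
    )
    conditions = [
        (float(conc), float(sep))
        for conc in config["concentrations"]
        for sep in config["trap_separations"]
    ]

    closing_points, opening_points = [], []
    per_condition = []
    t0 = _time.time()
    try:
        for i, (conc, sep) in enumerate(conditions):
            sim = TraceSimConfig(
                seed=_condition_seed(config["seed"], i),
                duration=float(config["duration_s"]),
                k_close_zero_force=float(config["k_close_per_conc"]),
                delta_x_close=float(config["delta_x_close"]),
                k_open_zero_force=float(config["k_open"]),
                delta_x_open=float(config["delta_x_open"]),
                ligand_concentration=conc,
                concentration_unit=str(config["concentration_unit"]),
                ligand=str(config["ligand"]),
                protein_contraction=float(config["contraction_nm"]),
                protein_extension_open=float(config["contraction_nm"]),
                trap_separation=sep,
                tether=tether,
                sampling_rate=float(config["sampling_rate_hz"]),
                average_to=float(config["average_to_hz"]),
                noise_amplitude=float(config["noise_amplitude_nm"]),
                noise_corner_hz=float(config["noise_corner_hz"]),
            )
            path = simulate_state_path(sim)
            if config["detect_method"] == "truth":
                dwells = path
            else:
                rendered = render_trace(path, sim)
                trace = rendered.to_trace()
                hmm = fit_hmm(trace, open_is_high=False)
                dwells = extract_dwells(viterbi_path(hmm, trace), trace)
            closing, opening = rates_from_dwells(
                dwells, n_bootstrap=int(config["bootstrap"]),
                seed=_condition_seed(config["seed"], 10_000 + i),
            )
            closing_points.append(closing)
            opening_points.append(opening)
            F_open, F_closed = sim.state_forces()
            per_condition.append({
                "concentration": conc,
                "trap_separation_nm": sep,
                "n_dwells": len(dwells),
                "force_open_pN": F_open,
                "force_closed_pN": F_closed,
                "closing_rate_per_s": closing.rate,
                "closing_se": closing.se,
                "opening_rate_per_s": opening.rate,
                "opening_se": opening.se,
                "dG_open_to_closed_kBT": dG_from_rates(closing.rate, opening.rate),
            })
        report["stages"]["simulate_detect_rates"] = {
            "status": "ok",
            "seconds": round(_time.time() - t0, 3),
            "conditions": per_condition,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        report["stages"]["simulate_detect_rates"] = {
            "status": "failed", "error": f"{type(exc).__name__}: {exc}",
        }
        report["stages"]["bell_fits"] = {"status": "skipped"}
        return report

    t0 = _time.time()
    try:
        closing_fit = fit_bell_global_closing(closing_points)
        opening_fit = fit_bell_global_opening(opening_points)
        truth_k_close = {
            float(c): float(config["k_close_per_conc"]) * float(c)
            for c in config["concentrations"]
        }
        report["stages"]["bell_fits"] = {
            "status": "ok",
            "seconds": round(_time.time() - t0, 3),
            "closing": {
                "delta_x_nm": closing_fit.delta_x,
                "delta_x_se": closing_fit.delta_x_se,
                "k0_per_s": {str(c): v for c, v in closing_fit.k0.items()},
                "k0_se": {str(c): v for c, v in closing_fit.k0_se.items()},
                "zero_force": {
                    str(c): list(v) for c, v in
                    extrapolate_zero_force(closing_fit).items()
                },
                "truth_delta_x_nm": float(config["delta_x_close"]),
                "truth_k0_per_s": {str(c): v for c, v in truth_k_close.items()},
            },
            "opening": {
                "delta_x_nm": opening_fit.delta_x,
                "delta_x_se": opening_fit.delta_x_se,
                "k0_per_s": {str(c): v for c, v in opening_fit.k0.items()},
                "k0_se": {str(c): v for c, v in opening_fit.k0_se.items()},
                "truth_delta_x_nm": float(config["delta_x_open"]),
                "truth_k0_per_s": float(config["k_open"]),
            },
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"]["bell_fits"] = {
            "status": "failed", "error": f"{type(exc).__name__}: {exc}",
        }
    return report


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return path


def summarise(report: dict) -> str:
    """Short human-readable summary of a pipeline report."""
    lines = [
        f"lidforce {report['software']['version']}  "
        f"config {report['config_hash']}  seed {report['seed']}"
    ]
    for name, stage in report["stages"].items():
        lines.append(f"[{stage['status']}] {name}"
                     + (f" ({stage.get('seconds', '?')} s)" if stage.get("seconds") else ""))
        if stage["status"] == "failed":
            lines.append(f"    {stage['error']}")
    bells = report["stages"].get("bell_fits", {})
    if bells.get("status") == "ok":
        c, o = bells["closing"], bells["opening"]
        lines.append(
            f"closing: dx = {c['delta_x_nm']:.3f} +/- {c['delta_x_se']:.3f} nm "
            f"(truth {c['truth_delta_x_nm']})"
        )
        lines.append(
            f"opening: dx = {o['delta_x_nm']:.3f} +/- {o['delta_x_se']:.3f} nm "
            f"(truth {o['truth_delta_x_nm']}), "
            f"k0 = {list(o['k0_per_s'].values())[0]:.3f} /s (truth {o['truth_k0_per_s']})"
        )
    return "\n".join(lines)
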