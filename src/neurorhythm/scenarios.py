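"""Scenario orchestration: configuration, end-to-end runs, artifact bundles.

A scenario is one experiment: pick a rhythm model, integrate the
reference trajectory, split the dataset 80/10/10, train the surrogate
with LM or BR (optionally restarting from several seeds and keeping the
best final training fit), and evaluate the metric battery.  Every
artifact is stamped with a hash of the resolved configuration so bundles
from different scenarios cannot be compared by accident.

The six default study scenarios are the three rhythm models crossed with
the two trainers, at hidden widths 20/20/20 (LM) and 50/100/100 (BR).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import io as nio
from .identify import add_measurement_noise, estimate_derivatives, fit_coefficients
from .integrate import Dataset, build_grid, generate_dataset, integrate_adams
from .metrics import error_histogram, evaluate_fit, phase_portrait_data
from .models import make_pdi_model
from .network import forward, init_network, save_network
from .training import TrainConfig, split_dataset, train_br, train_lm

__all__ = [
    "ScenarioConfig",
    "DEFAULT_SCENARIOS",
    "load_config",
    "run_scenario",
    "compare_trainers",
]

log = logging.getLogger("neurorhythm")

#: Hidden widths of the six default study scenarios, keyed (model, trainer).
DEFAULT_SCENARIOS: dict[tuple[int, str], int] = {
    (1, "lm"): 20, (2, "lm"): 20, (3, "lm"): 20,
    (1, "br"): 50, (2, "br"): 100, (3, "br"): 100,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated description of one experiment."""

    model: Optional[int] = None          # built-in model id, or None with model_file
    model_file: Optional[str] = None     # structured JSON coefficient file
    trainer: str = "lm"
    hidden: Optional[int] = None         # default: the study width for (model, trainer)
    t0: float = 0.0
    t1: float = 5.0
    step: float = 0.02
    y0: tuple[float, ...] = (1.0, 1.0, 1.0)
    seed: int = 0
    restarts: int = 1
    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    grad_min: float = 1e-7
    max_fail: int = 6
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    sigma: float = 0.0                   # identification scenarios only
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.model is None) == (self.model_file is None):
            raise ValueError("exactly one of model / model_file must be given")
        if self.model is not None and self.model not in (1, 2, 3):
            raise ValueError(f"model must be 1, 2 or 3, got {self.model}")
        if self.trainer not in ("lm", "br"):
            raise ValueError(f"trainer must be 'lm' or 'br', got {self.trainer!r}")
        if self.step <= 0 or self.t1 <= self.t0 or self.step > self.t1 - self.t0:
            raise ValueError("invalid time grid: need t1 > t0 and 0 < step <= span")
        if self.hidden is not None and self.hidden < 1:
            raise ValueError("hidden width must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "y0", tuple(float(v) for v in self.y0))
        object.__setattr__(self, "fractions", tuple(float(v) for v in self.fractions))

    @property
    def resolved_hidden(self) -> int:
        if self.hidden is not None:
            return self.hidden
        if self.model is not None and (self.model, self.trainer) in DEFAULT_SCENARIOS:
            return DEFAULT_SCENARIOS[(self.model, self.trainer)]
        return 20

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs, mu0=self.mu0, mu_inc=self.mu_inc,
            mu_dec=self.mu_dec, mu_max=self.mu_max, grad_min=self.grad_min,
            max_fail=self.max_fail, trainer=self.trainer,
        )

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path, **overrides) -> ScenarioConfig:
    """Read a YAML or JSON scenario file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    raw.update(overrides)
    known = {f.name for f in fields(ScenarioConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return ScenarioConfig(**raw)


def _resolve_model(config: ScenarioConfig):
    if config.model is not None:
        return make_pdi_model(config.model), f"pdi-{config.model}"
    return nio.read_model_json(config.model_file), Path(config.model_file).stem


def build_scenario_dataset(config: ScenarioConfig) -> Dataset:
    """Integrate the configured model over the configured grid (the
    pre-flight boundedness check is the integration itself: a blow-up
    aborts before any training)."""
    model, model_id = _resolve_model(config)
    grid = build_grid(config.t0, config.t1, config.step)
    return generate_dataset(model, np.array(config.y0), grid, model_id=model_id)


def _train_with_restarts(config: ScenarioConfig, data: Dataset):
    """Train from `restarts` seeded initialisations, keeping the run with
    the lowest final training MSE."""
    tc = config.train_config()
    split = split_dataset(data.n, config.fractions, seed=config.seed)
    best = None
    for r in range(config.restarts):
        seed = config.seed + 1000 * r
        net0 = init_network(config.resolved_hidden, data, seed=seed)
        if config.trainer == "lm":
            net, record = train_lm(net0, data, split, tc)
            br_state = None
        else:
            net, record, br_state = train_br(net0, data, split, tc)
        log.info("restart %d (seed %d): final train MSE %.4g, stop=%s",
                 r, seed, record.final_train_mse, record.stop_reason)
        if best is None or record.final_train_mse < best[1].final_train_mse:
            best = (net, record, br_state, seed)
    net, record, br_state, seed = best
    return net, record, br_state, split, seed


def run_scenario(config: ScenarioConfig, out_dir: Optional[str] = None) -> dict[str, Any]:
    """Execute generate -> split -> train -> evaluate and write the
    artifact bundle; returns the scenario summary (also written as
    ``summary.json``)."""
    t_start = time.time()
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    data = build_scenario_dataset(config)
    net, record, br_state, split, best_seed = _train_with_restarts(config, data)

    predicted = forward(net, data.inputs)
    reports = {
        tag: evaluate_fit(data.targets, predicted, subset=idx, tag=tag).to_dict()
        for tag, idx in (
            ("train", split.train), ("val", split.validation),
            ("test", split.test), ("all", None),
        )
    }
    resid = (data.targets - predicted).ravel()
    hist = error_histogram(resid)

    nio.write_dataset(data, out / "dataset.csv", out / "dataset.json")
    save_network(net, out / "network.json")
    nio.write_train_record(record, out / "train_record.csv", out / "train_record.json")
    with open(out / "metrics.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    with open(out / "histogram.csv", "w") as fh:
        fh.write("bin_left,bin_right,count\n")
        for i in range(hist.counts.size):
            fh.write(f"{hist.edges[i]!r},{hist.edges[i + 1]!r},{hist.counts[i]}\n")
    traj = integrate_adams(_resolve_model(config)[0], np.array(config.y0),
                           build_grid(config.t0, config.t1, config.step))
    for name, pts in phase_portrait_data(traj).items():
        np.savetxt(out / f"phase_{name}.csv", pts, delimiter=",",
                   header=name.replace("_", ","), comments="")

    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "model": config.model or config.model_file,
        "trainer": config.trainer,
        "hidden": config.resolved_hidden,
        "n_weights": net.n_weights,
        "seed": config.seed,
        "best_restart_seed": best_seed,
        "epochs_run": record.epochs_run,
        "stop_reason": record.stop_reason,
        "final_train_mse": record.final_train_mse,
        "best_val_mse": record.best_val_mse,
        "final_test_mse": float(record.mse_test[record.best_epoch]),
        "final_grad_norm": float(record.grad_norm[-1]) if record.epochs_run else None,
        "final_mu": float(record.mu[-1]) if record.epochs_run else None,
        "r_pooled_all": reports["all"]["r_pooled"],
        "zero_bin_center": hist.zero_bin_center,
        "dataset": {"n_inputs": data.n, "n_scalar_targets": data.n_scalar_targets},
        "wall_time_s": None,  # filled below
    }
    if br_state is not None:
        summary["br"] = {"alpha": br_state.alpha, "beta": br_state.beta,
                         "gamma": br_state.gamma, "e_w": br_state.e_w,
                         "e_d": br_state.e_d}
    summary["wall_time_s"] = round(time.time() - t_start, 3)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("scenario %s/%s done: train MSE %.4g, R(all) %.6f, %.1fs",
             summary["model"], config.trainer, summary["final_train_mse"],
             summary["r_pooled_all"], summary["wall_time_s"])
    return summary


def run_identification(config: ScenarioConfig, out_dir: Optional[str] = None) -> dict[str, Any]:
    """Simulate noisy rhythm measurements and recover the quadratic
    coefficient matrix by least squares; writes the measured channels and
    the recovered packed matrix."""
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    model, model_id = _resolve_model(config)
    grid = build_grid(config.t0, config.t1, config.step)
    traj = integrate_adams(model, np.array(config.y0), grid)
    rhythms = add_measurement_noise(traj, config.sigma, config.seed)
    d_est = fit_coefficients(rhythms.channels, estimate_derivatives(rhythms))
    nio.write_noisy_rhythms(rhythms, out / "rhythms.csv", out / "rhythms.json")
    nio.write_packed_coefficients(d_est, out / "coefficients.csv")
    from .models import pack_coefficients

    d_true = pack_coefficients(model)
    err = np.abs(d_est.entries - d_true.entries)
    summary = {
        "model": model_id,
        "sigma": config.sigma,
        "seed": config.seed,
        "max_abs_coeff_error": float(err.max()),
        "mean_abs_coeff_error": float(err.mean()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def compare_trainers(summary_a: dict, summary_b: dict) -> dict[str, Any]:
    """Side-by-side comparison of two completed scenario summaries that
    share a dataset (same model/grid provenance)."""
    if summary_a["model"] != summary_b["model"]:
        raise ValueError(
            f"cannot compare runs on different models: "
            f"{summary_a['model']!r} vs {summary_b['model']!r}"
        )
    rows = {}
    for s in (summary_a, summary_b):
        row = {
            "epochs": s["epochs_run"],
            "performance_mse": s["final_train_mse"],
            "validation_mse": s["best_val_mse"],
            "test_mse": s["final_test_mse"],
            "gradient": s["final_grad_norm"],
            "mu": s["final_mu"],
            "stop_reason": s["stop_reason"],
            "time_s": s["wall_time_s"],
        }
        if "br" in s:
            row.update({k: s["br"][k] for k in ("alpha", "beta", "gamma")})
        rows[s["trainer"]] = row
    return {"model": summary_a["model"], "trainers": rows}
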