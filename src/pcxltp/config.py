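"""Run configuration, validation and the end-to-end pipeline.

A run is described by a small YAML config (all keys optional): master seed,
output directory, the list of conditions to simulate with optional
per-condition overrides, clustering-model overrides and a log level.  The
pipeline simulates cohorts, summarises potentiation statistics, evaluates
the clustering feasibility model and writes plain-text artifacts
(JSON/TSV) plus a log recording the seed.  All randomness flows from the
single master seed; a repeated run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .occupancy import ConnectivityParams, SynapticClusteringModel
from .records import save_records
from .stats import PlasticityExperiment
from .synth import CONDITION_ORDER, CONDITION_PRESETS, simulate_ltp_experiment, spec_for_condition

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "run_pipeline"]

logger = logging.getLogger("pcxltp")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_SPEC_OVERRIDE_KEYS = {
    "true_potentiation_factor",
    "n_cells",
    "within_cell_cv",
    "between_cell_sd",
    "rmp_drift_mV",
    "baseline_mean_mV",
    "baseline_cv",
    "n_pre",
    "n_post",
}
_OCCUPANCY_KEYS = {f.name for f in fields(ConnectivityParams)}


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    seed: int = 0
    output_dir: str = "pcxltp_out"
    conditions: list[str] = field(default_factory=lambda: list(CONDITION_ORDER))
    condition_overrides: dict = field(default_factory=dict)
    occupancy: dict = field(default_factory=dict)
    mc_neurons: int = 100_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for cond in self.conditions:
            if cond not in CONDITION_PRESETS:
                raise ConfigError(f"unknown condition {cond!r}; known: {CONDITION_ORDER}")
        for cond, over in self.condition_overrides.items():
            if cond not in CONDITION_PRESETS:
                raise ConfigError(f"condition_overrides: unknown condition {cond!r}")
            bad = set(over) - _SPEC_OVERRIDE_KEYS
            if bad:
                raise ConfigError(
                    f"condition_overrides[{cond!r}]: unknown key(s) {sorted(bad)}; "
                    f"valid: {sorted(_SPEC_OVERRIDE_KEYS)}"
                )
            if "n_cells" in over and over["n_cells"] < 1:
                raise ConfigError(f"condition_overrides[{cond!r}]: n_cells must be >= 1")
        bad = set(self.occupancy) - _OCCUPANCY_KEYS
        if bad:
            raise ConfigError(
                f"occupancy: unknown key(s) {sorted(bad)}; valid: {sorted(_OCCUPANCY_KEYS)}"
            )
        if self.mc_neurons < 1:
            raise ConfigError("mc_neurons must be >= 1")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"unknown log_level {self.log_level!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"{path}: unknown key(s) {sorted(bad)}; valid: {sorted(known)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # wrong value type for a known key
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Simulate → summarise → clustering model, writing artifacts on disk.

    Layout under ``config.output_dir``::

        manifest.json            run metadata, seeds, versions
        records_<condition>.json simulated per-cell amplitude series
        condition_summary.tsv    per-condition potentiation statistics
        report.json              machine-readable condition summaries
        occupancy.json           exact + Monte-Carlo clustering probabilities
        run.log                  log with the master seed

    Refuses to overwrite a non-empty directory unless ``force`` is set.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True / --force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=config.log_level.upper())
    log_lines = [f"pcxltp {__version__}", f"master seed {config.seed}"]

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(len(config.conditions))
    all_records = []
    manifest = {
        "package": "pcxltp",
        "version": __version__,
        "seed": config.seed,
        "conditions": {},
    }
    for cond, child in zip(config.conditions, child_seeds):
        over = dict(config.condition_overrides.get(cond, {}))
        spec = spec_for_condition(cond, **over)
        rng = np.random.default_rng(child)
        records = simulate_ltp_experiment(spec, rng=rng)
        all_records.extend(records)
        rec_path = out / f"records_{cond}.json"
        save_records(records, rec_path)
        manifest["conditions"][cond] = {
            "n_cells": spec.n_cells,
            "true_potentiation_factor": spec.true_potentiation_factor,
            "between_cell_sd": spec.between_cell_sd,
            "within_cell_cv": spec.within_cell_cv,
            "records": rec_path.name,
        }
        log_lines.append(f"simulated {cond}: n={spec.n_cells}")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    results = PlasticityExperiment(all_records).fit()
    results.to_frame().to_csv(out / "condition_summary.tsv", sep="\t", index=False)
    report = {
        s.condition: {
            "n": s.n_cells,
            "mean_percent_of_control": s.mean_percent_of_control,
            "sem_percent": s.sem_percent,
            "t": s.t_statistic,
            "p": s.p_value,
            "excluded_n": s.n_excluded,
        }
        for s in results.summaries
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    log_lines.append(f"summarised {len(results.summaries)} conditions")

    params = ConnectivityParams(**config.occupancy)
    model = SynapticClusteringModel(params)
    exact = model.fit(method="exact")
    mc_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    mc = model.fit(method="mc", n_neurons=config.mc_neurons, seed=mc_seed)
    (out / "occupancy.json").write_text(
        json.dumps(
            {
                "params": dataclasses.asdict(params),
                "exact": {
                    "p_per_branch": exact.p_per_branch,
                    "p_any_branch": exact.p_any_branch,
                },
                "monte_carlo": {
                    "p_per_branch": mc.p_per_branch,
                    "p_any_branch": mc.p_any_branch,
                    "se_per_branch": mc.mc_se_per_branch,
                    "se_any_branch": mc.mc_se_any_branch,
                    "n_neurons": mc.n_samples,
                    "seed": mc_seed,
                },
            },
            indent=1,
        )
    )
    log_lines.append("clustering model evaluated (exact + MC)")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline complete: %s", out)
    return out
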