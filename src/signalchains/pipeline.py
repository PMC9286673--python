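"""Reproducible simulate -> measure -> fit -> report pipeline.

A run is driven by a single config (YAML or JSON) and one master seed; it
produces a chains CSV (when simulating), a per-generation metrics CSV, a
tidy growth-curve fit report, a Mantel-z significance summary, and a run
manifest sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import Chain, read_chain_table, write_chain_table
from .growth import ModelSpec, build_model_frame, fit_growth_model, significance_summary
from .simulate import SimulationConfig, simulate_experiment
from .transmission import experiment_metrics, signal_length_table

log = logging.getLogger("signalchains")


class ConfigError(ValueError):
    """A run config is structurally invalid."""


#: Dependent variables fitted by the report stage: (dv, item_level, include_size).
DEFAULT_MODEL_SET: list[tuple[str, bool, bool]] = [
    ("trials_to_criterion", False, False),
    ("cc", False, False),
    ("mantel_z", False, False),
    ("mean_nled_to_parent", False, False),
    ("mean_self_hamming", False, False),
    ("signal_length", True, True),
]


@dataclass
class RunConfig:
    """Parsed pipeline config: simulate mode or measure-only mode."""

    mode: str = "simulate"  # "simulate" | "measure"
    chains_csv: str | None = None  # measure mode input
    n_perm: int = 1000
    simulator: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"mode", "chains_csv", "n_perm", "simulator"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        mode = raw.get("mode", "simulate")
        if mode not in ("simulate", "measure"):
            raise ConfigError(f"mode must be 'simulate' or 'measure', got {mode!r}")
        if mode == "measure" and not raw.get("chains_csv"):
            raise ConfigError("measure mode requires chains_csv")
        try:
            sim = SimulationConfig.from_dict(raw.get("simulator", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"simulator: {exc}") from exc
        return cls(
            mode=mode,
            chains_csv=raw.get("chains_csv"),
            n_perm=int(raw.get("n_perm", 1000)),
            simulator=sim,
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "chains_csv": self.chains_csv,
            "n_perm": self.n_perm,
            "simulator": self.simulator.to_dict(),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fit_report(chains: list[Chain], metrics: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Fit the default growth-curve model set; one tidy row per term."""
    rows = []
    n_gen = metrics["generation"].nunique()
    if metrics["chain_id"].nunique() < 2 or n_gen < 3:
        log.info("fit stage skipped: need >= 2 chains and >= 3 generations")
        return pd.DataFrame(
            columns=["dv", "term", "estimate", "se", "z", "p", "simplification_level"]
        )
    for dv, item_level, include_size in DEFAULT_MODEL_SET:
        source = signal_length_table(chains) if item_level else metrics
        if dv in source.columns and source[dv].notna().sum() == 0:
            log.info("fit %s skipped: all values missing", dv)
            continue
        try:
            frame = build_model_frame(source, dv, item_level=item_level)
            fit = fit_growth_model(
                frame, ModelSpec(dv=dv, item_level=item_level, include_size=include_size)
            )
        except (ValueError, RuntimeError) as exc:
            log.warning("fit %s failed: %s", dv, exc)
            continue
        for _, r in fit.estimates.iterrows():
            rows.append(
                {
                    "dv": dv,
                    "term": r["term"],
                    "estimate": r["estimate"],
                    "se": r["se"],
                    "z": r["z"],
                    "p": r["p"],
                    "simplification_level": fit.simplification_level,
                }
            )
        log.info("fit %s: simplification level %d", dv, fit.simplification_level)
    return pd.DataFrame(rows)


def run_pipeline(
    config: "RunConfig | str | Path",
    out_dir,
    seed: int | None = None,
    n_perm: int | None = None,
) -> dict:
    """Execute the full pipeline and write outputs plus a run manifest.

    ``seed`` overrides the config's simulator seed; ``n_perm`` overrides
    the Mantel permutation count.  Partial outputs are removed on failure.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_file(config)
    if seed is not None:
        cfg.simulator.seed = int(seed)
    if n_perm is not None:
        cfg.n_perm = int(n_perm)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: dict[str, float] = {}

    try:
        t0 = time.time()
        if cfg.mode == "simulate":
            log.info("simulating %d chains x %d conditions",
                     cfg.simulator.n_chains, len(cfg.simulator.conditions))
            chains = simulate_experiment(cfg.simulator)
            chains_csv = out / "chains.csv"
            write_chain_table(chains, chains_csv)
            written.append(chains_csv)
        else:
            log.info("measure-only mode: reading %s", cfg.chains_csv)
            chains = read_chain_table(cfg.chains_csv)
        stages["simulate"] = time.time() - t0

        t0 = time.time()
        metrics = experiment_metrics(chains, n_perm=cfg.n_perm, seed=cfg.simulator.seed)
        metrics_csv = out / "metrics.csv"
        metrics.to_csv(metrics_csv, index=False)
        written.append(metrics_csv)
        stages["measure"] = time.time() - t0

        t0 = time.time()
        fits = fit_report(chains, metrics, seed=cfg.simulator.seed)
        fits_csv = out / "fits.csv"
        fits.to_csv(fits_csv, index=False)
        written.append(fits_csv)
        stages["fit"] = time.time() - t0

        t0 = time.time()
        summary = significance_summary(metrics)
        sig_csv = out / "significance.csv"
        merged = summary.mean_z.merge(summary.per_condition, on="condition")
        merged.to_csv(sig_csv, index=False)
        written.append(sig_csv)
        stages["report"] = time.time() - t0
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "package": "signalchains",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": cfg.simulator.seed,
        "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
        "outputs": {p.name: _sha256(p) for p in written},
    }
    manifest_path = out / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, manifest_path)  # atomic finalize
    return manifest
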