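"""One-config orchestration of the full aposematism analysis.

Four independent stages, each driven by its own input CSV and skipped (with
a logged warning) when the input is absent:

* ``spectra``  — per-genus green-component areas and absorption contrasts;
* ``behavior`` — event tabulation, pooled percentages, AIC model selection;
* ``false_prey`` — same/different contingency tables and G-tests;
* ``toxicity`` — log-logistic LC50/EC50 table with ">100%" censoring.

Every run writes a JSON manifest (config hash, input checksums, package
version, per-stage status) alongside the output tables, even when a stage
fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from . import __version__
from .behavior import ALL_COVARIATES, behavior_percentages, select_model, tabulate_actions
from .contingency import build_false_prey_tables, g_statistic
from .spectral import contrast_analysis, default_grid
from .toxicity import effective_concentration, fit_dose_response

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("bobwarn")

DEFAULT_CANDIDATES = [
    list(ALL_COVARIATES),
    ["wasp_color", "spider_type"],
    [],
]


@dataclass
class PipelineConfig:
    spectra: str | None = None
    trials: str | None = None
    false_prey: str | None = None
    dose_response: str | None = None
    lambda_max: float = 520.0
    grid: str = "400:700:1"
    reference: str = "attack"
    candidates: list = field(default_factory=lambda: [list(c) for c in DEFAULT_CANDIDATES])
    correction: str = "none"
    censor_threshold: float = 100.0
    seed: int = 0
    outdir: str = "bobwarn_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def grid_array(self) -> np.ndarray:
        try:
            start, stop, step = (float(x) for x in self.grid.split(":"))
        except ValueError as exc:
            raise ValueError(
                f"grid must be 'start:stop:step', got {self.grid!r}"
            ) from exc
        return default_grid(start, stop, step)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(df):
    """Render numerics with 6 significant digits for stable CSV output."""
    return df.map(lambda v: float(f"{v:.6g}") if isinstance(v, float) else v)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose input exists; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_hash": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
    }
    stages = {
        "spectra": (config.spectra, _run_spectra),
        "behavior": (config.trials, _run_behavior),
        "false_prey": (config.false_prey, _run_false_prey),
        "toxicity": (config.dose_response, _run_toxicity),
    }
    failed = False
    for name, (path, fn) in stages.items():
        if path is None or not Path(path).exists():
            log.warning("stage %s skipped: no input file (%s)", name, path)
            manifest["stages"][name] = {"status": "skipped"}
            continue
        manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
        t0 = time.perf_counter()
        try:
            outputs = fn(Path(path), config, outdir)
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": outputs,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        except Exception as exc:  # stage isolation: record, keep going
            failed = True
            manifest["stages"][name] = {"status": "error", "message": str(exc)}
            log.error("stage %s failed: %s", name, exc)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["ok"] = not failed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _run_spectra(path: Path, config: PipelineConfig, outdir: Path) -> list[str]:
    spectra = bio.read_spectra(path)
    table = contrast_analysis(spectra, config.lambda_max, config.grid_array())
    out = outdir / "contrast.csv"
    _fmt(table).to_csv(out, index=False)
    return [out.name]

def _run_behavior(path: Path, config: PipelineConfig, outdir: Path) -> list[str]:
    trials = bio.read_trials(path)
    counts = tabulate_actions(trials)
    pcts = behavior_percentages(trials)
    candidates = [tuple(c) for c in config.candidates]
    best, comparison = select_model(trials, candidates, reference=config.reference)
    outs = []
    for name, df in (
        ("behavior_counts.csv", counts),
        ("behavior_percentages.csv", _fmt(pcts)),
        ("model_comparison.csv", _fmt(comparison)),
    ):
        df.to_csv(outdir / name, index=False)
        outs.append(name)
    coef = best.coefficients.reset_index(names="term")
    _fmt(coef).to_csv(outdir / "best_model_coefficients.csv", index=False)
    outs.append("best_model_coefficients.csv")
    return outs


def _run_false_prey(path: Path, config: PipelineConfig, outdir: Path) -> list[str]:
    import pandas as pd

    trials = bio.read_false_prey(path)
    tables = build_false_prey_tables(trials)
    rows = []
    for name, tab in tables.items():
        res = g_statistic(tab, correction=config.correction)
        rows.append(
            {"table": name, "g": res.g, "df": res.df, "p_value": res.p_value}
        )
    out = outdir / "gtest.csv"
    _fmt(pd.DataFrame(rows)).to_csv(out, index=False)
    return [out.name]


def _run_toxicity(path: Path, config: PipelineConfig, outdir: Path) -> list[str]:
    import pandas as pd

    datasets = bio.read_dose_response(path)
    rows = []
    for ds in datasets:
        fit = fit_dose_response(ds)
        ec = effective_concentration(fit, 50.0, max_tested=config.censor_threshold)
        rows.append(
            {
                "sample_id": ds.sample_id,
                "endpoint": ds.endpoint,
                "estimate_pct": np.nan if ec.censored else ec.estimate,
                "ci_lower": np.nan if ec.censored else ec.ci_lower,
                "ci_upper": np.nan if ec.censored else ec.ci_upper,
                "censored": ec.censored,
                "report": str(ec),
            }
        )
    out = outdir / "toxicity.csv"
    _fmt(pd.DataFrame(rows)).to_csv(out, index=False)
    return [out.name]
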