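"""Plain-CSV readers and writers for every input family of the pipeline.

All dialects are long-format CSV with documented headers; reflectance may
arrive as percent (0-100) or fraction (0-1) and is auto-detected (max value
above 1.5 means percent) unless a unit override is given.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ActionEvent, Trial
from .contingency import FalsePreyTrial
from .spectral import ReflectanceSpectrum
from .toxicity import BINARY_ENDPOINTS, DoseResponseDataset

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_trials",
    "write_trials",
    "read_false_prey",
    "write_false_prey",
    "read_dose_response",
    "write_dose_response",
]

SPECTRA_COLUMNS = ["wavelength_nm", "reflectance", "genus", "patch", "replicate_id"]
TRIAL_COLUMNS = [
    "trial_id", "spider_type", "wasp_genus", "wasp_color", "wasp_length_mm",
    "spider_length_mm", "silk", "reaction_slot", "event_index", "behavior_code",
    "slot10",
]
FALSE_PREY_COLUMNS = ["background", "first_detected", "silk", "response",
                      "spider_length_mm"]
DOSE_COLUMNS = ["sample_id", "genus", "color", "endpoint", "dilution_pct",
                "replicate", "n_exposed", "n_affected", "response_fraction"]


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_spectra(path, units: str = "auto") -> list[ReflectanceSpectrum]:
    """Load long-format replicate spectra; returns one object per replicate.

    ``units`` is "auto" (percent if any value exceeds 1.5), "percent", or
    "fraction"; storage is always fractional.
    """
    if units not in ("auto", "percent", "fraction"):
        raise ValueError("units must be 'auto', 'percent' or 'fraction'")
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, SPECTRA_COLUMNS, path)
    scale = 1.0
    if units == "percent" or (units == "auto" and df["reflectance"].max() > 1.5):
        scale = 100.0
    out = []
    for (genus, patch, rep), g in df.groupby(
        ["genus", "patch", "replicate_id"], sort=True
    ):
        g = g.sort_values("wavelength_nm")
        out.append(
            ReflectanceSpectrum(
                wavelengths=g["wavelength_nm"].to_numpy(float),
                reflectance=g["reflectance"].to_numpy(float) / scale,
                genus=str(genus),
                patch=str(patch),
                replicate_id=str(rep),
            )
        )
    return out


def write_spectra(spectra: list[ReflectanceSpectrum], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "wavelength_nm": s.wavelengths,
                "reflectance": s.reflectance,
                "genus": s.genus,
                "patch": s.patch,
                "replicate_id": s.replicate_id,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path) -> list[Trial]:
    """Load live-prey trials from one-row-per-event CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, TRIAL_COLUMNS, path)
    trials = []
    for tid, g in df.groupby("trial_id", sort=True):
        g = g.sort_values("event_index")
        first = g.iloc[0]
        events = tuple(
            ActionEvent(behavior=int(r.behavior_code), slot10=str(r.slot10))
            for r in g.itertuples()
        )
        trials.append(
            Trial(
                trial_id=str(tid),
                spider_type=str(first["spider_type"]),
                wasp_color=str(first["wasp_color"]),
                wasp_genus=str(first["wasp_genus"]),
                wasp_length=float(first["wasp_length_mm"]),
                spider_length=float(first["spider_length_mm"]),
                silk_dragline=str(first["silk"]),
                reaction_slot=str(first["reaction_slot"]),
                events=events,
            )
        )
    return trials


def write_trials(trials: list[Trial], path) -> None:
    rows = []
    for t in trials:
        for i, e in enumerate(t.events, start=1):
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "spider_type": t.spider_type,
                    "wasp_genus": t.wasp_genus,
                    "wasp_color": t.wasp_color,
                    "wasp_length_mm": t.wasp_length,
                    "spider_length_mm": t.spider_length,
                    "silk": t.silk_dragline,
                    "reaction_slot": t.reaction_slot,
                    "event_index": i,
                    "behavior_code": e.behavior,
                    "slot10": e.slot10,
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_false_prey(path) -> list[FalsePreyTrial]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, FALSE_PREY_COLUMNS[:4], path)
    return [
        FalsePreyTrial(
            background=str(r.background),
            first_detected=str(r.first_detected),
            silk=str(r.silk),
            response=int(r.response),
            spider_length=float(getattr(r, "spider_length_mm", np.nan)),
        )
        for r in df.itertuples()
    ]


def write_false_prey(trials: list[FalsePreyTrial], path) -> None:
    pd.DataFrame(
        [
            {
                "background": t.background,
                "first_detected": t.first_detected,
                "silk": t.silk,
                "response": t.response,
                "spider_length_mm": t.spider_length,
            }
            for t in trials
        ],
        columns=FALSE_PREY_COLUMNS,
    ).to_csv(path, index=False)


def read_dose_response(path) -> list[DoseResponseDataset]:
    """Load dilution series; one dataset per (sample_id, endpoint) group."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, DOSE_COLUMNS[:6], path)
    datasets = []
    for (sid, endpoint), g in df.groupby(["sample_id", "endpoint"], sort=True):
        g = g.sort_values(["dilution_pct", "replicate"])
        kwargs = dict(
            dilutions=g["dilution_pct"].to_numpy(float),
            endpoint=str(endpoint),
            sample_id=str(sid),
        )
        if endpoint in BINARY_ENDPOINTS:
            kwargs["n_exposed"] = g["n_exposed"].to_numpy(int)
            kwargs["n_affected"] = g["n_affected"].to_numpy(int)
        else:
            kwargs["response_fraction"] = g["response_fraction"].to_numpy(float)
        datasets.append(DoseResponseDataset(**kwargs))
    return datasets


def write_dose_response(datasets: list[DoseResponseDataset], path) -> None:
    rows = []
    for ds in datasets:
        reps: dict[float, int] = {}
        for i, d in enumerate(ds.dilutions):
            reps[d] = reps.get(d, 0) + 1
            row = {
                "sample_id": ds.sample_id,
                "genus": "",
                "color": "",
                "endpoint": ds.endpoint,
                "dilution_pct": d,
                "replicate": reps[d],
                "n_exposed": "",
                "n_affected": "",
                "response_fraction": "",
            }
            if ds.is_binary:
                row["n_exposed"] = int(ds.n_exposed[i])
                row["n_affected"] = int(ds.n_affected[i])
            else:
                row["response_fraction"] = float(ds.response_fraction[i])
            rows.append(row)
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)
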