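"""Seeded synthetic inputs with the statistical structure of each assay.

Four generators emulate the four input families of the analysis:

* cuticle reflectance spectra — a flat, low "black" curve and a long-pass
  sigmoidal "orange" curve with multiplicative lognormal replicate noise;
* live-prey behavioral trials — modal grouped actions drawn from per
  (spider type, wasp color) probability vectors, wrapped in realistic event
  sequences, sizes and covariates;
* false-prey (lure) trials — independent same/different responses with an
  optional injected dependence on a covariate;
* dose-response series — binomial immobilization counts following a
  log-logistic curve in extract dilution.

Every generator is a pure function of (model, seed): one global seed fans
out to independent substreams, so each stage regenerates identically on its
own.  Defaults are the study's own conditions where stated (136 trials split
68:51:17 across spider groups; 30 lure trials; dilutions 25/50/75/100% with
triplicates of 10 neonates) and field-plausible choices elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .behavior import (
    GROUPED_ACTIONS,
    SPIDER_TYPES,
    TIME_SLOTS_10,
    WASP_COLORS,
    WASP_GENERA,
    ActionEvent,
    Trial,
)
from .contingency import FalsePreyTrial
from .spectral import ReflectanceSpectrum
from .toxicity import DoseResponseDataset, log_logistic

__all__ = [
    "SpectrumModel",
    "black_model",
    "TrialModel",
    "ToxModel",
    "gen_reflectance",
    "gen_trials",
    "gen_false_prey",
    "gen_mortality",
    "substreams",
]

_STAGES = ("spectra", "trials", "false_prey", "mortality")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Fan one global seed out to one independent RNG per pipeline stage."""
    seqs = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, seqs)}


# ---------------------------------------------------------------------------
# reflectance spectra


@dataclass(frozen=True)
class SpectrumModel:
    """Shape parameters for one cuticle patch.

    Orange cuticle is a long-pass edge: r_min below the edge, rising
    sigmoidally to r_max above it.  Black cuticle is flat at r_min.  Each
    replicate is the shape curve times a single lognormal factor
    (multiplicative measurement/specimen noise).
    """

    patch: str = "orange"
    r_min: float = 0.04
    r_max: float = 0.45
    edge_nm: float = 560.0
    edge_width_nm: float = 15.0
    noise_sd: float = 0.10
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.r_min < self.r_max <= 1):
            raise ValueError("need 0 <= r_min < r_max <= 1")
        if self.patch not in ("black", "orange"):
            raise ValueError("patch must be 'black' or 'orange'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def black_model(r_min: float = 0.04, noise_sd: float = 0.10, n_replicates: int = 5) -> SpectrumModel:
    """Convenience model for flat black cuticle (r_max is unused for black)."""
    return SpectrumModel(
        patch="black", r_min=r_min, r_max=min(1.0, r_min + 1e-6) if r_min >= 1 else 1.0,
        noise_sd=noise_sd, n_replicates=n_replicates,
    )


def gen_reflectance(
    model: SpectrumModel,
    grid: np.ndarray,
    rng: np.random.Generator | int,
    genus: str = "synthetic",
) -> list[ReflectanceSpectrum]:
    """Draw replicate reflectance spectra for one patch."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    w = np.asarray(grid, dtype=float)
    if model.patch == "orange":
        if not (w[0] <= model.edge_nm <= w[-1]):
            raise ValueError("edge_nm must lie within the grid")
        shape = model.r_min + (model.r_max - model.r_min) / (
            1.0 + np.exp(-(w - model.edge_nm) / model.edge_width_nm)
        )
    else:
        shape = np.full_like(w, model.r_min)
    out = []
    for i in range(model.n_replicates):
        factor = (
            rng.lognormal(mean=0.0, sigma=model.noise_sd) if model.noise_sd > 0 else 1.0
        )
        out.append(
            ReflectanceSpectrum(
                wavelengths=w,
                reflectance=np.clip(shape * factor, 0.0, 1.0),
                genus=genus,
                patch=model.patch,
                replicate_id=f"{model.patch}-{i + 1}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# live-prey behavioral trials


def _default_action_probs() -> dict[tuple[str, str], tuple[float, float, float]]:
    # (detect, attack, avoid) per (spider_type, wasp_color): BOB shifts mass
    # from attack toward detect/avoid, most strongly in captive adults.
    return {
        ("field_juvenile", "black"): (0.35, 0.50, 0.15),
        ("field_juvenile", "BOB"): (0.50, 0.30, 0.20),
        ("field_adult", "black"): (0.40, 0.45, 0.15),
        ("field_adult", "BOB"): (0.55, 0.20, 0.25),
        ("captive_adult", "black"): (0.50, 0.30, 0.20),
        ("captive_adult", "BOB"): (0.45, 0.10, 0.45),
    }


@dataclass(frozen=True)
class TrialModel:
    """Generating model for live-prey trials.

    ``action_probs`` maps (spider_type, wasp_color) to a (detect, attack,
    avoid) probability vector for the trial's modal action.  Spider-type
    proportions default to the study composition 68:51:17; event counts are
    Poisson with the study's mean of ~7 actions per trial; sizes are
    lognormal in mm.
    """

    action_probs: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=_default_action_probs
    )
    spider_type_props: tuple[float, float, float] = (68.0, 51.0, 17.0)
    p_bob: float = 0.5
    genus_props: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    events_per_trial: float = 7.0
    p_silk: float = 0.5
    wasp_length_mm: tuple[float, float] = (4.0, 0.25)  # lognormal median, sigma
    spider_length_mm: tuple[float, float] = (6.0, 0.25)

    def __post_init__(self) -> None:
        for key, p in self.action_probs.items():
            if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
                raise ValueError(f"action probabilities for {key} must sum to 1")
        if self.events_per_trial <= 0:
            raise ValueError("events_per_trial must be positive")


_GROUP_CODES = {"detect": (1, 2), "attack": (3, 4), "avoid": (5, 6)}


def gen_trials(
    model: TrialModel, n_trials: int, rng: np.random.Generator | int
) -> list[Trial]:
    """Draw live-prey trials whose modal grouped action follows the model.

    Each trial first draws its target modal action from the cell's
    probability vector, then fills a Poisson-sized event sequence dominated
    by that action (minority events from the other categories), so that
    ``most_common_action`` recovers the draw exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    type_p = np.asarray(model.spider_type_props, dtype=float)
    type_p = type_p / type_p.sum()
    genus_p = np.asarray(model.genus_props, dtype=float)
    genus_p = genus_p / genus_p.sum()
    trials = []
    for i in range(n_trials):
        stype = SPIDER_TYPES[rng.choice(3, p=type_p)]
        color = "BOB" if rng.random() < model.p_bob else "black"
        genus = WASP_GENERA[rng.choice(4, p=genus_p)]
        probs = np.asarray(model.action_probs[(stype, color)], dtype=float)
        target = GROUPED_ACTIONS[rng.choice(3, p=probs)]
        k = max(1, int(rng.poisson(model.events_per_trial)))
        # strict majority of events carry the target action
        n_target = max(k // 2 + 1, 1)
        others = [a for a in GROUPED_ACTIONS if a != target]
        groups = [target] * n_target + [
            others[rng.integers(2)] for _ in range(k - n_target)
        ]
        rng.shuffle(groups)
        events = tuple(
            ActionEvent(
                behavior=_GROUP_CODES[g][rng.integers(2)],
                slot10=TIME_SLOTS_10[rng.integers(4)],
            )
            for g in groups
        )
        trials.append(
            Trial(
                trial_id=f"T{i + 1:04d}",
                spider_type=stype,
                wasp_color=color,
                wasp_genus=genus,
                wasp_length=float(
                    model.wasp_length_mm[0] * rng.lognormal(0.0, model.wasp_length_mm[1])
                ),
                spider_length=float(
                    model.spider_length_mm[0]
                    * rng.lognormal(0.0, model.spider_length_mm[1])
                ),
                silk_dragline="yes" if rng.random() < model.p_silk else "no",
                reaction_slot=("0-5", "5-10", "10-20", "20-30", "30-40")[
                    rng.integers(5)
                ],
                events=events,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# false-prey trials


def gen_false_prey(
    p_same_by_level: dict[str, float] | float,
    n: int,
    rng: np.random.Generator | int,
    depend_on: str = "background",
    level_probs: dict[str, dict[str, float]] | None = None,
) -> list[FalsePreyTrial]:
    """Draw lure trials with an optional dependence of response on one covariate.

    ``p_same_by_level`` is either a single probability (independence) or a
    mapping from the levels of ``depend_on`` to P(response = same).
    Covariate levels are drawn independently with the given (or uniform)
    level probabilities.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    levels = {
        "background": ("white", "black"),
        "first_detected": ("black", "BOB"),
        "silk": ("no", "yes"),
    }
    level_probs = level_probs or {}
    out = []
    for _ in range(n):
        drawn = {}
        for var, levs in levels.items():
            p = level_probs.get(var, {levs[0]: 0.5, levs[1]: 0.5})
            drawn[var] = levs[0] if rng.random() < p[levs[0]] else levs[1]
        if isinstance(p_same_by_level, dict):
            p_same = p_same_by_level[drawn[depend_on]]
        else:
            p_same = float(p_same_by_level)
        if not (0 <= p_same <= 1):
            raise ValueError("p_same must lie in [0, 1]")
        out.append(
            FalsePreyTrial(
                background=drawn["background"],
                first_detected=drawn["first_detected"],
                silk=drawn["silk"],
                response=1 if rng.random() < p_same else 2,
                spider_length=float(6.0 * rng.lognormal(0.0, 0.2)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# dose-response series


@dataclass(frozen=True)
class ToxModel:
    """Generating model for an immobilization dilution series.

    Defaults mirror the assay design: dilutions 25/50/75/100% of the pure
    extract, triplicates of 10 neonates, a true LC50 of 60% and slope -4
    (response increasing with dose).
    """

    true_ec50: float = 60.0
    slope: float = -4.0
    dilutions: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0)
    replicates: int = 3
    organisms_per_replicate: int = 10
    endpoint: str = "immobilization_48h"

    def __post_init__(self) -> None:
        if self.true_ec50 <= 0:
            raise ValueError("true_ec50 must be positive")
        if any(d <= 0 or d > 100 for d in self.dilutions):
            raise ValueError("dilutions must lie in (0, 100]")
        if self.organisms_per_replicate < 1:
            raise ValueError("organisms_per_replicate must be >= 1")


def gen_mortality(
    model: ToxModel, rng: np.random.Generator | int, sample_id: str = "synthetic"
) -> DoseResponseDataset:
    """Draw binomial immobilization counts from the log-logistic model."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    d = np.repeat(np.asarray(model.dilutions, dtype=float), model.replicates)
    p = log_logistic(d, model.slope, model.true_ec50)
    n_exposed = np.full(d.shape, model.organisms_per_replicate, dtype=int)
    n_affected = rng.binomial(n_exposed, p)
    return DoseResponseDataset(
        dilutions=d,
        endpoint=model.endpoint,
        n_exposed=n_exposed,
        n_affected=n_affected,
        control_responses=np.zeros(model.replicates),
        sample_id=sample_id,
    )
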