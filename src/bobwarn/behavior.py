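"""Live-prey behavioral trials: taxonomy, tabulation, and the multinomial model.

Each trial pairs one jumping spider (field juvenile, field adult, or captive
adult) with one live wasp (BOB-patterned or all-black, one of four scelionid
genera) for 40 minutes.  The observer records a sequence of coded behaviors
in 10-minute slots.  The seven raw codes collapse to three grouped actions —
detect (codes 1-2), attack (3-4), avoid (5-6); code 7 ("None") is excluded —
and each trial's modal grouped action is the response of a multinomial
logistic regression whose candidate covariate sets are compared by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BEHAVIOR_LABELS",
    "GROUPED_ACTIONS",
    "SPIDER_TYPES",
    "WASP_COLORS",
    "WASP_GENERA",
    "TIME_SLOTS_10",
    "ALL_COVARIATES",
    "ActionEvent",
    "Trial",
    "MultinomialFit",
    "group_behavior",
    "most_common_action",
    "tabulate_actions",
    "behavior_percentages",
    "fit_multinomial",
    "aic",
    "select_model",
]

BEHAVIOR_LABELS = {
    1: "Alert and swivel",
    2: "Follow or stalk",
    3: "Crouch, jump and contact prey",
    4: "Pierce and ingest",
    5: "Prey undetected or ignored",
    6: "Detect visually and withdraw",
    7: "None",
}

GROUPED_ACTIONS = ("detect", "attack", "avoid")

# modal-response tie-break: rarer, more consequential outcomes win
_PRECEDENCE = {"attack": 0, "avoid": 1, "detect": 2}

SPIDER_TYPES = ("field_juvenile", "field_adult", "captive_adult")
WASP_COLORS = ("BOB", "black")
WASP_GENERA = ("Baryconus", "Chromoteleia", "Macroteleia", "Scelio")
TIME_SLOTS_10 = ("0-10", "10-20", "20-30", "30-40")
REACTION_SLOTS = ("0-5", "5-10", "10-20", "20-30", "30-40")

CATEGORICAL_COVARIATES = ("wasp_color", "spider_type", "wasp_genus", "silk_dragline")
CONTINUOUS_COVARIATES = ("wasp_length", "spider_length")
ALL_COVARIATES = CATEGORICAL_COVARIATES[:3] + CONTINUOUS_COVARIATES + ("silk_dragline",)


def group_behavior(code: int) -> str | None:
    """Collapse a raw behavior code to detect/attack/avoid; code 7 maps to None."""
    if code not in BEHAVIOR_LABELS:
        raise ValueError(f"behavior code must be in 1..7, got {code}")
    if code in (1, 2):
        return "detect"
    if code in (3, 4):
        return "attack"
    if code in (5, 6):
        return "avoid"
    return None


@dataclass(frozen=True)
class ActionEvent:
    behavior: int
    slot10: str

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIOR_LABELS:
            raise ValueError(f"behavior code must be in 1..7, got {self.behavior}")
        if self.slot10 not in TIME_SLOTS_10:
            raise ValueError(f"slot10 must be one of {TIME_SLOTS_10}")


@dataclass(frozen=True)
class Trial:
    trial_id: str
    spider_type: str
    wasp_color: str
    wasp_genus: str
    wasp_length: float
    spider_length: float
    silk_dragline: str  # "yes" | "no"
    reaction_slot: str
    events: tuple[ActionEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.spider_type not in SPIDER_TYPES:
            raise ValueError(f"spider_type must be one of {SPIDER_TYPES}")
        if self.wasp_color not in WASP_COLORS:
            raise ValueError(f"wasp_color must be one of {WASP_COLORS}")
        if self.wasp_genus not in WASP_GENERA:
            raise ValueError(f"wasp_genus must be one of {WASP_GENERA}")
        if self.silk_dragline not in ("yes", "no"):
            raise ValueError("silk_dragline must be 'yes' or 'no'")
        if self.reaction_slot not in REACTION_SLOTS:
            raise ValueError(f"reaction_slot must be one of {REACTION_SLOTS}")
        if not (self.wasp_length > 0 and self.spider_length > 0):
            raise ValueError("lengths must be positive")
        object.__setattr__(self, "events", tuple(self.events))


def most_common_action(trial: Trial) -> str:
    """Modal grouped action over a trial's events.

    Ties break by escalation precedence attack > avoid > detect.  Trials with
    no groupable event (all code 7) have no defined response.
    """
    groups = [g for e in trial.events if (g := group_behavior(e.behavior))]
    if not groups:
        raise ValueError(f"trial {trial.trial_id} has no groupable events")
    counts = pd.Series(groups).value_counts()
    best = counts[counts == counts.max()].index
    return min(best, key=_PRECEDENCE.__getitem__)


def tabulate_actions(trials: list[Trial]) -> pd.DataFrame:
    """Count grouped events by spider type, wasp color, action, and time slot.

    Returns a complete (all-cells) long-format table; the count total equals
    the number of groupable events across trials.
    """
    index = pd.MultiIndex.from_product(
        [SPIDER_TYPES, WASP_COLORS, GROUPED_ACTIONS, TIME_SLOTS_10],
        names=["spider_type", "wasp_color", "action", "slot10"],
    )
    counts = pd.Series(0, index=index, name="count")
    for t in trials:
        for e in t.events:
            g = group_behavior(e.behavior)
            if g is not None:
                counts.loc[(t.spider_type, t.wasp_color, g, e.slot10)] += 1
    return counts.reset_index()


def behavior_percentages(trials: list[Trial]) -> pd.DataFrame:
    """Modal-action percentages, pooled the way the genus comparison needs.

    BOB trials are expressed per genus (denominator: that genus's BOB trial
    count); black trials are pooled across genera into a single "black"
    group, because black cuticle is spectrally alike between genera.  Groups
    with no trials get NaN percentages rather than a division error.
    """
    records = []
    for t in trials:
        try:
            action = most_common_action(t)
        except ValueError:
            continue
        group = t.wasp_genus if t.wasp_color == "BOB" else "black (pooled)"
        records.append({"group": group, "action": action})
    df = pd.DataFrame(records, columns=["group", "action"])
    groups = [g for g in WASP_GENERA] + ["black (pooled)"]
    out = []
    for g in groups:
        sub = df[df["group"] == g]
        n = len(sub)
        row = {"group": g, "n_trials": n}
        for a in GROUPED_ACTIONS:
            row[f"{a}_pct"] = 100.0 * (sub["action"] == a).sum() / n if n else np.nan
        out.append(row)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class MultinomialFit:
    reference_category: str
    categories: tuple[str, ...]
    covariates: tuple[str, ...]
    coefficients: pd.DataFrame  # rows: design columns; cols: non-reference categories
    log_likelihood: float
    n_params: int
    converged: bool
    fitted_probabilities: pd.DataFrame  # per trial, one column per category

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


def _design_matrix(
    trials: list[Trial], covariates: tuple[str, ...]
) -> pd.DataFrame:
    data = pd.DataFrame(
        {
            "wasp_color": [t.wasp_color for t in trials],
            "spider_type": [t.spider_type for t in trials],
            "wasp_genus": [t.wasp_genus for t in trials],
            "silk_dragline": [t.silk_dragline for t in trials],
            "wasp_length": [t.wasp_length for t in trials],
            "spider_length": [t.spider_length for t in trials],
        }
    )
    cols = [pd.Series(1.0, index=data.index, name="intercept")]
    for cov in covariates:
        if cov in CONTINUOUS_COVARIATES:
            x = data[cov].astype(float)
            sd = x.std(ddof=1)
            cols.append(((x - x.mean()) / sd if sd > 0 else x * 0.0).rename(cov))
        elif cov in CATEGORICAL_COVARIATES:
            levels = sorted(data[cov].unique())
            for lev in levels[1:]:  # first (alphabetical) level is reference
                cols.append(
                    (data[cov] == lev).astype(float).rename(f"{cov}[{lev}]")
                )
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = pd.concat(cols, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept: list[str] = []
        for c in X.columns:
            trial_cols = kept + [c]
            if np.linalg.matrix_rank(X[trial_cols].to_numpy()) == len(kept):
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return X


def fit_multinomial(
    trials: list[Trial],
    covariates: tuple[str, ...] = (),
    reference: str = "attack",
) -> MultinomialFit:
    """Maximum-likelihood multinomial logistic regression on modal actions.

    The response is each trial's :func:`most_common_action`; coefficients are
    log-odds of each non-reference action versus ``reference`` (default
    "attack", so effects read as detecting-versus-attacking and
    avoiding-versus-attacking).  Continuous covariates are standardized;
    categorical ones are dummy-coded against the alphabetically first level.
    """
    if reference not in GROUPED_ACTIONS:
        raise ValueError(f"reference must be one of {GROUPED_ACTIONS}")
    responses = [most_common_action(t) for t in trials]
    observed = [c for c in GROUPED_ACTIONS if c in set(responses)]
    if reference in observed:
        categories = [reference] + [c for c in observed if c != reference]
    else:
        categories = observed
    y = pd.Categorical(responses, categories=categories).codes
    X = _design_matrix(trials, tuple(covariates))

    model = sm.MNLogit(y, X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = model.fit(method="bfgs", maxiter=500, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        warnings.warn(
            "multinomial fit did not converge (possible perfect separation)",
            stacklevel=2,
        )
    params = np.atleast_2d(res.params)
    coef = pd.DataFrame(params, index=X.columns, columns=categories[1:])
    probs = pd.DataFrame(res.predict(X.to_numpy()), columns=categories)
    return MultinomialFit(
        reference_category=categories[0],
        categories=tuple(categories),
        covariates=tuple(covariates),
        coefficients=coef,
        log_likelihood=float(res.llf),
        n_params=int(params.size),
        converged=converged,
        fitted_probabilities=probs,
    )


def aic(fit: MultinomialFit) -> float:
    """Akaike information criterion: 2k - 2*log-likelihood."""
    return fit.aic


def select_model(
    trials: list[Trial],
    candidates: list[tuple[str, ...]],
    reference: str = "attack",
) -> tuple[MultinomialFit, pd.DataFrame]:
    """Fit every candidate covariate set and return the minimum-AIC fit.

    Ties break toward fewer parameters, then toward earlier listed order.
    Non-converged candidates stay in the comparison table, flagged.
    """
    if not candidates:
        raise ValueError("at least one candidate covariate set is required")
    fits = [fit_multinomial(trials, cov, reference=reference) for cov in candidates]
    table = pd.DataFrame(
        {
            "covariates": ["+".join(c) if c else "intercept" for c in candidates],
            "n_params": [f.n_params for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "aic": [f.aic for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].n_params, i))
    return fits[order[0]], table
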