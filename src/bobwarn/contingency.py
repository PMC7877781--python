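"""Contingency tables and the log-likelihood-ratio (G) independence test.

Used for the false-prey (painted rice lure) experiment: 30 trials in which a
jumping spider faced one black and one BOB lure simultaneously, the response
being whether the spider treated the two lures the same way (coded 1) or
differently (coded 2).  The response is cross-tabulated against arena
background, which lure colour was detected first, and the presence of a
noticeable silk dragline, and each table is tested for independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FalsePreyTrial",
    "ContingencyTable",
    "GTestResult",
    "build_false_prey_tables",
    "g_statistic",
    "pearson_chi2",
]


@dataclass(frozen=True)
class FalsePreyTrial:
    """One automated-cage trial with a pair of painted lures."""

    background: str  # "white" | "black"
    first_detected: str  # "black" | "BOB"
    silk: str  # "yes" | "no"
    response: int  # 1 = same action toward both lures, 2 = different
    spider_length: float = float("nan")

    _LEVELS = {
        "background": ("white", "black"),
        "first_detected": ("black", "BOB"),
        "silk": ("no", "yes"),
    }

    def __post_init__(self) -> None:
        for name, levels in self._LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValueError(f"{name} must be one of {levels}")
        if self.response not in (1, 2):
            raise ValueError("response must be 1 (same) or 2 (different)")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple
    name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-d table")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p_value: float
    correction: str = "none"
    df_reduced: bool = False


def build_false_prey_tables(
    trials: list[FalsePreyTrial],
) -> dict[str, ContingencyTable]:
    """Cross-tabulate same/different response against the three trial covariates."""
    rows = pd.DataFrame(
        {
            "response": [t.response for t in trials],
            "background": [t.background for t in trials],
            "first_detected": [t.first_detected for t in trials],
            "silk": [t.silk for t in trials],
        }
    )
    out = {}
    for var in ("background", "first_detected", "silk"):
        levels = FalsePreyTrial._LEVELS[var]
        if len(rows):
            tab = pd.crosstab(rows["response"], rows[var]).reindex(
                index=[1, 2], columns=list(levels), fill_value=0
            )
            counts = tab.to_numpy()
        else:
            counts = np.zeros((2, len(levels)), dtype=int)
        out[var] = ContingencyTable(
            counts=counts,
            row_labels=("same", "different"),
            col_labels=levels,
            name=var,
        )
    return out


def _expected(counts: np.ndarray) -> np.ndarray:
    n = counts.sum()
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n


def g_statistic(table: ContingencyTable, correction: str = "none") -> GTestResult:
    """Likelihood-ratio test of independence: G = 2 * sum O*ln(O/E).

    Zero observed cells contribute 0 (the x*ln(x) -> 0 limit).  All-zero rows
    or columns are dropped with a df reduction and flag.  ``correction`` may
    be ``"williams"`` for the Williams small-sample adjustment; the default
    is the plain statistic.  The p-value is the upper chi-square tail with
    df = (r-1)(c-1).
    """
    if correction not in ("none", "williams"):
        raise ValueError("correction must be 'none' or 'williams'")
    counts = table.counts
    if counts.sum() == 0:
        raise ValueError("all-zero table")
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    df_reduced = not (keep_r.all() and keep_c.all())
    if df_reduced:
        warnings.warn("all-zero row/column dropped; df reduced", stacklevel=2)
        counts = counts[np.ix_(keep_r, keep_c)]
    r, c = counts.shape
    df = (r - 1) * (c - 1)
    expected = _expected(counts)
    if np.any(expected < 5):
        warnings.warn(
            "expected cell count below 5: chi-square approximation may be poor",
            stacklevel=2,
        )
    obs = counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    if correction == "williams":
        n = obs.sum()
        q = 1.0 + (
            (n / obs.sum(axis=1) - 1).sum() * (n / obs.sum(axis=0) - 1).sum()
        ) / (6.0 * n * df if df > 0 else np.inf)
        g = g / q
    g = max(g, 0.0)
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return GTestResult(g=float(g), df=df, p_value=p, correction=correction,
                       df_reduced=df_reduced)


def pearson_chi2(table: ContingencyTable) -> float:
    """Pearson X^2 = sum (O-E)^2/E; asymptotically equivalent cross-check for G."""
    counts = table.counts
    if counts.sum() == 0:
        raise ValueError("all-zero table")
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    counts = counts[np.ix_(keep_r, keep_c)]
    expected = _expected(counts)
    return float(((counts - expected) ** 2 / expected).sum())
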