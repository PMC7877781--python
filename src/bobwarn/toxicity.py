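"""Two-parameter log-logistic dose-response fits for wasp-extract toxicity.

Whole-body methanol extracts of BOB and black wasps are serially diluted
(25, 50, 75, 100 % of the pure extract) and assayed against *Daphnia magna*
(binary endpoint: immobilization of 10 neonates per replicate, read at 24 h
and 48 h) or *Vibrio fischeri* (continuous endpoint: fraction of
bioluminescence inhibited).  The response follows

    p(d) = 1 / (1 + exp(b * (ln d - ln e)))

where ``e`` is the LC50/EC50 (the dilution producing a half-maximal effect)
and ``b`` the slope; ``b < 0`` gives a response increasing with dose.
Extracts with no measurable effect up to the pure extract are reported as
censored ("> 100%") rather than with a point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseDataset",
    "DoseResponseFit",
    "EffectiveConcentration",
    "log_logistic",
    "fit_dose_response",
    "effective_concentration",
]

ENDPOINTS = (
    "immobilization_24h",
    "immobilization_48h",
    "inhibition_5min",
    "inhibition_15min",
)

BINARY_ENDPOINTS = ("immobilization_24h", "immobilization_48h")


def log_logistic(d: np.ndarray, b: float, e: float) -> np.ndarray:
    """Two-parameter log-logistic mean response (lower asymptote 0, upper 1)."""
    d = np.asarray(d, dtype=float)
    return 1.0 / (1.0 + np.exp(b * (np.log(d) - np.log(e))))


@dataclass(frozen=True)
class DoseResponseDataset:
    """A dilution series for one extract sample and endpoint.

    ``dilutions`` are percent of the pure extract, one entry per observation
    (replicates repeat the dilution value).  Binary endpoints carry
    ``n_exposed``/``n_affected`` counts; continuous endpoints carry
    ``response_fraction`` in [0, 1].  ``control_responses`` holds the
    dilution-0 observations (counts affected, or fractions).
    """

    dilutions: np.ndarray
    endpoint: str
    n_exposed: np.ndarray | None = None
    n_affected: np.ndarray | None = None
    response_fraction: np.ndarray | None = None
    control_responses: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.dilutions, dtype=float)
        if d.size == 0:
            raise ValueError("empty dataset")
        if np.any(d <= 0) or np.any(d > 100):
            raise ValueError("dilutions must lie in (0, 100] percent")
        object.__setattr__(self, "dilutions", d)
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.is_binary:
            if self.n_exposed is None or self.n_affected is None:
                raise ValueError("binary endpoints need n_exposed and n_affected")
            ne = np.asarray(self.n_exposed, dtype=int)
            na = np.asarray(self.n_affected, dtype=int)
            if ne.shape != d.shape or na.shape != d.shape:
                raise ValueError("count arrays must align with dilutions")
            if np.any(ne <= 0):
                raise ValueError("n_exposed must be positive")
            if np.any(na < 0) or np.any(na > ne):
                raise ValueError("need 0 <= n_affected <= n_exposed")
            object.__setattr__(self, "n_exposed", ne)
            object.__setattr__(self, "n_affected", na)
        else:
            if self.response_fraction is None:
                raise ValueError("continuous endpoints need response_fraction")
            rf = np.asarray(self.response_fraction, dtype=float)
            if rf.shape != d.shape:
                raise ValueError("response_fraction must align with dilutions")
            if np.any(rf < 0) or np.any(rf > 1):
                raise ValueError("response_fraction must lie in [0, 1]")
            object.__setattr__(self, "response_fraction", rf)

    @property
    def is_binary(self) -> bool:
        return self.endpoint in BINARY_ENDPOINTS

    @property
    def observed_fractions(self) -> np.ndarray:
        if self.is_binary:
            return self.n_affected / self.n_exposed
        return self.response_fraction


@dataclass(frozen=True)
class DoseResponseFit:
    slope: float
    ec50: float
    ci_lower: float
    ci_upper: float
    log_likelihood: float | None
    rss: float | None
    censored: bool
    converged: bool
    endpoint: str = ""
    sample_id: str = ""


def _delta_ci(b0: float, b1: float, cov: np.ndarray) -> tuple[float, float]:
    """95% CI for ec50 = exp(-b0/b1) via the delta method on the log scale."""
    log_e = -b0 / b1
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ cov @ grad)
    if not np.isfinite(var) or var < 0:
        return float("nan"), float("nan")
    half = 1.959963984540054 * np.sqrt(var)
    return float(np.exp(log_e - half)), float(np.exp(log_e + half))


def fit_dose_response(dataset: DoseResponseDataset) -> DoseResponseFit:
    """Fit the 2-parameter log-logistic model to a dilution series.

    Binary endpoints are fitted by binomial maximum likelihood (a logistic
    GLM on log-dilution, which is the same model reparameterised); continuous
    endpoints by least squares on the same mean function.  A dataset with no
    effect at any dose (or a complete effect everywhere) is non-identifiable
    and comes back censored with a warning.  The 95% CI is a normal
    approximation on ln(ec50).
    """
    if len(np.unique(dataset.dilutions)) < 3:
        raise ValueError("need at least 3 distinct dilutions")
    frac = dataset.observed_fractions
    if np.allclose(frac, 0.0) or np.allclose(frac, 1.0):
        warnings.warn(
            "response is flat at 0 or 1: ec50 is not identifiable; "
            "returning a censored fit",
            stacklevel=2,
        )
        return DoseResponseFit(
            slope=float("nan"), ec50=float("inf"),
            ci_lower=float("nan"), ci_upper=float("nan"),
            log_likelihood=None, rss=None, censored=True, converged=False,
            endpoint=dataset.endpoint, sample_id=dataset.sample_id,
        )
    # gross non-monotonicity check on per-dilution means
    means = pd.Series(frac).groupby(pd.Series(dataset.dilutions)).mean()
    if means.size >= 3 and (means.diff().dropna() < -0.25).any():
        warnings.warn("grossly non-monotone response pattern", stacklevel=2)

    logd = np.log(dataset.dilutions)
    X = sm.add_constant(logd)
    if dataset.is_binary:
        endog = np.column_stack(
            [dataset.n_affected, dataset.n_exposed - dataset.n_affected]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        b0, b1 = res.params
        cov = np.asarray(res.cov_params())
        ll, rss = float(res.llf), None
        converged = bool(res.converged)
    else:
        # least squares on the identity parameterisation p = 1/(1+exp(b0+b1*logd))
        def mean_fn(x, b0, b1):
            return 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))

        p0 = (-2.0 * np.log(50.0), 2.0)  # start near ec50=50%, moderate slope
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                mean_fn, logd, frac, p0=p0, maxfev=20000
            )
        b0, b1 = popt
        cov = pcov
        resid = frac - mean_fn(logd, *popt)
        ll, rss = None, float((resid**2).sum())
        converged = bool(np.all(np.isfinite(pcov)))

    if b1 == 0 or not np.isfinite(b1):
        warnings.warn("zero slope: ec50 not identifiable", stacklevel=2)
        return DoseResponseFit(
            slope=float("nan"), ec50=float("inf"),
            ci_lower=float("nan"), ci_upper=float("nan"),
            log_likelihood=ll, rss=rss, censored=True, converged=False,
            endpoint=dataset.endpoint, sample_id=dataset.sample_id,
        )
    # GLM linear predictor is b0 + b1*logd = -b*(ln d - ln e)
    slope = -float(b1)
    ec50 = float(np.exp(-b0 / b1))
    lo, hi = _delta_ci(float(b0), float(b1), cov)
    return DoseResponseFit(
        slope=slope, ec50=ec50, ci_lower=lo, ci_upper=hi,
        log_likelihood=ll, rss=rss, censored=False, converged=converged,
        endpoint=dataset.endpoint, sample_id=dataset.sample_id,
    )


@dataclass(frozen=True)
class EffectiveConcentration:
    """An LC/EC estimate at a given effect level, possibly censored."""

    level: float
    estimate: float | None
    ci_lower: float | None
    ci_upper: float | None
    censored: bool
    max_tested: float

    def __str__(self) -> str:
        if self.censored:
            return f"> {self.max_tested:g}%"
        s = f"{self.estimate:.1f}%"
        if self.ci_lower is not None and np.isfinite(self.ci_lower):
            s += f" ({self.ci_lower:.1f}, {self.ci_upper:.1f})"
        return s


def effective_concentration(
    fit: DoseResponseFit, level: float = 50.0, max_tested: float = 100.0
) -> EffectiveConcentration:
    """Dilution producing ``level``% of the maximal effect, with censoring.

    Estimates above the highest tested concentration (and non-identifiable
    fits) are reported as "> max_tested%" with no point estimate, matching
    the convention used for non-toxic extracts.
    """
    if not (0 < level < 100):
        raise ValueError("level must lie strictly between 0 and 100 percent")
    if fit.censored or not np.isfinite(fit.ec50):
        return EffectiveConcentration(
            level=level, estimate=None, ci_lower=None, ci_upper=None,
            censored=True, max_tested=max_tested,
        )
    # invert p(d) = level/100 for the log-logistic with slope b = fit.slope
    ratio = 100.0 / level - 1.0
    d = fit.ec50 * ratio ** (1.0 / fit.slope)
    if d > max_tested:
        return EffectiveConcentration(
            level=level, estimate=None, ci_lower=None, ci_upper=None,
            censored=True, max_tested=max_tested,
        )
    if level == 50.0:
        lo, hi = fit.ci_lower, fit.ci_upper
    else:
        lo = hi = float("nan")
    return EffectiveConcentration(
        level=level, estimate=float(d), ci_lower=lo, ci_upper=hi,
        censored=False, max_tested=max_tested,
    )
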