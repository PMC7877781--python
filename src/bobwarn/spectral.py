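"""Predator-vision spectral analysis of the black–orange–black (BOB) cuticle pattern.

The question this module answers is whether a green-sensitive predator (a
jumping spider with a single long-wavelength photopigment) can tell the black
and orange patches of a small wasp apart.  The chain is:

1. a Govardovskii visual-pigment template gives the normalized absorbance
   S(lambda) of an A1 alpha-band pigment with peak ``lambda_max``;
2. each measured cuticle reflectance R(lambda) is weighted pointwise by
   S(lambda) to give the *green component* R(lambda)*S(lambda), whose area
   estimates how much reflected light the pigment can absorb;
3. the *absorption contrast* of a genus is the black-patch area minus the
   orange-patch area, with an error propagated from the replicate standard
   deviations.  Negative contrast means the orange patch dominates the
   absorbable signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReflectanceSpectrum",
    "PigmentTemplate",
    "GreenComponent",
    "ComponentSummary",
    "AbsorptionContrast",
    "govardovskii_alpha",
    "resample",
    "green_component",
    "area_under_curve",
    "aggregate_replicates",
    "absorption_contrast",
    "default_grid",
    "contrast_analysis",
]

# Govardovskii A1 alpha-band template constants
_A = 69.7
_B = 28.0
_C = -14.9
_D = 0.674
_b = 0.922
_c = 1.104

WAVELENGTH_RANGE = (250.0, 850.0)
LAMBDA_MAX_RANGE = (330.0, 700.0)


def _check_grid(wavelengths: np.ndarray, name: str = "wavelengths") -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError(f"{name} must be a 1-d sequence of length >= 2")
    if not np.all(np.diff(w) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    lo, hi = WAVELENGTH_RANGE
    if w[0] < lo or w[-1] > hi:
        raise ValueError(f"{name} must lie within [{lo:g}, {hi:g}] nm")
    return w


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Cuticle reflectance for one genus/patch/replicate.

    Reflectance is stored as a unitless fraction; percent-scale inputs
    (max > 1.5) are detected and rescaled at load time in :mod:`bobwarn.io`.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    genus: str
    patch: str  # "black" or "orange"
    replicate_id: str

    def __post_init__(self) -> None:
        w = _check_grid(self.wavelengths)
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != w.shape:
            raise ValueError("wavelengths and reflectance must have equal length")
        if np.any(r < 0):
            raise ValueError("reflectance must be non-negative")
        if self.patch not in ("black", "orange"):
            raise ValueError(f"patch must be 'black' or 'orange', got {self.patch!r}")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class PigmentTemplate:
    """Normalized alpha-band absorbance curve of an A1 visual pigment."""

    lambda_max: float
    wavelengths: np.ndarray
    sensitivity: np.ndarray
    band: str = "alpha"
    chromophore: str = "A1"

    @property
    def area(self) -> float:
        return area_under_curve(self.sensitivity, self.wavelengths)


@dataclass(frozen=True)
class GreenComponent:
    """Receptor-weighted reflectance R(lambda)*S(lambda) and its area."""

    wavelengths: np.ndarray
    values: np.ndarray
    area: float
    genus: str = ""
    patch: str = ""
    replicate_id: str = ""


@dataclass(frozen=True)
class ComponentSummary:
    """Replicate mean curve and the spread of the per-replicate areas."""

    mean_curve: np.ndarray
    wavelengths: np.ndarray
    mean_area: float
    sd_area: float
    n_replicates: int
    genus: str = ""
    patch: str = ""

    @property
    def sd_area_pct(self) -> float:
        """SD of the areas as a percentage of the mean area (nan if mean is 0)."""
        if self.mean_area > 0:
            return 100.0 * self.sd_area / self.mean_area
        return float("nan")


@dataclass(frozen=True)
class AbsorptionContrast:
    """Signed black-minus-orange green-component area difference.

    ``value < 0`` means the orange patch contributes more absorbable light
    than the black patch; ``within_error`` flags contrasts smaller than the
    propagated replicate uncertainty, i.e. patches the predator's green
    channel cannot reliably distinguish.
    """

    genus: str
    value: float
    error: float

    @property
    def within_error(self) -> bool:
        return abs(self.value) <= self.error


def govardovskii_alpha(lambda_max: float, grid: np.ndarray) -> PigmentTemplate:
    """Evaluate the A1 alpha-band visual-pigment template on a wavelength grid.

    Uses S(lambda) = 1 / [exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D] with
    x = lambda_max/lambda and a = 0.8795 + 0.0459*exp(-(lambda_max-300)^2/11940).
    The peak sits at ``lambda_max`` (within the grid resolution) and the
    long-wavelength tail decays to zero.

    Parameters
    ----------
    lambda_max : float
        Pigment absorbance peak in nm, within [330, 700].
    grid : array-like
        Strictly increasing wavelengths (nm) within [250, 850].
    """
    lo, hi = LAMBDA_MAX_RANGE
    if not (lo <= lambda_max <= hi):
        raise ValueError(f"lambda_max must be within [{lo:g}, {hi:g}] nm")
    w = _check_grid(grid, "grid")
    x = lambda_max / w
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    return PigmentTemplate(lambda_max=float(lambda_max), wavelengths=w, sensitivity=s)


def resample(spectrum: ReflectanceSpectrum, grid: np.ndarray) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    g = _check_grid(grid, "grid")
    if g[0] < spectrum.wavelengths[0] or g[-1] > spectrum.wavelengths[-1]:
        raise ValueError(
            "target grid extends beyond the measured span "
            f"[{spectrum.wavelengths[0]:g}, {spectrum.wavelengths[-1]:g}] nm"
        )
    r = np.interp(g, spectrum.wavelengths, spectrum.reflectance)
    return ReflectanceSpectrum(
        wavelengths=g,
        reflectance=r,
        genus=spectrum.genus,
        patch=spectrum.patch,
        replicate_id=spectrum.replicate_id,
    )


def green_component(
    spectrum: ReflectanceSpectrum, template: PigmentTemplate
) -> GreenComponent:
    """Weight a reflectance spectrum by the pigment template pointwise.

    The spectrum and template must already share the same grid (use
    :func:`resample` first); the area is the trapezoidal integral of the
    product curve.
    """
    if spectrum.wavelengths.shape != template.wavelengths.shape or not np.allclose(
        spectrum.wavelengths, template.wavelengths
    ):
        raise ValueError("spectrum and template must share an identical grid")
    values = spectrum.reflectance * template.sensitivity
    return GreenComponent(
        wavelengths=spectrum.wavelengths,
        values=values,
        area=area_under_curve(values, spectrum.wavelengths),
        genus=spectrum.genus,
        patch=spectrum.patch,
        replicate_id=spectrum.replicate_id,
    )


def area_under_curve(values: np.ndarray, wavelengths: np.ndarray) -> float:
    """Composite trapezoidal area over a (possibly non-uniform) grid."""
    w = _check_grid(wavelengths)
    v = np.asarray(values, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and wavelengths must have equal length")
    return float(np.trapezoid(v, w))


def aggregate_replicates(components: list[GreenComponent]) -> ComponentSummary:
    """Pointwise mean curve plus mean and sample SD (n-1) of replicate areas."""
    if len(components) == 0:
        raise ValueError("at least one component is required")
    grid = components[0].wavelengths
    for c in components[1:]:
        if c.wavelengths.shape != grid.shape or not np.allclose(c.wavelengths, grid):
            raise ValueError("all components must share the same grid")
    curves = np.vstack([c.values for c in components])
    areas = np.array([c.area for c in components])
    n = len(components)
    if n == 1:
        warnings.warn("single replicate: sd_area is 0 by convention", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(areas, ddof=1))
    return ComponentSummary(
        mean_curve=curves.mean(axis=0),
        wavelengths=grid,
        mean_area=float(areas.mean()),
        sd_area=sd,
        n_replicates=n,
        genus=components[0].genus,
        patch=components[0].patch,
    )


def absorption_contrast(
    black: ComponentSummary, orange: ComponentSummary, genus: str = ""
) -> AbsorptionContrast:
    """Black-area minus orange-area contrast with quadrature-propagated error."""
    if black.wavelengths.shape != orange.wavelengths.shape or not np.allclose(
        black.wavelengths, orange.wavelengths
    ):
        raise ValueError("summaries must come from the same grid")
    value = black.mean_area - orange.mean_area
    error = float(np.hypot(black.sd_area, orange.sd_area))
    return AbsorptionContrast(genus=genus or black.genus, value=float(value), error=error)


def default_grid(start: float = 400.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """Visible-range analysis grid, inclusive of both ends."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def contrast_analysis(
    spectra: list[ReflectanceSpectrum],
    lambda_max: float = 520.0,
    grid: np.ndarray | None = None,
):
    """Per-genus absorption-contrast table from a set of replicate spectra.

    Resamples every spectrum onto the analysis grid, weights by the pigment
    template, aggregates replicates per (genus, patch), and contrasts black
    against orange for each genus that has both patches.  Returns a pandas
    DataFrame with one row per genus: areas, percentage SDs, signed
    contrast, propagated error and the within-error flag.
    """
    import pandas as pd  # deferred: keeps the numeric core importable alone

    if grid is None:
        grid = default_grid()
    template = govardovskii_alpha(lambda_max, grid)
    by_group: dict[tuple[str, str], list[GreenComponent]] = {}
    for s in spectra:
        comp = green_component(resample(s, grid), template)
        by_group.setdefault((s.genus, s.patch), []).append(comp)
    summaries = {k: aggregate_replicates(v) for k, v in by_group.items()}
    rows = []
    for genus in sorted({g for g, _ in summaries}):
        black = summaries.get((genus, "black"))
        orange = summaries.get((genus, "orange"))
        if black is None or orange is None:
            continue
        c = absorption_contrast(black, orange, genus)
        rows.append(
            {
                "genus": genus,
                "black_area": black.mean_area,
                "black_sd_pct": black.sd_area_pct,
                "orange_area": orange.mean_area,
                "orange_sd_pct": orange.sd_area_pct,
                "contrast": c.value,
                "error": c.error,
                "within_error": c.within_error,
            }
        )
    return pd.DataFrame(rows)
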