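"""Deterministic two-step thermal inactivation kinetics.

The primary model is the log-linear survivor curve

    log10 C(t) = log10 C0 - t / D_T

where ``D_T`` (the decimal reduction time, minutes) is the time at constant
temperature ``T`` needed to destroy 90% of a heat-labile substance.  The
secondary (Bigelow) model describes how ``D_T`` changes with temperature,

    log10 D_T = log10 D_Tref + (T_ref - T) / z

where ``z`` (degrees C) is the temperature rise that reduces ``D_T`` tenfold
and ``D_Tref`` is the D value at the chosen reference temperature.

Both steps are ordinary least-squares fits on a log scale.  Parameter
confidence intervals are obtained by transforming the Student-t interval of
the fitted coefficient through the first-order error-propagation (delta)
rule ``delta(f(x)) = |f'(x)| * delta(x)``:

* ``D_T = -1/slope``        so  delta(D_T) = D_T**2 * delta(1/D_T)
* ``z = 1/slope``           so  delta(z)   = z**2  * delta(1/z)
* ``D_Tref = 10**intercept`` so delta(D_Tref) = ln(10) * D_Tref * delta(log10 D_Tref)

The secondary regression is parametrized as y = log10(D_T) on
x = (T_ref - T): the slope is then ``1/z`` (positive for inactivation data)
and the intercept is ``log10(D_Tref)`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InvalidInputError,
    NoInactivationError,
    TemperatureDependenceError,
)

__all__ = [
    "IsothermalDataset",
    "RegressionFit",
    "DTEstimate",
    "DTTable",
    "SecondaryFit",
    "ols_fit",
    "fit_primary",
    "fit_secondary",
    "propagate_delta",
    "confidence_band",
    "prediction_band",
]

#: Default divisor turning a 95% CI half-width into a normal sigma.
DEFAULT_CI_TO_SIGMA = 2.0


@dataclass(frozen=True)
class IsothermalDataset:
    """One constant-temperature survivor curve.

    Parameters
    ----------
    temperature : float
        Temperature of the isothermal experiment, degrees C.
    times : array-like
        Sampling times in minutes, non-negative, at least two distinct.
    log_conc : array-like
        log10 concentration at each time; same length as ``times``.
    label : str
        Free-text identifier.
    """

    temperature: float
    times: np.ndarray
    log_conc: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        log_conc = np.asarray(self.log_conc, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "log_conc", log_conc)
        if times.ndim != 1 or log_conc.ndim != 1:
            raise InvalidInputError("times and log_conc must be 1-D sequences")
        if len(times) != len(log_conc):
            raise InvalidInputError("times and log_conc must have equal length")
        if len(times) < 3:
            raise InvalidInputError("an isothermal dataset needs at least 3 points")
        if np.any(times < 0):
            raise InvalidInputError("times must be non-negative")
        if np.unique(times).size < 2:
            raise InvalidInputError("at least two distinct time values required")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(log_conc))):
            raise InvalidInputError("times and log_conc must be finite")

    @classmethod
    def from_concentrations(
        cls,
        temperature: float,
        times: Sequence[float],
        conc: Sequence[float],
        label: str = "",
    ) -> "IsothermalDataset":
        """Build a dataset from raw concentrations, taking log10.

        Raises
        ------
        InvalidInputError
            If any concentration is non-positive (cannot be log-transformed).
        """
        conc = np.asarray(conc, dtype=float)
        if np.any(conc <= 0):
            raise InvalidInputError(
                "concentrations must be strictly positive for the log transform"
            )
        return cls(temperature, np.asarray(times, float), np.log10(conc), label)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares summary shared by both kinetic steps.

    Carries everything the coefficient intervals and the confidence /
    prediction band formulas need: coefficient standard errors, the residual
    standard deviation ``resid_sd`` (denominator n-2), the centered sum of
    squares ``sxx`` = sum((x_i - x_bar)**2), and the Student-t quantile
    ``t_crit`` at ``alpha/2`` with ``n - 2`` degrees of freedom.
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    resid_sd: float
    sxx: float
    x_mean: float
    n: int
    alpha: float = 0.05
    t_crit: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidInputError("a regression fit needs n >= 3")
        if not self.sxx > 0:
            raise DegenerateDesignError("sxx must be positive (>= 2 distinct x)")
        if self.resid_sd < 0:
            raise InvalidInputError("resid_sd must be non-negative")

    @property
    def df(self) -> int:
        """Residual degrees of freedom, n - 2."""
        return self.n - 2

    def predict(self, x0):
        """Fitted mean response at ``x0``."""
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


@dataclass(frozen=True)
class DTEstimate:
    """A D value at one temperature with its 95% CI and sampling sigma.

    ``sigma`` is the normal standard deviation used when the estimate is
    resampled by the Monte Carlo machinery; by default it is
    ``ci95_half / 2`` (see :data:`DEFAULT_CI_TO_SIGMA`).
    """

    temperature: float
    d_value: float
    ci95_half: float = 0.0
    sigma: Optional[float] = None
    fit: Optional[RegressionFit] = None

    def __post_init__(self) -> None:
        if not self.d_value > 0:
            raise InvalidInputError("d_value must be positive")
        if self.ci95_half < 0:
            raise InvalidInputError("ci95_half must be non-negative")
        if self.sigma is None:
            object.__setattr__(self, "sigma", self.ci95_half / DEFAULT_CI_TO_SIGMA)
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")

    def with_sigma_from_ci(self, ci_to_sigma_factor: float) -> "DTEstimate":
        """Return a copy whose sigma is ``ci95_half / ci_to_sigma_factor``."""
        if not ci_to_sigma_factor > 0:
            raise InvalidInputError("ci_to_sigma_factor must be positive")
        return replace(self, sigma=self.ci95_half / ci_to_sigma_factor)


@dataclass(frozen=True)
class DTTable:
    """A set of per-temperature D estimates (>= 3 distinct temperatures)."""

    entries: tuple

    def __init__(self, entries: Sequence[DTEstimate]):
        entries = tuple(entries)
        if len(entries) < 3:
            raise InvalidInputError("a DTTable needs at least 3 temperatures")
        temps = [e.temperature for e in entries]
        if len(set(temps)) != len(temps):
            raise InvalidInputError("temperatures must be pairwise distinct")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([e.temperature for e in self.entries])

    @property
    def d_values(self) -> np.ndarray:
        return np.array([e.d_value for e in self.entries])

    @property
    def ci95_halves(self) -> np.ndarray:
        return np.array([e.ci95_half for e in self.entries])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([e.sigma for e in self.entries])

    def with_sigma_from_ci(self, ci_to_sigma_factor: float) -> "DTTable":
        return DTTable([e.with_sigma_from_ci(ci_to_sigma_factor) for e in self])

    def scaled_ci(self, factor: float) -> "DTTable":
        """Scale every CI half-width (and sigma) by ``factor``."""
        return DTTable(
            [
                replace(
                    e,
                    ci95_half=e.ci95_half * factor,
                    sigma=e.sigma * factor,
                )
                for e in self
            ]
        )


@dataclass(frozen=True)
class SecondaryFit:
    """Bigelow secondary-model fit: D_Tref and z with 95% CI half-widths."""

    t_ref: float
    d_tref: float
    d_tref_ci95_half: float
    z: float
    z_ci95_half: float
    fit: RegressionFit

    def __post_init__(self) -> None:
        if not (self.d_tref > 0 and self.z > 0):
            raise InvalidInputError("d_tref and z must be positive")
        if self.d_tref_ci95_half < 0 or self.z_ci95_half < 0:
            raise InvalidInputError("CI half-widths must be non-negative")

    def predict_log10_d(self, temperature):
        """log10 D at ``temperature`` from the fitted model."""
        return np.log10(self.d_tref) + (self.t_ref - np.asarray(temperature)) / self.z


def ols_fit(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> RegressionFit:
    """Ordinary least-squares line fit with the summary both steps reuse.

    Parameters
    ----------
    x, y : sequences of equal length >= 3, with >= 2 distinct x values.
    alpha : float
        Two-sided significance level for ``t_crit`` (default 0.05).

    Returns
    -------
    RegressionFit
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 3:
        raise InvalidInputError("ols_fit needs at least 3 points")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all x values identical: slope undefined")

    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    resid_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    x_mean = float(np.mean(x))
    sxx = float(np.sum((x - x_mean) ** 2))
    # linregress stderrs assume resid_sd > 0 handled consistently; recompute
    # from the closed forms so a perfect line yields exact zeros.
    se_slope = resid_sd / np.sqrt(sxx)
    se_intercept = resid_sd * np.sqrt(1.0 / n + x_mean**2 / sxx)
    t_crit = float(stats.t.ppf(1 - alpha / 2, n - 2))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        resid_sd=resid_sd,
        sxx=sxx,
        x_mean=x_mean,
        n=n,
        alpha=alpha,
        t_crit=t_crit,
    )


def propagate_delta(kind: str, value: float, delta_in: float) -> float:
    """First-order (delta-method) transform of a CI half-width.

    Parameters
    ----------
    kind : {"d_from_inv_d", "z_from_inv_z", "d_from_log_d"}
        ``d_from_inv_d``: from delta(1/D) to delta(D) = D**2 * delta(1/D).
        ``z_from_inv_z``: from delta(1/z) to delta(z) = z**2 * delta(1/z).
        ``d_from_log_d``: from delta(log10 D) to delta(D) = ln(10)*D*delta.
    value : float
        The (positive) parameter value on the target scale.
    delta_in : float
        CI half-width of the transformed parameter, >= 0.
    """
    if not value > 0:
        raise InvalidInputError("value must be positive")
    if delta_in < 0:
        raise InvalidInputError("delta_in must be non-negative")
    if kind in ("d_from_inv_d", "z_from_inv_z"):
        return value**2 * delta_in
    if kind == "d_from_log_d":
        return float(np.log(10.0)) * value * delta_in
    raise InvalidInputError(f"unknown delta-transform kind: {kind!r}")


def fit_primary(
    dataset: IsothermalDataset,
    alpha: float = 0.05,
    ci_to_sigma_factor: float = DEFAULT_CI_TO_SIGMA,
) -> DTEstimate:
    """Fit the log-linear survivor curve and return D_T with its 95% CI.

    D_T is the negative reciprocal of the slope of log10 C vs t.  The CI
    half-width transforms the slope's Student-t interval through the delta
    rule: delta(D_T) = D_T**2 * t_crit * se_slope.

    Raises
    ------
    NoInactivationError
        If the fitted slope is non-negative (no decay: D_T undefined).
    """
    fit = ols_fit(dataset.times, dataset.log_conc, alpha=alpha)
    if fit.slope >= 0:
        raise NoInactivationError(
            f"slope {fit.slope:.4g} >= 0 at {dataset.temperature} C: no inactivation"
        )
    d_value = -1.0 / fit.slope
    ci95_half = propagate_delta("d_from_inv_d", d_value, fit.t_crit * fit.se_slope)
    return DTEstimate(
        temperature=dataset.temperature,
        d_value=d_value,
        ci95_half=ci95_half,
        sigma=ci95_half / ci_to_sigma_factor,
        fit=fit,
    )


def fit_secondary(table: DTTable, t_ref: float = 120.0, alpha: float = 0.05) -> SecondaryFit:
    """Fit the Bigelow model to a table of D values.

    Regresses y = log10(D_T) on x = (t_ref - T); then z = 1/slope and
    D_Tref = 10**intercept.  CI half-widths come from the coefficients'
    Student-t intervals through the delta transforms.

    Raises
    ------
    TemperatureDependenceError
        If the slope is non-positive (D does not decrease with temperature).
    """
    x = t_ref - table.temperatures
    y = np.log10(table.d_values)
    fit = ols_fit(x, y, alpha=alpha)
    if fit.slope <= 0:
        raise TemperatureDependenceError(
            "log10(D) does not decrease with temperature: z undefined"
        )
    z = 1.0 / fit.slope
    d_tref = 10.0**fit.intercept
    z_ci = propagate_delta("z_from_inv_z", z, fit.t_crit * fit.se_slope)
    d_ci = propagate_delta("d_from_log_d", d_tref, fit.t_crit * fit.se_intercept)
    return SecondaryFit(
        t_ref=t_ref,
        d_tref=d_tref,
        d_tref_ci95_half=d_ci,
        z=z,
        z_ci95_half=z_ci,
        fit=fit,
    )


def confidence_band(fit: RegressionFit, x0) -> np.ndarray:
    """95% confidence-band half-width for the mean response at ``x0``.

    t_crit * resid_sd * sqrt(1/N + (x0 - x_bar)**2 / sxx); symmetric around
    the fitted line.  Accepts scalars or arrays.
    """
    x0 = np.asarray(x0, dtype=float)
    hw = fit.t_crit * fit.resid_sd * np.sqrt(
        1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx
    )
    return hw if hw.ndim else float(hw)


def prediction_band(fit: RegressionFit, x0) -> np.ndarray:
    """95% prediction-band half-width for a new observation at ``x0``.

    t_crit * resid_sd * sqrt(1 + 1/N + (x0 - x_bar)**2 / sxx).
    """
    x0 = np.asarray(x0, dtype=float)
    hw = fit.t_crit * fit.resid_sd * np.sqrt(
        1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx
    )
    return hw if hw.ndim else float(hw)
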