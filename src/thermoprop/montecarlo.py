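"""Nested Monte Carlo propagation of D_T uncertainty into D_Tref and z.

The two-stage scheme:

* **Stage 1 (outer).**  Each temperature's D value is treated as a random
  variable, normal with mean equal to the estimate and sigma equal to its
  95% CI half-width divided by ``ci_to_sigma_factor``, discretized on a
  0.5-sigma grid.  ``n_outer`` joint sets of D values (independent across
  temperatures) are drawn and the Bigelow secondary model is refitted to
  each set, giving ``n_outer`` pairs of (D_Tref, CI) and (z, CI).
* **Stage 2 (inner).**  Each outer fit's parameters are themselves treated
  as discretized normals (mu = estimate, sigma = CI / ci_to_sigma_factor)
  and ``n_inner`` values are drawn from each, independently per parameter.

The pooled ``n_outer * n_inner`` values per parameter define the reported
mean, SD and 95% CI half-width (``summary_ci_factor * SD`` by default).

Outer D sets whose secondary regression has a non-positive slope (possible
under very wide input CIs) are rejected and redrawn, with a logged count;
the run aborts if the rejection rate exceeds ``max_reject_fraction``.

Randomness uses one root :class:`numpy.random.SeedSequence` spawning named
sub-streams (one per temperature for stage 1, one per parameter for stage
2, one per size in the sensitivity analysis) so each component is
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import DiscretizedNormal, discretize_normal, sample_discretized
from .exceptions import InvalidInputError, TemperatureDependenceError, ThermopropError
from .kinetics import DTTable, fit_secondary

__all__ = [
    "MCConfig",
    "MCResult",
    "SensitivityResult",
    "run_two_stage_mc",
    "summarize_pooled",
    "validate_sampler",
    "sensitivity_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCConfig:
    """Configuration of the nested Monte Carlo scheme.

    Attributes
    ----------
    n_outer, n_inner : int
        Outer (D-set) and inner (per-fit) sample counts; default 500 each.
    seed : int
        Root seed for the whole run.
    t_ref : float
        Reference temperature for the secondary model, degrees C.
    ci_to_sigma_factor : float
        Divisor converting a 95% CI half-width into a normal sigma
        (default 2.0; 1.96 or a Student-t quantile are alternatives).
    summary_ci_factor : float
        Multiplier converting the pooled SD into the reported 95% CI
        half-width (default 2.0, mirroring the input convention).
    truncation_half_width_sigma : float
        Extent of the discretization grid in sigma units (default 4.0).
    alpha : float
        Significance level for the per-set regression intervals.
    stage2_sampling : {"discretized", "normal"}
        Whether stage 2 reuses the 0.5-sigma discretization (default) or
        samples the fitted parameters from continuous normals.
    degenerate_policy : {"redraw", "error"}
        What to do with outer D sets whose secondary slope is <= 0.
    summary_method : {"sd", "percentile"}
        Pooled CI from summary_ci_factor*SD (default) or from the
        2.5/97.5 percentiles.
    """

    n_outer: int = 500
    n_inner: int = 500
    seed: int = 0
    t_ref: float = 120.0
    ci_to_sigma_factor: float = 2.0
    summary_ci_factor: float = 2.0
    truncation_half_width_sigma: float = 4.0
    alpha: float = 0.05
    stage2_sampling: str = "discretized"
    degenerate_policy: str = "redraw"
    max_reject_fraction: float = 0.2
    summary_method: str = "sd"

    def __post_init__(self) -> None:
        if self.n_outer < 1 or self.n_inner < 1:
            raise InvalidInputError("n_outer and n_inner must be >= 1")
        if self.ci_to_sigma_factor <= 0 or self.summary_ci_factor <= 0:
            raise InvalidInputError("CI conversion factors must be positive")
        if self.stage2_sampling not in ("discretized", "normal"):
            raise InvalidInputError("stage2_sampling must be 'discretized' or 'normal'")
        if self.degenerate_policy not in ("redraw", "error"):
            raise InvalidInputError("degenerate_policy must be 'redraw' or 'error'")
        if self.summary_method not in ("sd", "percentile"):
            raise InvalidInputError("summary_method must be 'sd' or 'percentile'")


@dataclass(frozen=True)
class MCResult:
    """Pooled Monte Carlo output for one secondary-model parameter."""

    parameter: str
    pooled_values: np.ndarray
    mean: float
    sd: float
    ci95_half: float
    per_outer_estimates: np.ndarray
    per_outer_ci95_half: np.ndarray
    n_rejected: int = 0


@dataclass(frozen=True)
class SensitivityResult:
    """Summary table of the Monte Carlo size sensitivity analysis."""

    table: pd.DataFrame  # columns: label, n_outer, n_inner, parameter, mean, sd, ci95_half

    def row(self, label: str, parameter: str) -> pd.Series:
        t = self.table
        hit = t[(t["label"] == label) & (t["parameter"] == parameter)]
        if hit.empty:
            raise KeyError((label, parameter))
        return hit.iloc[0]


def summarize_pooled(
    values: Sequence[float], config: MCConfig
) -> Tuple[float, float, float]:
    """Mean, sample SD (n-1) and 95% CI half-width of pooled draws."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("summarize_pooled needs at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if config.summary_method == "percentile":
        lo, hi = np.percentile(values, [2.5, 97.5])
        ci95_half = float((hi - lo) / 2.0)
    else:
        ci95_half = config.summary_ci_factor * sd
    return mean, sd, ci95_half


def _secondary_batch(x: np.ndarray, d_sets: np.ndarray, alpha: float):
    """Vectorized Bigelow fits of many D sets against fixed x = t_ref - T.

    Returns arrays (slope, d_tref, d_tref_ci, z, z_ci) of length n_sets.
    Rows with non-positive slope get NaN parameter values (the caller
    decides the degenerate policy).
    """
    with np.errstate(all="ignore"):
        y = np.log10(d_sets)  # (n_sets, n_temps)
    n = x.size
    x_mean = x.mean()
    xc = x - x_mean
    sxx = float(np.sum(xc**2))
    with np.errstate(all="ignore"):
        slope = y @ xc / sxx
        intercept = y.mean(axis=1) - slope * x_mean
        resid = y - (intercept[:, None] + slope[:, None] * x[None, :])
        resid_sd = np.sqrt(np.sum(resid**2, axis=1) / (n - 2))
    se_slope = resid_sd / np.sqrt(sxx)
    se_intercept = resid_sd * np.sqrt(1.0 / n + x_mean**2 / sxx)
    t_crit = stats.t.ppf(1 - alpha / 2, n - 2)

    # a set with any non-positive D (possible when sigma is huge) yields a
    # non-finite row in y and is marked degenerate alongside slope <= 0
    ok = (slope > 0) & np.all(np.isfinite(y), axis=1)
    slope = np.where(ok, slope, np.nan)
    z = np.where(ok, 1.0 / np.where(ok, slope, 1.0), np.nan)
    d_tref = np.where(ok, 10.0**intercept, np.nan)
    z_ci = z**2 * t_crit * se_slope
    d_ci = np.log(10.0) * d_tref * t_crit * se_intercept
    return slope, d_tref, d_ci, z, z_ci


def _draw_d_sets(
    sigmas: np.ndarray,
    mus: np.ndarray,
    n_sets: int,
    temp_rngs: Sequence[np.random.Generator],
    half_width_sigma: float,
) -> np.ndarray:
    """Draw n_sets joint D vectors, one discretized normal per temperature."""
    cols = []
    for mu, sigma, rng in zip(mus, sigmas, temp_rngs):
        dist = discretize_normal(mu, sigma, half_width_sigma)
        cols.append(sample_discretized(dist, n_sets, rng))
    return np.column_stack(cols)


def _sample_stage2(
    estimates: np.ndarray,
    sigmas: np.ndarray,
    n_inner: int,
    rng: np.random.Generator,
    config: MCConfig,
) -> np.ndarray:
    """Draw n_inner values per outer fit; returns (n_outer, n_inner)."""
    u = rng.standard_normal((estimates.size, n_inner))
    if config.stage2_sampling == "normal":
        return estimates[:, None] + sigmas[:, None] * u
    kmax = int(round(2 * config.truncation_half_width_sigma))
    k = np.clip(np.rint(u / 0.5), -kmax, kmax)
    return estimates[:, None] + 0.5 * sigmas[:, None] * k


def run_two_stage_mc(
    table: DTTable,
    config: MCConfig,
    seed_seq: Optional[np.random.SeedSequence] = None,
) -> Tuple[MCResult, MCResult]:
    """Run the nested Monte Carlo; returns (D_Tref result, z result).

    ``seed_seq`` overrides ``config.seed`` when given (used internally by
    the sensitivity analysis to hand out independent sub-streams).
    """
    table = table.with_sigma_from_ci(config.ci_to_sigma_factor)
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    n_temps = len(table)
    children = seed_seq.spawn(n_temps + 2)
    temp_rngs = [np.random.default_rng(s) for s in children[:n_temps]]
    rng_dtref = np.random.default_rng(children[n_temps])
    rng_z = np.random.default_rng(children[n_temps + 1])

    mus = table.d_values
    sigmas = table.sigmas
    x = config.t_ref - table.temperatures

    # Stage 1: outer D sets and one secondary fit per set, with redraws
    # for sets whose regression slope is non-positive.
    d_sets = _draw_d_sets(
        sigmas, mus, config.n_outer, temp_rngs, config.truncation_half_width_sigma
    )
    slope, d_tref, d_ci, z, z_ci = _secondary_batch(x, d_sets, config.alpha)
    n_rejected = 0
    while True:
        bad = np.where(~(slope > 0))[0]
        if bad.size == 0:
            break
        if config.degenerate_policy == "error":
            raise TemperatureDependenceError(
                f"{bad.size} outer D set(s) produced a non-positive secondary slope"
            )
        n_rejected += bad.size
        total = config.n_outer + n_rejected
        if n_rejected > config.max_reject_fraction * total:
            raise ThermopropError(
                f"rejection rate {n_rejected}/{total} exceeds "
                f"{config.max_reject_fraction:.0%}: input CIs too wide for "
                "a meaningful secondary fit"
            )
        redraw = _draw_d_sets(
            sigmas, mus, bad.size, temp_rngs, config.truncation_half_width_sigma
        )
        s2, dt2, dci2, z2, zci2 = _secondary_batch(x, redraw, config.alpha)
        slope[bad], d_tref[bad], d_ci[bad], z[bad], z_ci[bad] = s2, dt2, dci2, z2, zci2
    if n_rejected:
        logger.info("redrew %d degenerate outer D set(s)", n_rejected)

    # Stage 2: inner draws from each outer fit's parameter distribution.
    pooled_d = _sample_stage2(
        d_tref, d_ci / config.ci_to_sigma_factor, config.n_inner, rng_dtref, config
    ).ravel()
    pooled_z = _sample_stage2(
        z, z_ci / config.ci_to_sigma_factor, config.n_inner, rng_z, config
    ).ravel()

    results = []
    for name, pooled, est, ci in (
        ("D_Tref", pooled_d, d_tref, d_ci),
        ("z", pooled_z, z, z_ci),
    ):
        mean, sd, ci95 = summarize_pooled(pooled, config)
        results.append(
            MCResult(
                parameter=name,
                pooled_values=pooled,
                mean=mean,
                sd=sd,
                ci95_half=ci95,
                per_outer_estimates=est,
                per_outer_ci95_half=ci,
                n_rejected=n_rejected,
            )
        )
    return results[0], results[1]


def validate_sampler(table: DTTable, n: int, config: MCConfig) -> pd.DataFrame:
    """Check the discretized sampler by re-estimating each input D value.

    Draws ``n`` values per temperature from its discretized normal and
    reports the recovered mean and recovered CI half-width
    (``summary_ci_factor * SD``) next to the inputs; the recovered mean
    should sit within ~3*sigma/sqrt(n) of the input mean.
    """
    table = table.with_sigma_from_ci(config.ci_to_sigma_factor)
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    for entry, child in zip(table, seed_seq.spawn(len(table))):
        rng = np.random.default_rng(child)
        dist = discretize_normal(
            entry.d_value, entry.sigma, config.truncation_half_width_sigma
        )
        draws = sample_discretized(dist, n, rng)
        sd = float(draws.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "temperature_C": entry.temperature,
                "D_min": entry.d_value,
                "CI95_half_min": entry.ci95_half,
                "recovered_mean": float(draws.mean()),
                "recovered_ci95_half": config.summary_ci_factor * sd,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_analysis(
    table: DTTable,
    sizes: Sequence[Tuple[int, int]],
    config: MCConfig,
) -> SensitivityResult:
    """Repeat the nested Monte Carlo over a range of (n_outer, n_inner).

    Each size gets an independent sub-stream of the root seed, so the
    whole analysis is reproducible and sizes do not share draws.
    """
    if not sizes:
        raise InvalidInputError("sizes must be non-empty")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(sizes))
    rows = []
    for (n_out, n_in), child in zip(sizes, children):
        cfg = replace(config, n_outer=n_out, n_inner=n_in)
        res_d, res_z = run_two_stage_mc(table, cfg, seed_seq=child)
        label = f"{n_out}x{n_in}"
        for res in (res_d, res_z):
            rows.append(
                {
                    "label": label,
                    "n_outer": n_out,
                    "n_inner": n_in,
                    "parameter": res.parameter,
                    "mean": res.mean,
                    "sd": res.sd,
                    "ci95_half": res.ci95_half,
                    "n_rejected": res.n_rejected,
                }
            )
    return SensitivityResult(table=pd.DataFrame(rows))
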