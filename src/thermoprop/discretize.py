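"""Discretized-normal distributions on a 0.5-sigma grid.

A normal distribution N(mu, sigma) is replaced by bins of width 0.5*sigma,
the central bin spanning [mu - 0.25*sigma, mu + 0.25*sigma].  Each bin is
represented by its midpoint and carries the normal probability mass of the
bin; the mass beyond the truncation half-width is folded into the two
outermost bins so that total mass stays 1 and the expectation stays at mu.
Sampling draws a standard normal deviate and assigns the midpoint of the
bin it falls in (out-of-range deviates land in the nearest outermost bin),
which realises exactly those bin masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidInputError

__all__ = ["DiscretizedNormal", "discretize_normal", "sample_discretized"]


@dataclass(frozen=True)
class DiscretizedNormal:
    """Midpoint/probability representation of a 0.5-sigma binned normal."""

    mu: float
    sigma: float
    midpoints: np.ndarray
    probabilities: np.ndarray
    half_width_sigma: float

    @property
    def mean(self) -> float:
        """Expectation of the discrete distribution (== mu by symmetry)."""
        return float(np.dot(self.midpoints, self.probabilities))

    @property
    def sd(self) -> float:
        """Standard deviation of the discrete distribution."""
        m = self.mean
        return float(np.sqrt(np.dot((self.midpoints - m) ** 2, self.probabilities)))

    def probability_of(self, midpoint: float, atol: float = None) -> float:
        """Mass of the bin whose midpoint is within ``atol`` of ``midpoint``.

        The default tolerance is tight (1e-9 in absolute units); pass a
        looser one to look up midpoints quoted at printed precision.
        """
        if atol is None:
            atol = 1e-9 * max(1.0, abs(self.sigma))
        idx = np.where(np.abs(self.midpoints - midpoint) <= atol)[0]
        if idx.size == 0:
            raise InvalidInputError(f"{midpoint} is not a bin midpoint")
        return float(self.probabilities[idx[0]])


def discretize_normal(
    mu: float, sigma: float, half_width_sigma: float = 4.0
) -> DiscretizedNormal:
    """Discretize N(mu, sigma) into 0.5-sigma bins.

    Parameters
    ----------
    mu : float
        Location of the normal distribution.
    sigma : float
        Scale, >= 0.  ``sigma == 0`` degenerates to a single bin at mu
        with probability 1.
    half_width_sigma : float
        How many sigmas the outermost midpoints extend to (default 4.0);
        tail mass beyond the outermost bin edges is folded inward.
    """
    if sigma < 0:
        raise InvalidInputError("sigma must be non-negative")
    if not half_width_sigma > 0:
        raise InvalidInputError("half_width_sigma must be positive")
    if sigma == 0:
        return DiscretizedNormal(
            mu=mu,
            sigma=0.0,
            midpoints=np.array([mu]),
            probabilities=np.array([1.0]),
            half_width_sigma=half_width_sigma,
        )
    kmax = int(round(2 * half_width_sigma))
    k = np.arange(-kmax, kmax + 1)
    midpoints = mu + 0.5 * sigma * k
    lower = (0.5 * k - 0.25)  # bin edges in sigma units
    upper = (0.5 * k + 0.25)
    probabilities = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    # fold the residual tails into the outermost bins
    probabilities[0] += stats.norm.cdf(lower[0])
    probabilities[-1] += stats.norm.sf(upper[-1])
    return DiscretizedNormal(
        mu=float(mu),
        sigma=float(sigma),
        midpoints=midpoints,
        probabilities=probabilities,
        half_width_sigma=float(half_width_sigma),
    )


def sample_discretized(
    dist: DiscretizedNormal, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` midpoints from a discretized normal.

    Each draw generates a standard normal deviate and returns the midpoint
    of the 0.5-sigma bin containing it; deviates beyond the truncation
    half-width map to the outermost bins, matching the folded tail mass.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if dist.sigma == 0:
        return np.full(n, dist.mu)
    u = rng.standard_normal(n)
    kmax = int(round(2 * dist.half_width_sigma))
    k = np.clip(np.rint(u / 0.5), -kmax, kmax)
    return dist.mu + 0.5 * dist.sigma * k
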