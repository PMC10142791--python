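"""Bounded, right-skewed distributions for cell dimensions.

Morphometric tables summarise observed cell dimensions as mean, sd, min and
max. The printed minimum acts as a resolution floor (nothing below ~3 px is
measured), so a distribution matched to the table must place its support at
that floor rather than at zero: a plain lognormal truncated to the printed
[min, max] cannot, in general, reproduce the printed mean and sd (the
attainable moment set of that two-parameter family on a short interval does
not contain them).

The model used here is a lognormal with location offset at the printed
minimum, right-truncated at the printed maximum, with (mu, sigma) fit so the
truncated distribution reproduces the printed mean and sd exactly. Sampling
is by inverse CDF, so a fixed uniform stream maps to a fixed sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class BoundedLognormal:
    """Lognormal with ``loc`` at ``lo``, conditioned on values <= ``hi``."""

    mu: float
    sigma: float
    lo: float
    hi: float
    mean: float  # achieved truncated mean
    sd: float    # achieved truncated sd

    @property
    def _frozen(self):
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu), loc=self.lo)

    def ppf(self, q):
        """Quantile of the [lo, hi]-truncated law, q in [0, 1]."""
        if self.sigma <= 0 or self.hi <= self.lo:
            return np.full_like(np.asarray(q, dtype=float), self.mean)
        d = self._frozen
        z = d.cdf(self.hi)
        x = d.ppf(np.asarray(q, dtype=float) * z)
        return np.clip(x, self.lo, self.hi)

    def ppf_interval(self, q, a, b):
        """Quantile of the law further conditioned to [a, b] ⊂ [lo, hi].

        ``a`` and ``b`` may be arrays (per-sample intervals). Intervals are
        clipped to [lo, hi]; an empty interval yields NaN so callers can
        resample.
        """
        if self.sigma <= 0 or self.hi <= self.lo:
            return np.full_like(np.asarray(q, dtype=float), self.mean)
        a = np.clip(np.asarray(a, dtype=float), self.lo, self.hi)
        b = np.clip(np.asarray(b, dtype=float), self.lo, self.hi)
        d = self._frozen
        fa, fb = d.cdf(a), d.cdf(b)
        with np.errstate(invalid="ignore"):
            x = d.ppf(fa + np.asarray(q, dtype=float) * (fb - fa))
        x = np.where(b > a, x, np.nan)
        return np.clip(x, a, np.maximum(a, b))

    def sample(self, n: int, rng: np.random.Generator):
        return self.ppf(rng.random(n))


def _truncated_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and sd of lo + LN(mu, sigma) conditioned on the sum <= hi."""
    cap = hi - lo
    b = (np.log(cap) - mu) / sigma
    z = stats.norm.cdf(b)
    if z <= 0:
        return np.nan, np.nan

    def ek(k):
        return np.exp(k * mu + 0.5 * k * k * sigma * sigma) * stats.norm.cdf(b - k * sigma) / z

    m1 = ek(1)
    var = max(ek(2) - m1 * m1, 0.0)
    return lo + m1, np.sqrt(var)


@lru_cache(maxsize=512)
def fit_bounded_lognormal(mean: float, sd: float, lo: float, hi: float) -> BoundedLognormal:
    """Fit (mu, sigma) so the bounded law has the requested mean and sd.

    Degenerate inputs (sd <= 0, or hi <= lo) collapse to a point mass. Where
    the printed summary is infeasible (e.g. mean equal to max with nonzero
    sd) the fit is best-effort least squares and the achieved moments are
    recorded on the returned object.
    """
    if not (lo <= mean <= hi):
        raise ValueError(f"mean {mean} outside bounds [{lo}, {hi}]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0 or hi <= lo:
        return BoundedLognormal(0.0, 0.0, lo, hi, mean, 0.0)

    offset = max(mean - lo, 1e-6 * (hi - lo))
    s2 = np.log(1.0 + (sd / offset) ** 2)
    x0 = np.array([np.log(offset) - s2 / 2.0, np.sqrt(s2)])

    def resid(p):
        m, s = _truncated_moments(p[0], p[1], lo, hi)
        if not np.isfinite(m):
            return [1e3, 1e3]
        return [(m - mean) / mean, (s - sd) / sd]

    sol = optimize.least_squares(
        resid, x0,
        bounds=([-14.0, 1e-4], [np.log(hi - lo) + 2.0, 3.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    mu, sigma = sol.x
    m, s = _truncated_moments(mu, sigma, lo, hi)
    return BoundedLognormal(float(mu), float(sigma), lo, hi, float(m), float(s))


def lognormal_sphere_volume_mean(mean: float, sd: float) -> float:
    """Closed-form mean of (pi/6) d^3 for an (untruncated) lognormal diameter.

    E[d^3] = mu^3 (1 + sigma^2/mu^2)^3 in terms of the arithmetic mean and sd;
    used as the analytic cross-check for Monte-Carlo volume estimates.
    """
    return np.pi / 6.0 * mean**3 * (1.0 + (sd / mean) ** 2) ** 3
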