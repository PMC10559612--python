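"""Seeded random sampling for Monte Carlo trials.

Two sources of randomness are distinguished:

* *parameter uncertainty* — the initial level of a rate is drawn once per
  trial around its point estimate (:func:`sample_initial_rate`);
* *trend stochasticity* — the year-over-year change ratio is redrawn every
  simulated year around its estimated trend (:func:`sample_change_ratio`).

Default families: a normal truncated at zero (mean = point estimate,
sd = spread) for initial rates, and a lognormal with median equal to the
estimated ratio and log-sd equal to the spread for change ratios. Both
degenerate to the exact point estimate at spread 0, which collapses the whole
pipeline to a deterministic closed form. Families are configurable via
:class:`SamplingConfig`.

Trial streams are spawned from a single master seed with
``numpy.random.SeedSequence`` so they are reproducible and mutually
non-overlapping by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingConfig",
    "trial_streams",
    "sample_initial_rate",
    "sample_change_ratio",
]

TRUNCATED_NORMAL = "truncated_normal"
LOGNORMAL = "lognormal"


@dataclass(frozen=True)
class SamplingConfig:
    """Distribution families, master seed and trial count for one scenario."""

    master_seed: int = 0
    n_trials: int = 100
    rate_distribution: str = TRUNCATED_NORMAL
    change_distribution: str = LOGNORMAL
    #: redraw change-ratio noise each simulated year (True) or once per trial
    redraw_change_each_year: bool = True

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.rate_distribution not in (TRUNCATED_NORMAL, LOGNORMAL):
            raise ValueError(f"unknown rate distribution {self.rate_distribution!r}")
        if self.change_distribution not in (TRUNCATED_NORMAL, LOGNORMAL):
            raise ValueError(f"unknown change distribution {self.change_distribution!r}")


def trial_streams(master_seed: int, n_trials: int) -> list[np.random.Generator]:
    """Spawn ``n_trials`` independent, reproducible generators from one seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n_trials)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def _truncated_normal_at_zero(mean: float, sd: float, rng: np.random.Generator) -> float:
    # Inverse-CDF draw from N(mean, sd) truncated to [0, inf); avoids
    # rejection loops so the stream advances by exactly one uniform.
    from scipy.stats import norm

    lo = norm.cdf(0.0, loc=mean, scale=sd)
    u = rng.uniform(lo, 1.0)
    return float(norm.ppf(u, loc=mean, scale=sd))


def sample_initial_rate(
    mean: float,
    spread: float,
    rng: np.random.Generator,
    distribution: str = TRUNCATED_NORMAL,
    upper: float | None = None,
) -> float:
    """Draw an initial rate around its point estimate.

    The draw is never negative; ``spread = 0`` returns ``mean`` exactly
    without consuming randomness. ``upper`` optionally caps the draw (used
    for proportions, which must stay within [0, 1]).
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if spread == 0:
        draw = mean
    elif distribution == TRUNCATED_NORMAL:
        draw = _truncated_normal_at_zero(mean, spread, rng)
    elif distribution == LOGNORMAL:
        if mean == 0:
            draw = 0.0
        else:
            # median = mean; spread interpreted as an absolute half-width,
            # mapped to a log-sd via the coefficient of variation.
            draw = mean * math.exp(rng.normal(0.0, spread / mean))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    draw = max(draw, 0.0)
    if upper is not None:
        draw = min(draw, upper)
    return draw


def sample_change_ratio(
    mean_ratio: float,
    spread: float,
    rng: np.random.Generator,
    distribution: str = LOGNORMAL,
) -> float:
    """Draw a year-over-year change ratio; always strictly positive.

    ``spread = 0`` returns ``mean_ratio`` exactly. The lognormal family has
    median ``mean_ratio`` and log-sd ``spread``, so the geometric mean of
    repeated draws recovers the estimated trend.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    if mean_ratio <= 0:
        raise ValueError("mean_ratio must be > 0")
    if spread == 0:
        return mean_ratio
    if distribution == LOGNORMAL:
        return float(mean_ratio * math.exp(rng.normal(0.0, spread)))
    if distribution == TRUNCATED_NORMAL:
        draw = _truncated_normal_at_zero(mean_ratio, spread, rng)
        return max(draw, 1e-12)  # ratios must stay positive
    raise ValueError(f"unknown distribution {distribution!r}")
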