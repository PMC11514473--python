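"""A value with a standard error, and first-order error propagation.

Rate constants, equilibrium constants and free energies throughout the
package carry propagated standard errors.  Propagation is first-order
(delta method); Monte-Carlo propagation is provided as an independent
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class Measurement:
    """A scalar with a standard error."""

    value: float
    err: float = 0.0

    def __post_init__(self) -> None:
        if self.err < 0:
            raise ValueError(f"err must be non-negative, got {self.err}")

    @property
    def rel(self) -> float:
        """Relative error |err/value| (inf for value == 0)."""
        if self.value == 0:
            return math.inf
        return abs(self.err / self.value)

    def __iter__(self):
        yield self.value
        yield self.err

    def __format__(self, spec: str) -> str:
        spec = spec or ".4g"
        return f"{self.value:{spec}} +/- {self.err:{spec}}"


def as_measurement(x) -> Measurement:
    """Coerce a float, (value, err) pair or Measurement to a Measurement."""
    if isinstance(x, Measurement):
        return x
    if np.isscalar(x):
        return Measurement(float(x), 0.0)
    v, e = x
    return Measurement(float(v), float(e))


def ratio(x, y) -> Measurement:
    """x/y with first-order propagation.

    sigma_r = r * sqrt((sx/x)^2 + (sy/y)^2); inputs must be nonzero
    (denominator) and positive errors are assumed independent.
    """
    x, y = as_measurement(x), as_measurement(y)
    if y.value == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    r = x.value / y.value
    err = abs(r) * math.sqrt(x.rel**2 + y.rel**2) if x.value != 0 else abs(x.err / y.value)
    return Measurement(r, err)


def product(x, y) -> Measurement:
    x, y = as_measurement(x), as_measurement(y)
    p = x.value * y.value
    if x.value == 0 or y.value == 0:
        return Measurement(p, math.hypot(x.err * y.value, y.err * x.value))
    return Measurement(p, abs(p) * math.sqrt(x.rel**2 + y.rel**2))


def log_ratio(x, y) -> Measurement:
    """ln(x/y) with propagated error sqrt((sx/x)^2 + (sy/y)^2)."""
    x, y = as_measurement(x), as_measurement(y)
    if x.value <= 0 or y.value <= 0:
        raise ValueError("log_ratio requires positive values")
    return Measurement(math.log(x.value / y.value), math.sqrt(x.rel**2 + y.rel**2))


def weighted_mean(values: Sequence[Measurement]) -> Measurement:
    """Inverse-variance weighted mean with its standard error.

    Falls back to the unweighted mean (and standard error of the mean)
    when any input lacks a positive error.
    """
    ms = [as_measurement(v) for v in values]
    if not ms:
        raise ValueError("weighted_mean of empty sequence")
    if any(m.err <= 0 for m in ms):
        vals = np.array([m.value for m in ms])
        sem = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
        return Measurement(float(vals.mean()), float(sem))
    w = np.array([1.0 / m.err**2 for m in ms])
    v = np.array([m.value for m in ms])
    return Measurement(float(np.sum(w * v) / np.sum(w)), float(1.0 / math.sqrt(np.sum(w))))


def monte_carlo(
    func: Callable[..., float],
    inputs: Sequence[Measurement],
    n_draws: int = 100_000,
    seed: int = 0,
) -> Measurement:
    """Monte-Carlo propagation: draw each input ~ N(value, err), push
    through ``func`` and report the sample mean and standard deviation.

    Serves as the independent cross-check of the analytic (delta-method)
    errors; non-finite draws (e.g. a negative rate under a log) are
    discarded.
    """
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [rng.normal(m.value, m.err, size=n_draws) for m in map(as_measurement, inputs)]
    )
    out = np.array([func(*row) for row in draws])
    out = out[np.isfinite(out)]
    if out.size < n_draws // 2:
        raise RuntimeError("Monte-Carlo propagation: too many invalid draws")
    return Measurement(float(out.mean()), float(out.std(ddof=1)))
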