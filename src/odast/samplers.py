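"""Univariate slice sampling (stepping-out and shrinkage).

Two entry points: :func:`slice_sample` updates a single scalar, and
:func:`slice_sample_vec` updates a whole array of *conditionally independent*
coordinates in lockstep, evaluating an elementwise log-density on the full
array.  Both implement the same procedure: draw an auxiliary height under the
density at the current point, step the initial bracket out in width-sized
increments with a randomized budget split, then shrink the bracket towards the
current point until a proposal lands inside the slice.  The update leaves the
target distribution invariant.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import DiagnosticError

_MAX_SHRINK = 1000  # bracket shrinks geometrically; this is never reached


def slice_sample(
    log_density: Callable[[float], float],
    x0: float,
    width: float = 1.0,
    max_steps: int = 50,
    rng: np.random.Generator | None = None,
) -> float:
    """One slice-sampling update of a scalar with target ``exp(log_density)``.

    ``width`` is the initial bracket size and ``max_steps`` bounds the total
    number of stepping-out expansions (split randomly between the two sides).
    """
    if rng is None:
        rng = np.random.default_rng()
    x0 = float(x0)
    f0 = float(log_density(x0))
    if not np.isfinite(f0):
        raise DiagnosticError(f"log-density not finite at the current point ({f0})")
    y = f0 - rng.exponential()
    left = x0 - width * rng.random()
    right = left + width
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and log_density(left) > y:
        left -= width
        j -= 1
    while k > 0 and log_density(right) > y:
        right += width
        k -= 1
    for _ in range(_MAX_SHRINK):
        x1 = left + rng.random() * (right - left)
        if log_density(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    raise DiagnosticError("slice shrinkage failed to terminate")


def slice_sample_vec(
    log_density: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    width: float | np.ndarray = 1.0,
    max_steps: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Slice-update every coordinate of ``x0`` simultaneously.

    ``log_density`` must map an array of coordinate values to the elementwise
    log-density of each coordinate's own univariate conditional; coordinates
    must be conditionally independent of one another for the joint update to
    be a valid Gibbs step.
    """
    if rng is None:
        rng = np.random.default_rng()
    x0 = np.asarray(x0, dtype=float)
    shape = x0.shape
    with np.errstate(over="ignore", invalid="ignore"):
        f0 = np.asarray(log_density(x0), dtype=float)
        if not np.isfinite(f0).all():
            bad = int(np.sum(~np.isfinite(f0)))
            raise DiagnosticError(
                f"log-density not finite at the current point for {bad} coordinate(s)"
            )
        y = f0 - rng.exponential(size=shape)
        left = x0 - width * rng.random(size=shape)
        right = left + width
        j = rng.integers(0, max_steps, size=shape)
        k = max_steps - 1 - j

        grow = (j > 0) & (log_density(left) > y)
        while grow.any():
            left = np.where(grow, left - width, left)
            j = j - grow
            grow = grow & (j > 0) & (log_density(left) > y)
        grow = (k > 0) & (log_density(right) > y)
        while grow.any():
            right = np.where(grow, right + width, right)
            k = k - grow
            grow = grow & (k > 0) & (log_density(right) > y)

        x = x0.copy()
        accepted = np.zeros(shape, dtype=bool)
        for _ in range(_MAX_SHRINK):
            prop = left + rng.random(size=shape) * (right - left)
            ok = log_density(prop) >= y
            take = ok & ~accepted
            x = np.where(take, prop, x)
            accepted |= take
            if accepted.all():
                return x
            shrink = ~accepted
            left = np.where(shrink & (prop < x0), prop, left)
            right = np.where(shrink & (prop >= x0), prop, right)
    raise DiagnosticError("slice shrinkage failed to terminate")
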