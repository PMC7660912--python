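"""Biased persistent random walk: the per-move direction distribution.

A motile cell picks one of the eight Moore-neighbourhood directions.
Directions are indexed 0-7 counter-clockwise from east::

    index   0      1         2    3        4     5          6     7
    move    right  up-right  up   up-left  left  down-left  down  down-right
    angle   0      pi/4      2pi/4 ...                            7pi/4

(the field's usual 1-8 numbering shifted to 0-based).  "Up" increases the
row coordinate; grids that couple to these moves store ``values[y, x]``.

The move distribution is the normalised product of a gradient factor
(softmax of the eight chemoattractant differences, sharpness ``k_grad``) and
a persistence factor (a discretised Gaussian over the angular distance to the
previous move direction, width ``sigma_mem``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_DIRECTIONS",
    "ANGLES",
    "MOVE_DY",
    "MOVE_DX",
    "neighbour_differences",
    "gradient_distribution",
    "memory_distribution",
    "combined_distribution",
    "sample_move",
]

N_DIRECTIONS = 8

#: angle of each move direction, radians CCW from east
ANGLES = np.arange(N_DIRECTIONS) * np.pi / 4

#: lattice displacement of each move (dy = vertical, "up" positive)
MOVE_DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)
MOVE_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)


def neighbour_differences(field: np.ndarray, y: int, x: int) -> np.ndarray:
    """Chemoattractant differences ``c_j - c_i`` to the 8 Moore neighbours.

    Periodic wrap on both axes; diagonal neighbours use the raw concentration
    difference (no distance correction).
    """
    h, w = field.shape
    yy = (y + MOVE_DY) % h
    xx = (x + MOVE_DX) % w
    return field[yy, xx] - field[y, x]


def _normalise(weights: np.ndarray) -> np.ndarray:
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        # unreachable with exp-based factors, but keep a safe uniform fallback
        import warnings

        warnings.warn("degenerate direction weights; falling back to uniform",
                      stacklevel=3)
        return np.full(N_DIRECTIONS, 1.0 / N_DIRECTIONS)
    return weights / total


def gradient_distribution(differences: np.ndarray, k_grad: float) -> np.ndarray:
    """Softmax of ``k_grad * (c_j - c_i)`` over the 8 directions.

    Shift-invariant by construction: the maximum exponent is subtracted
    before exponentiation (exact, not an approximation), which also guards
    against overflow at large ``k_grad``.
    """
    differences = np.asarray(differences, dtype=float)
    if differences.shape != (N_DIRECTIONS,):
        raise ValueError("expected 8 neighbour differences")
    if not np.all(np.isfinite(differences)):
        raise ValueError("neighbour differences must be finite")
    z = k_grad * differences
    w = np.exp(z - z.max())
    return _normalise(w)


def angular_distance(theta_a, theta_b, wrap: bool = True):
    """Angular separation; wrapped to [0, pi] by default.

    The unwrapped variant returns the raw difference ``theta_a - theta_b``
    (angles taken in [0, 2pi)) and is kept selectable for comparison: without
    wrapping, persistence is asymmetric around the previous heading.
    """
    d = np.asarray(theta_a, dtype=float) - theta_b
    if wrap:
        d = np.abs(d) % (2 * np.pi)
        d = np.minimum(d, 2 * np.pi - d)
    return d


def memory_distribution(theta_prev: float, sigma_mem: float,
                        wrap: bool = True) -> np.ndarray:
    """Discretised Gaussian persistence kernel over the 8 move angles.

    The mode sits at the previous move direction; ``sigma_mem`` (radians)
    sets how readily the cell turns.  Normalisation over the eight discrete
    angles replaces the continuous Gaussian constant.
    """
    if sigma_mem <= 0:
        raise ValueError("sigma_mem must be strictly positive")
    d = angular_distance(ANGLES, theta_prev, wrap=wrap)
    w = np.exp(-(d * d) / (2.0 * sigma_mem * sigma_mem))
    return _normalise(w)


def combined_distribution(grad: np.ndarray, mem: np.ndarray) -> np.ndarray:
    """Normalised elementwise product of gradient and persistence factors."""
    grad = np.asarray(grad, dtype=float)
    mem = np.asarray(mem, dtype=float)
    if grad.shape != (N_DIRECTIONS,) or mem.shape != (N_DIRECTIONS,):
        raise ValueError("expected two 8-direction distributions")
    return _normalise(grad * mem)


def sample_move(dist: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a direction index 0-7 from a direction distribution."""
    u = rng.random()
    return int(np.searchsorted(np.cumsum(dist), u, side="right").clip(0, 7))
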