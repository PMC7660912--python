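"""Reaction--diffusion mediator fields on the periodic lattice.

The pro- (``c``) and anti-inflammatory (``g``) mediators obey

    df/dt = D lap(f) - gamma f + sources,

discretised with a five-point Laplacian on a unit-spaced periodic grid and
explicit Euler substeps.  Agent releases are discrete per-tick deposits: an
amount is queued in a :class:`SourceAccumulator` during the agent phase and
added to the lattice exactly once, at the start of the next tick, before the
diffusion substeps.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

__all__ = [
    "SourceAccumulator",
    "MediatorField",
    "laplacian_5pt",
    "stable_substep_count",
    "init_circular_perturbation",
    "max_concentration",
    "write_snapshot",
]

logger = logging.getLogger(__name__)


def laplacian_5pt(field: np.ndarray) -> np.ndarray:
    """Five-point Laplacian with periodic wrap on both axes (unit spacing)."""
    return (
        np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0)
        + np.roll(field, 1, axis=1) + np.roll(field, -1, axis=1)
        - 4.0 * field
    )


def stable_substep_count(D: float, safety: float = 0.5) -> tuple[int, float]:
    """Number of Euler substeps per tick and substep size ``dt``.

    The 2-D explicit-Euler von Neumann bound on a unit grid is
    ``dt < 1/(4D)``; we take ``dt <= safety/(4D)`` and choose the smallest
    integer substep count with ``dt = 1/n_substeps`` satisfying it, so a tick
    is always an integer number of substeps.  ``D = 0`` needs no substepping.
    """
    if D < 0:
        raise ValueError("diffusivity must be non-negative")
    if not (0.0 < safety <= 1.0):
        raise ValueError("safety factor must lie in (0, 1]")
    if D == 0:
        return 1, 1.0
    n = max(1, math.ceil(4.0 * D / safety))
    return n, 1.0 / n


class SourceAccumulator:
    """Pending mediator deposits for one field, applied once per tick.

    Internally an accumulation lattice: simultaneous deposits at one site are
    additive, and :meth:`drain` hands the accumulated increments to the PDE
    step exactly once.
    """

    def __init__(self, shape: tuple[int, int]):
        self.pending = np.zeros(shape, dtype=float)
        self.n_deposits = 0

    def deposit(self, position: tuple[int, int], amount: float) -> None:
        if amount < 0:
            raise ValueError("deposit amount must be non-negative")
        self.pending[position] += amount
        self.n_deposits += 1

    def drain(self) -> np.ndarray:
        out = self.pending
        self.pending = np.zeros_like(out)
        self.n_deposits = 0
        return out


class MediatorField:
    """One mediator lattice with its diffusion/decay constants and substepping.

    Parameters
    ----------
    values : array
        Initial non-negative concentration lattice.
    D, gamma : float
        Dimensionless diffusivity (grid^2/tick) and decay rate (1/tick).
    safety : float
        Fraction of the explicit-Euler stability bound used for ``dt``.
    """

    def __init__(self, values: np.ndarray, D: float, gamma: float,
                 safety: float = 0.5):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("mediator lattice must be 2-D")
        if np.any(values < 0):
            raise ValueError("mediator concentrations must be non-negative")
        if gamma < 0:
            raise ValueError("decay rate must be non-negative")
        self.values = values.copy()
        self.D = float(D)
        self.gamma = float(gamma)
        self.n_substeps, self.dt = stable_substep_count(D, safety)
        self.clamp_count = 0  # round-off negativities clamped so far

    def advance_tick(self, sources: SourceAccumulator | None = None) -> None:
        """Apply queued deposits, then run one tick of Euler substeps in place."""
        f = self.values
        if sources is not None:
            f += sources.drain()
        D, gamma, dt = self.D, self.gamma, self.dt
        for _ in range(self.n_substeps):
            f += dt * (D * laplacian_5pt(f) - gamma * f)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                "non-finite mediator concentration: the explicit Euler step "
                "is unstable for these parameters")
        neg = f < 0
        if neg.any():
            self.clamp_count += int(neg.sum())
            logger.warning("clamped %d negative mediator value(s) to zero",
                           int(neg.sum()))
            np.maximum(f, 0.0, out=f)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def init_circular_perturbation(shape: tuple[int, int],
                               r: float, c0: float,
                               centre: tuple[int, int] | None = None
                               ) -> np.ndarray:
    """Lattice with ``c0`` on sites within Euclidean distance ``r`` of the centre.

    The perturbation models the initial tissue insult.  ``r = 0`` perturbs
    exactly the centre site.
    """
    if r < 0 or c0 < 0:
        raise ValueError("r and c0 must be non-negative")
    h, w = shape
    if centre is None:
        centre = (h // 2, w // 2)
    if r > min(h, w) / 2:
        warnings.warn("perturbation radius exceeds half the domain; the disc "
                      "is clipped to the lattice", stacklevel=2)
    yy, xx = np.ogrid[:h, :w]
    mask = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= r * r
    field = np.zeros(shape, dtype=float)
    field[mask] = c0
    return field


def max_concentration(field: "MediatorField | np.ndarray") -> float:
    """Domain-maximum concentration of a field (the chronicity readout)."""
    values = field.values if isinstance(field, MediatorField) else field
    return float(np.max(values))


def write_snapshot(out_dir: str, tick: int, c: np.ndarray, g: np.ndarray) -> str:
    """Write both lattices for one tick as ``snap_t{tick}.npz`` under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"snap_t{tick}.npz")
    np.savez_compressed(path, c=c, g=g, tick=tick)
    return path
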