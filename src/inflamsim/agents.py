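"""Stochastic rule sets for the three immune-cell agent classes.

Macrophages move (preferring neighbouring apoptotic cells, else chemotaxing
up the pro-inflammatory gradient), phagocytose co-located apoptotic
neutrophils, release anti-inflammatory mediator once activated, leave
resolved tissue, and age out.  Active neutrophils chemotax, release
pro-inflammatory mediator, and on lifespan exhaustion become immobile
apoptotic cells, which eventually necrose and dump mediator.

These functions are the reference, per-agent semantics; the tick loop in
:mod:`inflamsim.engine` runs either on them directly (``backend="python"``)
or on an equivalent compiled kernel for large simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chemotaxis as cx
from .mediators import SourceAccumulator
from .params import ModelParams

__all__ = [
    "Macrophage",
    "Neutrophil",
    "ApoptoticNeutrophil",
    "draw_lifespan",
    "recruit_macrophages",
    "recruit_neutrophils",
    "macrophage_move",
    "phagocytose",
    "release_anti_inflammatory",
    "macrophage_departure",
    "neutrophil_step",
    "apoptotic_step",
]


@dataclass
class Macrophage:
    y: int
    x: int
    prev_dir: int              # last executed move direction, 0-7
    lifespan_remaining: int
    activated: bool = False    # set on first successful phagocytosis, sticky


@dataclass
class Neutrophil:
    y: int
    x: int
    prev_dir: int
    lifespan_remaining: int


@dataclass
class ApoptoticNeutrophil:
    y: int
    x: int
    necrosis_countdown: int    # position never changes; cell is immobile


_LIFESPAN_ATTR = {
    "macrophage": "macrophage_lifespan",
    "neutrophil": "neutrophil_lifespan",
    "apoptotic": "apoptotic_lifespan",
}


def draw_lifespan(agent_class: str, params: ModelParams,
                  rng: np.random.Generator) -> int:
    """Integer lifespan in ticks, uniform on the class interval (inclusive)."""
    try:
        lo, hi = getattr(params, _LIFESPAN_ATTR[agent_class])
    except KeyError:
        raise ValueError(f"unknown agent class {agent_class!r}") from None
    return int(rng.integers(lo, hi + 1))


def _shuffled_sites(shape: tuple[int, int],
                    rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    order = rng.permutation(h * w)
    return np.column_stack(np.divmod(order, w))


def recruit_macrophages(c: np.ndarray, params: ModelParams, current_count: int,
                        rng: np.random.Generator) -> list[Macrophage]:
    """Visit sites in shuffled order; where ``c > alpha_mr`` recruit with
    probability ``p_mr`` until the global cap ``m_max`` is reached."""
    recruits: list[Macrophage] = []
    for y, x in _shuffled_sites(c.shape, rng):
        if current_count + len(recruits) >= params.m_max:
            break
        if c[y, x] > params.alpha_mr and rng.random() < params.p_mr:
            recruits.append(Macrophage(
                y=int(y), x=int(x), prev_dir=int(rng.integers(8)),
                lifespan_remaining=draw_lifespan("macrophage", params, rng)))
    return recruits


def recruit_neutrophils(c: np.ndarray, g: np.ndarray, params: ModelParams,
                        current_count: int,
                        rng: np.random.Generator) -> list[Neutrophil]:
    """As for macrophages, but recruitment requires high ``c`` *and* low
    ``g`` (``c > alpha_ncr`` and ``g < alpha_ngr``), capped at ``n_max``."""
    recruits: list[Neutrophil] = []
    for y, x in _shuffled_sites(c.shape, rng):
        if current_count + len(recruits) >= params.n_max:
            break
        if (c[y, x] > params.alpha_ncr and g[y, x] < params.alpha_ngr
                and rng.random() < params.p_nr):
            recruits.append(Neutrophil(
                y=int(y), x=int(x), prev_dir=int(rng.integers(8)),
                lifespan_remaining=draw_lifespan("neutrophil", params, rng)))
    return recruits


def _chemotactic_direction(y: int, x: int, prev_dir: int, c: np.ndarray,
                           params: ModelParams,
                           rng: np.random.Generator) -> int:
    dc = cx.neighbour_differences(c, y, x)
    grad = cx.gradient_distribution(dc, params.k_grad)
    mem = cx.memory_distribution(cx.ANGLES[prev_dir], params.sigma_mem,
                                 wrap=params.wrap_angles)
    return cx.sample_move(cx.combined_distribution(grad, mem), rng)


def _block_3x3(field: np.ndarray, y: int, x: int) -> np.ndarray:
    h, w = field.shape
    return field[np.ix_([(y - 1) % h, y, (y + 1) % h],
                        [(x - 1) % w, x, (x + 1) % w])]


def macrophage_move(agent: Macrophage, apoptotic_count: np.ndarray,
                    c: np.ndarray, params: ModelParams,
                    rng: np.random.Generator) -> None:
    """One macrophage move, in priority order:

    1. a uniformly random neighbouring site holding apoptotic neutrophils;
    2. else a chemotactic move if any mediator is present nearby
       (3x3 max of ``c`` at least ``epsilon_c``);
    3. else a uniformly random neighbour.

    The executed direction becomes the new ``prev_dir`` in every branch.
    """
    h, w = c.shape
    yy = (agent.y + cx.MOVE_DY) % h
    xx = (agent.x + cx.MOVE_DX) % w
    candidates = np.flatnonzero(apoptotic_count[yy, xx] > 0)
    if candidates.size:
        d = int(candidates[rng.integers(candidates.size)])
    elif _block_3x3(c, agent.y, agent.x).max() >= params.epsilon_c:
        d = _chemotactic_direction(agent.y, agent.x, agent.prev_dir,
                                   c, params, rng)
    else:
        d = int(rng.integers(8))
    agent.y = int(yy[d])
    agent.x = int(xx[d])
    agent.prev_dir = d


def phagocytose(agent: Macrophage, apoptotic_here: list[ApoptoticNeutrophil],
                params: ModelParams, rng: np.random.Generator
                ) -> ApoptoticNeutrophil | None:
    """Select one co-located apoptotic cell at random and remove it with
    probability ``p_ma``.  The first successful removal permanently switches
    the macrophage to its activated (mediator-releasing) phenotype.

    Returns the removed apoptotic cell, or ``None``.
    """
    if not apoptotic_here:
        return None
    victim = apoptotic_here[int(rng.integers(len(apoptotic_here)))]
    if rng.random() < params.p_ma:
        agent.activated = True
        return victim
    return None


def release_anti_inflammatory(agent: Macrophage, g_sources: SourceAccumulator,
                              params: ModelParams,
                              rng: np.random.Generator) -> bool:
    """Queue a ``delta_mg`` deposit of ``g`` with probability ``p_mg``,
    if and only if the macrophage is activated.  Returns whether it released."""
    if agent.activated and rng.random() < params.p_mg:
        g_sources.deposit((agent.y, agent.x), params.delta_mg)
        return True
    return False


def macrophage_departure(agent: Macrophage, c: np.ndarray,
                         params: ModelParams,
                         rng: np.random.Generator) -> bool:
    """Leave the tissue with probability ``p_ml`` when the summed ``c`` over
    the 3x3 neighbourhood (own site included) is below ``alpha_ml``.
    Returns True if the macrophage departs."""
    c_bar = float(_block_3x3(c, agent.y, agent.x).sum())
    return c_bar < params.alpha_ml and rng.random() < params.p_ml


def neutrophil_step(agent: Neutrophil, c: np.ndarray,
                    c_sources: SourceAccumulator, params: ModelParams,
                    rng: np.random.Generator) -> ApoptoticNeutrophil | None:
    """One full neutrophil tick: chemotactic moves, mediator release,
    ageing, and in-place apoptotic replacement when the lifespan runs out.

    Returns the replacement :class:`ApoptoticNeutrophil` if the cell died.
    """
    h, w = c.shape
    for _ in range(params.neutrophil_moves_per_tick):
        d = _chemotactic_direction(agent.y, agent.x, agent.prev_dir,
                                   c, params, rng)
        agent.y = int((agent.y + cx.MOVE_DY[d]) % h)
        agent.x = int((agent.x + cx.MOVE_DX[d]) % w)
        agent.prev_dir = d
    if rng.random() < params.p_nc:
        c_sources.deposit((agent.y, agent.x), params.delta_nc)
    agent.lifespan_remaining -= 1
    if agent.lifespan_remaining <= 0:
        return ApoptoticNeutrophil(
            y=agent.y, x=agent.x,
            necrosis_countdown=draw_lifespan("apoptotic", params, rng))
    return None


def apoptotic_step(agent: ApoptoticNeutrophil,
                   c_sources: SourceAccumulator,
                   params: ModelParams) -> bool:
    """Count down to necrosis; on reaching zero, dump ``delta_ac`` of ``c``
    at the (never-changing) position and report removal.  Deterministic."""
    agent.necrosis_countdown -= 1
    if agent.necrosis_countdown <= 0:
        c_sources.deposit((agent.y, agent.x), params.delta_ac)
        return True
    return False
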