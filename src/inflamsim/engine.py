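"""The tick loop coupling mediator PDEs and immune-cell agents.

Each tick (one simulated minute): queued mediator deposits are applied and
both fields take their diffusion-decay substeps; neutrophils are recruited
on even ticks and macrophages every fifth tick at sites where the mediator
conditions hold; then every agent acts once, in one uniformly shuffled order
spanning all three classes.  Runs start from a circular pro-inflammatory
perturbation with no cells and no anti-inflammatory mediator.

Two backends implement identical rules: ``"python"`` drives the per-agent
reference functions of :mod:`inflamsim.agents` (transparent, fine for small
grids and short horizons) and ``"numba"`` (default) runs the compiled
kernel in :mod:`inflamsim._kernel` for production-size experiments.  Each
backend is bit-reproducible under a fixed seed; the two use different random
streams and so agree statistically, not sample-by-sample.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _kernel, agents as ag
from .mediators import (MediatorField, SourceAccumulator,
                        init_circular_perturbation, write_snapshot)
from .params import ModelParams, validate

__all__ = [
    "SimulationState",
    "SimulationSummary",
    "BatchSummary",
    "new_state",
    "step_tick",
    "run_simulation",
    "run_batch",
    "classify_outcome",
    "sensitivity_scan",
    "SENSITIVITY_PARAMS",
]

_SERIES = ("n_active", "n_apoptotic", "n_macrophage", "n_activated",
           "max_c", "max_g")


@dataclass
class SimulationSummary:
    """Per-tick global readouts, recorded every ``record_stride`` ticks
    (plus the final tick): cell counts and domain-maximum concentrations."""

    ticks: np.ndarray
    n_active: np.ndarray
    n_apoptotic: np.ndarray
    n_macrophage: np.ndarray
    n_activated: np.ndarray
    max_c: np.ndarray
    max_g: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"tick": self.ticks,
                             **{k: getattr(self, k) for k in _SERIES}})

    def final(self) -> dict[str, float]:
        return {k: getattr(self, k)[-1] for k in _SERIES}


@dataclass
class BatchSummary:
    """Mean and standard-deviation envelopes over a batch of runs."""

    ticks: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    outcomes: list[str]
    summaries: list[SimulationSummary]

    @property
    def tally(self) -> dict[str, int]:
        return dict(collections.Counter(self.outcomes))


@dataclass
class SimulationState:
    """Mutable python-backend state: fields, source queues and agent lists."""

    params: ModelParams
    c: MediatorField
    g: MediatorField
    c_sources: SourceAccumulator
    g_sources: SourceAccumulator
    macrophages: list = dc_field(default_factory=list)
    neutrophils: list = dc_field(default_factory=list)
    apoptotic: list = dc_field(default_factory=list)
    tick: int = 0
    rng: np.random.Generator = dc_field(
        default_factory=np.random.default_rng)


def new_state(params: ModelParams, seed: int) -> SimulationState:
    """Fresh state: circular ``c`` perturbation, ``g = 0``, no agents."""
    params = validate(params)
    shape = params.grid_shape
    c0_field = init_circular_perturbation(shape, params.r, params.c0)
    return SimulationState(
        params=params,
        c=MediatorField(c0_field, params.D_c, params.gamma_c,
                        params.pde_safety),
        g=MediatorField(np.zeros(shape), params.D_g, params.gamma_g,
                        params.pde_safety),
        c_sources=SourceAccumulator(shape),
        g_sources=SourceAccumulator(shape),
        rng=np.random.default_rng(seed),
    )


def step_tick(state: SimulationState) -> SimulationState:
    """Advance the python-backend state by one tick, in place."""
    p = state.params
    rng = state.rng
    state.c.advance_tick(state.c_sources)
    state.g.advance_tick(state.g_sources)

    if state.tick % p.neutrophil_recruit_period == 0:
        n_here = len(state.neutrophils)
        if p.count_apoptotic_in_cap:
            n_here += len(state.apoptotic)
        state.neutrophils.extend(ag.recruit_neutrophils(
            state.c.values, state.g.values, p, n_here, rng))
    if state.tick % p.macrophage_recruit_period == 0:
        state.macrophages.extend(ag.recruit_macrophages(
            state.c.values, p, len(state.macrophages), rng))

    # indexes of apoptotic cells per site, plus the per-site count lattice
    apo_at: dict[tuple[int, int], list] = collections.defaultdict(list)
    apo_count = np.zeros(p.grid_shape, dtype=np.int64)
    for a in state.apoptotic:
        apo_at[(a.y, a.x)].append(a)
        apo_count[a.y, a.x] += 1

    roster: list[tuple[str, object]] = (
        [("m", m) for m in state.macrophages]
        + [("n", n) for n in state.neutrophils]
        + [("a", a) for a in state.apoptotic])
    removed: set[int] = set()
    new_apoptotic: list = []

    for idx in rng.permutation(len(roster)):
        kind, agent = roster[idx]
        if id(agent) in removed:
            continue
        if kind == "m":
            ag.macrophage_move(agent, apo_count, state.c.values, p, rng)
            here = [a for a in apo_at[(agent.y, agent.x)]
                    if id(a) not in removed]
            victim = ag.phagocytose(agent, here, p, rng)
            if victim is not None:
                removed.add(id(victim))
                apo_at[(victim.y, victim.x)].remove(victim)
                apo_count[victim.y, victim.x] -= 1
            ag.release_anti_inflammatory(agent, state.g_sources, p, rng)
            if ag.macrophage_departure(agent, state.c.values, p, rng):
                removed.add(id(agent))
                continue
            agent.lifespan_remaining -= 1
            if agent.lifespan_remaining <= 0:
                removed.add(id(agent))
        elif kind == "n":
            replacement = ag.neutrophil_step(agent, state.c.values,
                                             state.c_sources, p, rng)
            if replacement is not None:
                removed.add(id(agent))
                new_apoptotic.append(replacement)
                apo_at[(replacement.y, replacement.x)].append(replacement)
                apo_count[replacement.y, replacement.x] += 1
        else:
            if ag.apoptotic_step(agent, state.c_sources, p):
                removed.add(id(agent))
                apo_at[(agent.y, agent.x)].remove(agent)
                apo_count[agent.y, agent.x] -= 1

    state.macrophages = [m for m in state.macrophages
                         if id(m) not in removed]
    state.neutrophils = [n for n in state.neutrophils
                         if id(n) not in removed]
    state.apoptotic = ([a for a in state.apoptotic if id(a) not in removed]
                       + [a for a in new_apoptotic if id(a) not in removed])
    state.tick += 1
    return state


def _record_ticks(T: int, stride: int) -> np.ndarray:
    ticks = np.arange(0, T, stride)
    if ticks[-1] != T - 1:
        ticks = np.append(ticks, T - 1)
    return ticks


def _run_python(params: ModelParams, seed: int, T: int, stride: int,
                snapshot_dir=None, snapshot_ticks=()) -> SimulationSummary:
    state = new_state(params, seed)
    rec_ticks = _record_ticks(T, stride)
    rows = {k: [] for k in _SERIES}
    snaps = set(snapshot_ticks)
    for t in range(T):
        step_tick(state)
        if snapshot_dir is not None and t in snaps:
            write_snapshot(snapshot_dir, t, state.c.values, state.g.values)
        if t in rec_ticks:
            rows["n_active"].append(len(state.neutrophils))
            rows["n_apoptotic"].append(len(state.apoptotic))
            rows["n_macrophage"].append(len(state.macrophages))
            rows["n_activated"].append(
                sum(m.activated for m in state.macrophages))
            rows["max_c"].append(state.c.values.max())
            rows["max_g"].append(state.g.values.max())
    return SimulationSummary(ticks=rec_ticks,
                             **{k: np.asarray(v) for k, v in rows.items()})


def _grow(arrays: list[np.ndarray], needed: int) -> list[np.ndarray]:
    cap = len(arrays[0])
    if cap >= needed:
        return arrays
    new_cap = max(needed, 2 * cap)
    out = []
    for a in arrays:
        b = np.zeros(new_cap, dtype=a.dtype)
        b[:cap] = a
        out.append(b)
    return out


def _run_numba(params: ModelParams, seed: int, T: int, stride: int,
               snapshot_dir=None, snapshot_ticks=()) -> SimulationSummary:
    p = params
    H, W = p.grid_shape
    state = new_state(p, seed)  # fields + accumulators; agents live in arrays
    _kernel.seed_rng(seed)

    fpar = np.array([p.p_nr, p.p_nc, p.p_mr, p.p_mg, p.p_ml, p.p_ma,
                     p.delta_ac, p.delta_nc, p.delta_mg])
    ipar = np.array([p.n_max, p.m_max,
                     p.macrophage_recruit_period, p.neutrophil_recruit_period,
                     p.neutrophil_moves_per_tick,
                     *p.macrophage_lifespan, *p.neutrophil_lifespan,
                     *p.apoptotic_lifespan,
                     1 if p.count_apoptotic_in_cap else 0], dtype=np.int64)
    mem_table = _kernel.memory_table(p.sigma_mem, p.wrap_angles)

    mac = [np.zeros(p.m_max, dtype=np.int64) for _ in range(4)]
    mac_act = np.zeros(p.m_max, dtype=np.bool_)
    mac_alive = np.zeros(p.m_max, dtype=np.bool_)
    neu = [np.zeros(p.n_max, dtype=np.int64) for _ in range(4)]
    neu_alive = np.zeros(p.n_max, dtype=np.bool_)
    apo = [np.zeros(p.n_max, dtype=np.int64) for _ in range(3)]
    apo_alive = np.zeros(p.n_max, dtype=np.bool_)
    apo_site = np.zeros((H, W), dtype=np.int64)
    m0 = n0 = a0 = 0

    rec_ticks = _record_ticks(T, stride)
    rec_set = set(int(t) for t in rec_ticks)
    snap_set = set(snapshot_ticks)
    rows = {k: [] for k in _SERIES}

    c, g = state.c.values, state.g.values
    wgrad = np.empty((H, W, 8))
    has_c = np.empty((H, W), dtype=np.bool_)
    dep_elig = np.empty((H, W), dtype=np.bool_)

    for t in range(T):
        # PDE tick: apply queued deposits, then compiled Euler substeps
        for fld, src in ((state.c, state.c_sources),
                         (state.g, state.g_sources)):
            fld.values += src.drain()
            fld.clamp_count += _kernel.pde_tick(
                fld.values, fld.D, fld.gamma, fld.dt, fld.n_substeps)
        if not (np.isfinite(c.sum()) and np.isfinite(g.sum())):
            raise FloatingPointError(
                "non-finite mediator concentration: unstable PDE step")

        _kernel.tick_precompute(c, p.k_grad, p.epsilon_c, p.alpha_ml,
                                wgrad, has_c, dep_elig)
        mac_elig = c > p.alpha_mr
        neu_elig = (c > p.alpha_ncr) & (g < p.alpha_ngr)

        # apoptotic CSR buckets over the compacted prefix [0, a0)
        sites = apo[0][:a0] * W + apo[1][:a0]
        bucket_idx = np.argsort(sites, kind="stable").astype(np.int64)
        counts = np.bincount(sites, minlength=H * W)
        bucket_start = np.zeros(H * W + 1, dtype=np.int64)
        np.cumsum(counts, out=bucket_start[1:])

        needed = a0 + min(n0 + p.n_max, p.n_max) + 1
        if len(apo[0]) < needed:
            grown = _grow(apo + [apo_alive], needed)
            apo, apo_alive = grown[:3], grown[3]

        m0, n0, a_hw = _kernel.tick_kernel(
            t, c, g, state.c_sources.pending, state.g_sources.pending,
            wgrad, has_c, dep_elig, mac_elig, neu_elig, mem_table,
            mac[0], mac[1], mac[2], mac[3], mac_act, mac_alive, m0,
            neu[0], neu[1], neu[2], neu[3], neu_alive, n0,
            apo[0], apo[1], apo[2], apo_alive, a0,
            apo_site, bucket_start, bucket_idx, fpar, ipar)

        # compact each class so alive agents occupy the array prefix
        keep = np.flatnonzero(mac_alive[:m0])
        for a in mac:
            a[:keep.size] = a[keep]
        mac_act[:keep.size] = mac_act[keep]
        n_activated = int(mac_act[:keep.size].sum())
        mac_alive[:] = False
        mac_alive[:keep.size] = True
        m0 = keep.size

        keep = np.flatnonzero(neu_alive[:n0])
        for a in neu:
            a[:keep.size] = a[keep]
        neu_alive[:] = False
        neu_alive[:keep.size] = True
        n0 = keep.size

        keep = np.flatnonzero(apo_alive[:a_hw])
        for a in apo:
            a[:keep.size] = a[keep]
        apo_alive[:] = False
        apo_alive[:keep.size] = True
        a0 = keep.size

        if snapshot_dir is not None and t in snap_set:
            write_snapshot(snapshot_dir, t, c, g)
        if t in rec_set:
            rows["n_active"].append(n0)
            rows["n_apoptotic"].append(a0)
            rows["n_macrophage"].append(m0)
            rows["n_activated"].append(n_activated)
            rows["max_c"].append(c.max())
            rows["max_g"].append(g.max())

    return SimulationSummary(ticks=rec_ticks,
                             **{k: np.asarray(v) for k, v in rows.items()})


def run_simulation(params: ModelParams, seed: int, T: int,
                   backend: str = "numba",
                   record_stride: int | None = None,
                   snapshot_dir: str | None = None,
                   snapshot_ticks: tuple[int, ...] = ()) -> SimulationSummary:
    """Run one simulation of ``T`` ticks and return its summary series.

    If ``snapshot_dir`` is given, both mediator lattices are written there
    (``snap_t{tick}.npz``) at each tick listed in ``snapshot_ticks``.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    params = validate(params)
    stride = record_stride or params.record_stride
    if backend == "numba":
        return _run_numba(params, seed, T, stride, snapshot_dir,
                          snapshot_ticks)
    if backend == "python":
        return _run_python(params, seed, T, stride, snapshot_dir,
                           snapshot_ticks)
    raise ValueError(f"unknown backend {backend!r}")


def classify_outcome(summary: SimulationSummary, params: ModelParams,
                     tol: float | None = None) -> str:
    """``"resolved"`` iff, at the final record, no active or apoptotic
    neutrophils remain and the maximum ``c`` is below the resolution
    tolerance; otherwise ``"chronic"``.  Mediators decay exponentially and
    never reach exact zero in floating point, hence the tolerance, set well
    below every recruitment threshold."""
    tol = params.resolution_tol if tol is None else tol
    f = summary.final()
    resolved = (f["n_active"] + f["n_apoptotic"] == 0) and f["max_c"] < tol
    return "resolved" if resolved else "chronic"


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-run seeds below 2**31, derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, np.uint64) % (2**31 - 1)).astype(np.int64)


def run_batch(params: ModelParams, n_reps: int, master_seed: int, T: int,
              backend: str = "numba",
              record_stride: int | None = None,
              seeds: np.ndarray | None = None) -> BatchSummary:
    """``n_reps`` independent runs with seeds derived from ``master_seed``;
    per-tick mean/sd envelopes plus the resolved/chronic outcome tally."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if seeds is None:
        seeds = derive_seeds(master_seed, n_reps)
    summaries = [run_simulation(params, int(s), T, backend, record_stride)
                 for s in seeds[:n_reps]]
    mean = {}
    sd = {}
    for k in _SERIES:
        stack = np.stack([getattr(s, k) for s in summaries]).astype(float)
        mean[k] = stack.mean(axis=0)
        sd[k] = stack.std(axis=0, ddof=0)
    outcomes = [classify_outcome(s, params) for s in summaries]
    return BatchSummary(ticks=summaries[0].ticks, mean=mean, sd=sd,
                        outcomes=outcomes, summaries=summaries)


#: parameters swept by the one-at-a-time sensitivity scan.  delta_ac is the
#: concentration scale of the model and is excluded; chemotaxis parameters
#: are held at their calibrated values.
SENSITIVITY_PARAMS = (
    "c0", "r", "D_c", "D_g", "gamma_c", "gamma_g", "delta_nc", "delta_mg",
    "p_nr", "p_nc", "p_mr", "p_mg", "p_ml", "p_ma",
    "alpha_ncr", "alpha_ngr", "alpha_mr", "alpha_ml", "n_max", "m_max",
)

_PROBABILITIES = ("p_nr", "p_nc", "p_mr", "p_mg", "p_ml", "p_ma")
_INT_PARAMS = ("n_max", "m_max")


def _perturb(params: ModelParams, name: str, scale: float) -> ModelParams:
    value = getattr(params, name) * scale
    if name in _PROBABILITIES and value > 1.0:
        value = 1.0  # probabilities cannot exceed one: run at certainty
    if name in _INT_PARAMS:
        value = max(1, int(round(value)))
    return params.replace(**{name: value})


def _max_c_at(summary: SimulationSummary, t_eval: int) -> float:
    idx = int(np.searchsorted(summary.ticks, t_eval))
    idx = min(idx, len(summary.ticks) - 1)
    return float(summary.max_c[idx])


def sensitivity_scan(base_params: ModelParams, factor: float = 0.5,
                     t_eval: int = 5000, n_reps: int = 100,
                     master_seed: int = 0,
                     param_names: tuple[str, ...] = SENSITIVITY_PARAMS,
                     backend: str = "numba",
                     record_stride: int | None = None) -> pd.DataFrame:
    """One-at-a-time scan: each parameter up and down by ``factor``,
    reporting the percentage change in the batch-mean maximal ``c`` at
    ``t_eval`` relative to baseline.

    The same per-run seeds are used for the baseline and every perturbed
    batch (common random numbers), so the reported change is not swamped by
    run-to-run noise.  The ``sd`` column is the standard deviation of the
    per-run paired percentage changes.  A baseline mean of zero makes the
    percentage undefined: the row is flagged and carries NaN.
    """
    if not (0.0 < factor < 1.0):
        raise ValueError("factor must lie in (0, 1)")
    T = t_eval + 1
    seeds = derive_seeds(master_seed, n_reps)
    base = run_batch(base_params, n_reps, master_seed, T, backend,
                     record_stride, seeds=seeds)
    base_vals = np.array([_max_c_at(s, t_eval) for s in base.summaries])
    base_mean = base_vals.mean()

    rows = []
    for name in param_names:
        for direction, scale in (("+", 1.0 + factor), ("-", 1.0 - factor)):
            pert = _perturb(base_params, name, scale)
            batch = run_batch(pert, n_reps, master_seed, T, backend,
                              record_stride, seeds=seeds)
            vals = np.array([_max_c_at(s, t_eval) for s in batch.summaries])
            if base_mean == 0:
                rows.append((name, direction, np.nan, np.nan, True))
                continue
            pct = 100.0 * (vals.mean() - base_mean) / base_mean
            with np.errstate(divide="ignore", invalid="ignore"):
                per_run = 100.0 * (vals - base_vals) / base_vals
            per_run = per_run[np.isfinite(per_run)]
            sd = float(per_run.std(ddof=1)) if per_run.size > 1 else np.nan
            rows.append((name, direction, float(pct), sd, False))
    return pd.DataFrame(
        rows, columns=["parameter", "direction", "pct_change", "sd",
                       "undefined"])
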