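"""Model constants, dimensional scalings and parameter validation.

All quantities in the simulator are dimensionless.  The dimensional anchors
are a grid spacing of one macrophage diameter (``L* = 20`` micrometres) and a
tick of one minute (``T* = 1``), so that one move per tick corresponds to a
cell speed of 20 um/min.  Diffusivities and decay rates entering the mediator
PDEs are nondimensionalised against these scales.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ScalingParams",
    "ModelParams",
    "ParameterError",
    "nondimensionalise_diffusivity",
    "nondimensionalise_decay",
    "validate",
    "load_params",
    "save_params",
]

#: conversion factor cm^2/s -> um^2/min
_CM2_S_TO_UM2_MIN = 1e8 * 60.0

#: minutes per day, for decay rates quoted per day
_MIN_PER_DAY = 1440.0


class ParameterError(ValueError):
    """Raised when a parameter set violates one or more invariants.

    The message lists every violated invariant by field name.
    """


@dataclass(frozen=True)
class ScalingParams:
    """Dimensional scales used to nondimensionalise the mediator PDEs.

    Attributes
    ----------
    L_star : float
        Length scale, micrometres per grid space (default one macrophage
        diameter, 20 um).
    T_star : float
        Time scale, minutes per tick.
    D_star : float
        Dimensional mediator diffusivity, cm^2/s.
    gamma_star : float
        Dimensional mediator decay rate, 1/day.
    """

    L_star: float = 20.0
    T_star: float = 1.0
    D_star: float = 1e-7
    gamma_star: float = 3.0

    def __post_init__(self) -> None:
        errors = []
        if not self.L_star > 0:
            errors.append("L_star must be strictly positive")
        if not self.T_star > 0:
            errors.append("T_star must be strictly positive")
        if self.D_star < 0:
            errors.append("D_star must be non-negative")
        if self.gamma_star < 0:
            errors.append("gamma_star must be non-negative")
        if errors:
            raise ParameterError("; ".join(errors))


def nondimensionalise_diffusivity(scaling: ScalingParams) -> float:
    """Dimensionless diffusivity ``D = D* T* / L*^2`` in grid^2/tick.

    ``D*`` is given in cm^2/s, ``T*`` in minutes and ``L*`` in micrometres;
    the unit conversion is handled internally.  The baseline
    ``D* = 1e-7 cm^2/s`` with ``L* = 20 um`` and ``T* = 1 min`` yields 1.5.
    """
    d_um2_min = scaling.D_star * _CM2_S_TO_UM2_MIN
    return d_um2_min * scaling.T_star / scaling.L_star**2


def nondimensionalise_decay(scaling: ScalingParams) -> float:
    """Dimensionless decay rate ``gamma = gamma* T*`` per tick.

    ``gamma*`` is quoted per day; the baseline 3/day with a one-minute tick
    gives 3/1440 ~= 0.00208 (reported as 0.002 to one significant figure).
    The full-precision value is returned; rounding is a display concern.
    """
    return scaling.gamma_star / _MIN_PER_DAY * scaling.T_star


_PROBABILITY_FIELDS = ("p_nr", "p_nc", "p_mr", "p_mg", "p_ml", "p_ma")
_THRESHOLD_FIELDS = ("alpha_ncr", "alpha_ngr", "alpha_mr", "alpha_ml")
# c0 nominally lives on the [0, 1] mediator scale but may exceed 1, e.g.
# when the sensitivity scan inflates the insult severity by 50%
_NONNEG_FIELDS = ("c0", "D_c", "D_g", "gamma_c", "gamma_g",
                  "delta_ac", "delta_nc", "delta_mg", "k_grad", "r")


@dataclass
class ModelParams:
    """Every constant of the inflammation model, with baseline defaults.

    Field names follow the symbols conventional for this model family
    (``c0``, ``r``, ``D_c`` ...).  Mediator concentrations live on the scale
    [0, 1] fixed by ``delta_ac = 1``, the amount of pro-inflammatory mediator
    dumped by a necrosing apoptotic neutrophil; ``delta_ac`` is therefore the
    concentration scale of the model and is excluded from sensitivity scans.
    """

    # initial condition: circular pro-inflammatory perturbation
    c0: float = 1.0          # severity of the perturbation, in [0, 1]
    r: float = 10.0          # radius of the perturbed disc, grid spaces

    # mediator PDE parameters (dimensionless, grid^2/tick and 1/tick)
    D_c: float = 1.5
    D_g: float = 1.5
    gamma_c: float = 3.0 / 1440.0   # full precision; prints as 0.002
    gamma_g: float = 3.0 / 1440.0

    # source increments per release event
    delta_ac: float = 1.0    # c dumped on necrosis (concentration scale)
    delta_nc: float = 0.001  # c released by an active neutrophil
    delta_mg: float = 0.001  # g released by an activated macrophage

    # per-event probabilities
    p_nr: float = 0.02       # neutrophil recruitment
    p_nc: float = 0.5        # neutrophil releases c
    p_mr: float = 0.04       # macrophage recruitment
    p_mg: float = 0.8        # activated macrophage releases g
    p_ml: float = 0.8        # macrophage leaves resolved tissue
    p_ma: float = 1.0        # phagocytosis of a co-located apoptotic cell

    # concentration thresholds, on the [0, 1] mediator scale
    alpha_ncr: float = 0.05   # min c for neutrophil recruitment
    alpha_ngr: float = 0.015  # max g for neutrophil recruitment
    alpha_mr: float = 0.4     # min c for macrophage recruitment
    alpha_ml: float = 0.02    # min neighbourhood c for macrophages to remain

    # chemotaxis (biased persistent random walk); healthy defaults
    k_grad: float = 80.0      # gradient sensitivity, per unit concentration
    sigma_mem: float = 1.0    # persistence standard deviation, radians

    # global agent caps
    n_max: int = 4000         # active neutrophils
    m_max: int = 1000         # macrophages

    # domain and scheduling
    grid_shape: tuple[int, int] = (100, 100)
    macrophage_recruit_period: int = 5   # ticks between recruitment sweeps
    neutrophil_recruit_period: int = 2
    neutrophil_moves_per_tick: int = 2   # 40 um/min vs 20 um/min macrophages

    # lifespan ranges, ticks, drawn uniformly (inclusive)
    macrophage_lifespan: tuple[int, int] = (1440, 86400)   # 1-60 days
    neutrophil_lifespan: tuple[int, int] = (60, 1440)      # 1-24 hours
    apoptotic_lifespan: tuple[int, int] = (60, 720)        # 1-12 hours

    # numerical and bookkeeping knobs
    pde_safety: float = 0.5          # explicit-Euler stability safety factor
    epsilon_c: float = 1e-6          # "no mediator in neighbourhood" cutoff
    resolution_tol: float = 1e-3     # max c below which tissue counts healthy
    record_stride: int = 10          # ticks between recorded summary rows
    count_apoptotic_in_cap: bool = False  # apoptotic cells vs n_max
    wrap_angles: bool = True         # circular angular distance in persistence

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "macrophage_lifespan",
                    "neutrophil_lifespan", "apoptotic_lifespan"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter name(s): {', '.join(sorted(unknown))}")
        kwargs = dict(d)
        for key in ("grid_shape", "macrophage_lifespan",
                    "neutrophil_lifespan", "apoptotic_lifespan"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return validate(cls(**kwargs))


def validate(params: ModelParams) -> ModelParams:
    """Check every invariant; return the params or raise :class:`ParameterError`.

    All violations are collected and reported together, named by field.
    """
    errors: list[str] = []
    for name in _PROBABILITY_FIELDS:
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            errors.append(f"{name}={v} outside [0, 1]")
    for name in _THRESHOLD_FIELDS:
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            errors.append(f"{name}={v} outside [0, 1]")
    for name in _NONNEG_FIELDS:
        v = getattr(params, name)
        if v < 0:
            errors.append(f"{name}={v} must be non-negative")
    for name in ("n_max", "m_max"):
        v = getattr(params, name)
        if not (isinstance(v, (int,)) and v >= 1):
            errors.append(f"{name}={v} must be a positive integer")
    for name in ("macrophage_recruit_period", "neutrophil_recruit_period",
                 "neutrophil_moves_per_tick", "record_stride"):
        v = getattr(params, name)
        if not (isinstance(v, int) and v >= 1):
            errors.append(f"{name}={v} must be a positive integer")
    for name in ("macrophage_lifespan", "neutrophil_lifespan",
                 "apoptotic_lifespan"):
        lo, hi = getattr(params, name)
        if not (0 < lo <= hi):
            errors.append(f"{name}=({lo}, {hi}) bounds must satisfy 0 < lo <= hi")
    if len(params.grid_shape) != 2 or any(s < 3 for s in params.grid_shape):
        errors.append(f"grid_shape={params.grid_shape} must be 2-D, >= 3 per side")
    if not params.sigma_mem > 0:
        errors.append(f"sigma_mem={params.sigma_mem} must be strictly positive")
    if not (0.0 < params.pde_safety <= 1.0):
        errors.append(f"pde_safety={params.pde_safety} outside (0, 1]")
    if errors:
        raise ParameterError("; ".join(errors))
    return params


def load_params(path: str, overrides: dict[str, Any] | None = None) -> ModelParams:
    """Load a flat key-value YAML/JSON parameter file, apply overrides, validate."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if overrides:
        d.update(overrides)
    return ModelParams.from_dict(d)


def save_params(params: ModelParams, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
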