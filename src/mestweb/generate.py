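"""Synthetic community generator for ensemble experiments.

Reproduces the statistical design of the persistence-versus-connectance
ensembles: per-replicate exploiter growth rates drawn uniformly from
[0.3, 0.4] (mortalities 0.05 and consumption rates 0.15 fixed), a shared
symmetric interspecific competition coefficient beta, a random initial
predator diet wired at a prescribed initial connectance, and random
positive initial biomasses with the initial effort budget split equally
over the wired links.

Randomness is organised as a two-level seed hierarchy built on
``numpy.random.SeedSequence``: a base seed spawns one stream per
(parameter draw, initial-condition draw) replicate, so any replicate can
be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CommunityState, EXPLOITER_DEFAULTS, ModelParams

__all__ = [
    "EnsembleSpec",
    "Wiring",
    "draw_params",
    "wire_initial_foraging",
    "draw_initial_state",
    "replicate_rng",
]

#: Range of the per-exploiter growth rates in the ensemble design.
RI_RANGE = (0.3, 0.4)
#: Default range of random initial biomasses (not printed anywhere in the
#: study design; documented package choice, configurable per spec).
BIOMASS_RANGE = (0.1, 1.0)


@dataclass
class EnsembleSpec:
    """Design of one persistence-versus-connectance experiment.

    ``N`` is the community size (``n = N - 3`` exploiters plus mutualist,
    specialist predator and top predator); ``n_param_draws`` x
    ``n_init_draws`` replicates are run per connectance value.
    """

    N: int
    beta: float
    g: float
    connectance_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    n_param_draws: int = 5
    n_init_draws: int = 5
    base_seed: int = 0
    T_total: float = 20000.0
    T_check: float = 2000.0
    extinction_threshold: float = 1e-12

    def __post_init__(self):
        if self.N < 4:
            raise ValueError("community needs at least 4 species (N >= 4)")
        if any(not (0 < c <= 1) for c in self.connectance_grid):
            raise ValueError("connectance values must lie in (0, 1]")
        if self.n_param_draws < 1 or self.n_init_draws < 1:
            raise ValueError("replicate counts must be >= 1")

    @property
    def n(self) -> int:
        return self.N - 3


@dataclass
class Wiring:
    """An initial diet of the top predator: which of the ``n+2`` potential
    prey (F0, F1..Fn, C) are linked, and the equal-split effort vector."""

    active: np.ndarray          # bool over (F0, F1..Fn, C)
    theta: np.ndarray           # efforts on F0..Fn (thetaC is the remainder)

    @property
    def n_links(self) -> int:
        return int(self.active.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / self.active.size


def replicate_rng(base_seed: int, *indices: int) -> np.random.Generator:
    """Independent generator for one replicate of one experiment stage."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=indices))


def draw_params(spec: EnsembleSpec, rng: np.random.Generator) -> ModelParams:
    """One random parameter set of the ensemble design.

    ``ri ~ U[0.3, 0.4]`` i.i.d.; ``di = 0.05``, ``ui = 0.15``; the
    competition matrix is filled symmetrically with ``spec.beta``; every
    other rate keeps its baseline value.
    """
    n = spec.n
    if n < 1:
        raise ValueError("model requires at least one exploiter (N >= 4)")
    ri = rng.uniform(*RI_RANGE, size=n)
    return ModelParams(n=n, ri=ri,
                       ui=np.full(n, EXPLOITER_DEFAULTS["ui"]),
                       di=np.full(n, EXPLOITER_DEFAULTS["di"]),
                       beta=spec.beta, g=spec.g)


def wire_initial_foraging(n_prey: int, connectance: float,
                          rng: np.random.Generator) -> Wiring:
    """Random initial diet at a prescribed connectance.

    ``L = round(connectance * n_prey)`` links (at least one) are chosen
    uniformly without replacement among the ``n_prey = n + 2`` potential
    prey; each wired link receives effort ``1/L``.  If C is wired its
    share arrives through the simplex remainder ``thetaC = 1/L``.
    """
    if not (0 < connectance <= 1):
        raise ValueError("connectance must lie in (0, 1]")
    if n_prey < 2:
        raise ValueError("need at least two potential prey (F0 and C)")
    L = max(1, int(round(connectance * n_prey)))
    chosen = rng.choice(n_prey, size=L, replace=False)
    active = np.zeros(n_prey, dtype=bool)
    active[chosen] = True
    theta = np.zeros(n_prey - 1)
    theta[active[:-1]] = 1.0 / L
    return Wiring(active=active, theta=theta)


def draw_initial_state(params: ModelParams, wiring: Wiring,
                       rng: np.random.Generator,
                       biomass_range: tuple[float, float] = BIOMASS_RANGE
                       ) -> CommunityState:
    """Random positive initial biomasses with the wired effort vector."""
    n = params.n
    if wiring.theta.shape[0] != n + 1:
        raise ValueError("wiring does not match params.n")
    lo, hi = biomass_range
    b = rng.uniform(lo, hi, size=n + 3)
    return CommunityState(F0=float(b[0]), F=b[1:1 + n], C=float(b[n + 1]),
                          P=float(b[n + 2]), theta=wiring.theta.copy())
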