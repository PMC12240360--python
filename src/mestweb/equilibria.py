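"""Coexistence equilibria, Jacobian stability and (u1, beta) stability maps.

A *network structure* fixes which of the top predator's foraging links
``{F0, F1..Fn, C}`` are active.  Each structure corresponds to a boundary
face of the foraging-effort simplex, and its coexistence equilibrium is a
boundary equilibrium of the adaptive model:

* single active link — the whole effort budget sits on that prey;
* two or more active links — interior efforts are pinned by the replicator
  fixed-point condition, equality of the per-effort fitness returns
  ``w_j = eP u_j F_j`` (``w_C = eP uC C``) across active prey, together
  with the unit-sum constraint.

The algebraic system (per-capita growth brackets of every coexisting
species = 0, plus the effort conditions) is solved by a seeded multi-start
root search.  Local stability is judged by the maximal real part of the
Jacobian eigenvalues, ``Re(lambda_max)``, in one of two scopes:

``full`` (default)
    Jacobian of the complete adaptive system, biomasses plus the
    independent effort coordinates ``theta0..thetan``.  At a boundary
    structure this automatically carries the diet-expansion invasion
    rates ``g (w_k - wbar)`` of every inactive link — the directions
    through which adaptive foraging destabilises a structure.
``ecological``
    Biomass block only, efforts frozen at their equilibrium values (the
    fixed-preference community matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.stats import qmc

from .model import ModelParams, rhs_jacobian, rhs_vector

__all__ = [
    "StructureMask",
    "EquilibriumResult",
    "find_equilibrium",
    "jacobian",
    "stability_map",
    "count_boundary_structures",
]

#: Fig-3-style named structures of the four-species community (n = 1).
#: Keys are the prey of P that remain active.
NAMED_STRUCTURES = {
    "A": (True, True, False),    # thetaC = 0: P eats F0 and F1
    "B": (True, True, True),     # full diet
    "C": (False, True, False),   # theta0 = thetaC = 0: P eats only F1
    "D": (False, True, True),    # theta0 = 0: P eats F1 and C
}


@dataclass(frozen=True)
class StructureMask:
    """Active/inactive flags over P's prey links ``(F0, F1..Fn, C)``."""

    active: tuple[bool, ...]

    def __post_init__(self):
        if len(self.active) < 2:
            raise ValueError("mask needs at least F0 and C slots")
        if not any(self.active):
            raise ValueError("structure must keep at least one active link")

    @classmethod
    def from_label(cls, label: str) -> "StructureMask":
        """Named four-species structures A-D (see module docstring)."""
        try:
            return cls(NAMED_STRUCTURES[label.upper()])
        except KeyError:
            raise ValueError(
                f"unknown structure {label!r}; choose from {sorted(NAMED_STRUCTURES)}"
            )

    @classmethod
    def from_active_prey(cls, n: int, prey: Sequence[int | str]) -> "StructureMask":
        """Build a mask for ``n`` exploiters from active prey identifiers:
        integers 0..n for ``F0..Fn`` or the string ``"C"``."""
        flags = [False] * (n + 2)
        for p in prey:
            flags[n + 1 if p == "C" else int(p)] = True
        return cls(tuple(flags))

    @property
    def n(self) -> int:
        return len(self.active) - 2

    @property
    def n_active(self) -> int:
        return sum(self.active)

    @property
    def includes_C(self) -> bool:
        return self.active[-1]

    def theta_from_active(self, efforts: np.ndarray) -> np.ndarray:
        """Scatter efforts over active links into a theta vector of length
        n+1 (``thetaC`` implied by the remainder)."""
        theta = np.zeros(self.n + 1)
        idx = [i for i, a in enumerate(self.active[:-1]) if a]
        theta[idx] = efforts[: len(idx)]
        return theta


@dataclass
class EquilibriumResult:
    """A solved (or failed) coexistence equilibrium of one structure."""

    biomass: np.ndarray | None
    theta: np.ndarray | None
    residual: float
    feasible: bool
    re_lambda_max: float = np.nan
    eigenvalues: np.ndarray | None = None
    message: str = ""
    present: np.ndarray | None = None

    def state_vector(self) -> np.ndarray:
        if self.biomass is None:
            raise ValueError("no solution stored")
        return np.concatenate([self.biomass, self.theta])


def count_boundary_structures(m: int) -> int:
    """Number of boundary network structures (proper, non-empty subsets of
    ``m`` selectable foraging links): ``2**m - 2``.

    With a specialist predator plus 32 exploiters (m = 33) this is the
    8 589 934 590 boundary equilibria that make exhaustive structure
    enumeration hopeless for large communities.
    """
    if m <= 0:
        raise ValueError("need at least one selectable link")
    return 2 ** m - 2


def find_equilibrium(params: ModelParams, mask: StructureMask,
                     guess: np.ndarray | None = None, *,
                     present: Sequence[bool] | None = None,
                     n_starts: int = 16, seed: int = 0,
                     residual_tol: float = 1e-10,
                     positive_tol: float = 1e-8) -> EquilibriumResult:
    """Solve the coexistence equilibrium of one network structure.

    ``present`` restricts the community to a species subset (boolean over
    ``F0, F1..Fn, C, P``; default all present); absent species are pinned
    at zero biomass and drop out of the algebraic system.

    Multi-start root search: an optional caller guess (biomasses of
    present species, then free efforts) followed by seeded Latin-hypercube
    starts over biomasses in (0, 5] with efforts starting uniform over
    active links.  The first root that is feasible — residual below
    ``residual_tol``, all present biomasses strictly positive, efforts in
    [0, 1] — is returned; if no start converges the structure is reported
    infeasible for these parameters.
    """
    p = params
    n = p.n
    if mask.n != n:
        raise ValueError("mask size does not match params.n")
    pres = np.ones(n + 3, dtype=bool) if present is None else np.asarray(
        present, dtype=bool)
    if pres.shape != (n + 3,):
        raise ValueError(f"present must have length {n + 3}")
    resid, n_free, theta_of, biomass_of, act = _build(p, mask, pres)

    starts: list[np.ndarray] = []
    if guess is not None:
        starts.append(np.asarray(guess, dtype=float))
    sampler = qmc.LatinHypercube(d=int(pres.sum()), seed=seed)
    lhs = qmc.scale(sampler.random(n_starts), 1e-3, 5.0)
    n_eff = n_free - int(pres.sum())
    eff0 = np.full(n_eff, 1.0 / mask.n_active) if n_eff else np.empty(0)
    for row in lhs:
        starts.append(np.concatenate([row, eff0]))

    best_fail = EquilibriumResult(None, None, np.inf, False,
                                  message="no root from any start",
                                  present=pres)
    for z0 in starts:
        if z0.size != n_free:
            raise ValueError(f"guess must have length {n_free}")
        sol = root(resid, z0, method="hybr")
        if not sol.success:
            continue
        z = sol.x
        r = float(np.max(np.abs(resid(z))))
        if r > residual_tol:
            continue
        biomass = biomass_of(z)
        theta = theta_of(z)
        thC = 1.0 - theta.sum()
        ok = (np.all(biomass[pres] > positive_tol)
              and np.all(theta >= -1e-12) and theta.sum() <= 1 + 1e-12
              and (not act[-1] or thC > positive_tol)
              and (act[-1] or abs(thC) < 1e-9))
        if not ok:
            best_fail = EquilibriumResult(
                biomass, theta, r, False,
                message="converged to non-feasible root", present=pres)
            continue
        return EquilibriumResult(np.clip(biomass, 0, None), theta, r, True,
                                 present=pres)
    return best_fail


def _build(p, mask, pres):
    """Assemble the square algebraic system for one structure.

    Unknowns are the biomasses of present species followed by the free
    active efforts.  When C is an active link its effort is the simplex
    remainder (never an unknown); when C is inactive the last active
    effort is eliminated through the unit sum.
    """
    n = p.n
    nb = n + 3
    act = mask.active
    act_species = [i for i, a in enumerate(act[:-1]) if a]
    free_theta = mask.n_active >= 2
    n_eff = 0
    if free_theta:
        n_eff = len(act_species) - (0 if act[-1] else 1)
    idx_present = np.nonzero(pres)[0]
    n_pres = idx_present.size
    n_free = n_pres + n_eff

    def biomass_of(z):
        b = np.zeros(nb)
        b[idx_present] = z[:n_pres]
        return b

    def theta_of(z):
        th = np.zeros(n + 1)
        if not free_theta:
            if act_species:
                th[act_species[0]] = 1.0
            return th
        if act[-1]:
            th[act_species] = z[n_pres:n_pres + len(act_species)]
        else:
            eff = z[n_pres:n_pres + len(act_species) - 1]
            th[act_species[:-1]] = eff
            th[act_species[-1]] = 1.0 - eff.sum()
        return th

    def resid(z):
        b = biomass_of(z)
        th = theta_of(z)
        x = np.concatenate([b, th])
        dx = rhs_vector(x, p)
        out = np.empty(n_free)
        for k, i in enumerate(idx_present):
            out[k] = dx[i] / b[i] if b[i] != 0 else dx[i]
        if free_theta:
            F0, F, C = b[0], b[1:1 + n], b[n + 1]
            w = p.eP * np.concatenate(([p.u0 * F0], p.ui * F, [p.uC * C]))
            w_act = [w[i] for i in act_species]
            if act[-1]:
                w_act.append(w[-1])
            out[n_pres:] = [w_act[k + 1] - w_act[0]
                            for k in range(len(w_act) - 1)]
        return out

    return resid, n_free, theta_of, biomass_of, act


# keep the internal builder used by find_equilibrium consistent


def jacobian(params: ModelParams, equilibrium: EquilibriumResult | np.ndarray,
             scope: str = "full") -> np.ndarray:
    """Jacobian at an equilibrium, in the requested scope.

    ``full`` returns the (2n+4)-dimensional Jacobian of the adaptive
    system; ``ecological`` the (n+3)-dimensional biomass block with
    efforts frozen.  Entries are analytic (see
    :func:`mestweb.model.rhs_jacobian`) and are validated against central
    finite differences in the test suite.
    """
    if isinstance(equilibrium, EquilibriumResult):
        x = equilibrium.state_vector()
        pres = (equilibrium.present if equilibrium.present is not None
                else np.ones(params.n + 3, dtype=bool))
    else:
        x = np.asarray(equilibrium)
        pres = np.ones(params.n + 3, dtype=bool)
    J = rhs_jacobian(x, params)
    nb = params.n + 3
    if scope == "ecological":
        idx = np.nonzero(pres)[0]
    elif scope == "full":
        idx = np.concatenate([np.nonzero(pres)[0], np.arange(nb, J.shape[0])])
    else:
        raise ValueError("scope must be 'ecological' or 'full'")
    return J[np.ix_(idx, idx)]


def evaluate_stability(params: ModelParams, eq: EquilibriumResult,
                       scope: str = "full") -> EquilibriumResult:
    """Attach eigenvalues and Re(lambda_max) to a feasible equilibrium."""
    if not eq.feasible:
        return eq
    J = jacobian(params, eq, scope)
    lam = np.linalg.eigvals(J)
    eq.eigenvalues = lam
    eq.re_lambda_max = float(lam.real.max())
    return eq


def stability_map(params_base: ModelParams, mask: StructureMask,
                  u1_grid: Sequence[float], beta_grid: Sequence[float], *,
                  scope: str = "full", seed: int = 0,
                  n_starts: int = 16) -> pd.DataFrame:
    """Re(lambda_max) of one structure over a (u1, beta) grid.

    ``beta`` is applied symmetrically (``beta_10 = beta_01 = beta``) over
    the whole competition matrix; ``u1`` replaces the first exploiter's
    consumption rate.  Cells where no feasible coexistence root exists
    are marked infeasible (the white regions of a stability map).
    Deterministic given ``seed``: every cell is solved cold with the same
    multi-start protocol, so the map is independent of traversal order.
    """
    rows = []
    for u1 in u1_grid:
        for beta in beta_grid:
            ui = params_base.ui.copy()
            ui[0] = u1
            p = params_base.replace(ui=ui, beta=float(beta))
            eq = find_equilibrium(p, mask, seed=seed,
                                  n_starts=n_starts)
            if eq.feasible:
                eq = evaluate_stability(p, eq, scope)
            rows.append({"u1": float(u1), "beta": float(beta),
                         "feasible": bool(eq.feasible),
                         "re_lambda_max": eq.re_lambda_max,
                         "residual": eq.residual})
    return pd.DataFrame(rows)
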