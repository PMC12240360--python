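"""Core state, parameters and vector field of the adaptive-foraging MEST model.

The MEST community couples four guilds across three trophic levels: a
mutualist ``F0`` (e.g. a pollinating fig wasp, standing in for the
fig-pollinator mutualism), ``n`` exploiters ``F1..Fn`` (non-pollinating
wasps that parasitise the mutualism), a specialist predator ``C``
(parasitoid wasp feeding only on the mutualist) and an omnivorous top
predator ``P`` (predatory ant).  All functional responses are linear
(Holling type I) and every rate is dimensionless.

Biomass dynamics
----------------
::

    dF0/dt = F0 ( r0 - alpha0 F0 - sum_i beta[i,0] Fi - aC C - theta0 u0 P - d0 )
    dFi/dt = ri Fi (1 - Fi / (F0/q)) - sum_{j!=i} beta[j,i] Fj Fi
             - thetai ui Fi P - di Fi
    dC/dt  = C ( eC aC F0 - thetaC uC P - dC - alphaC C )
    dP/dt  = P W_P,   W_P = eP sum_k thetak uk Fk + eP thetaC uC C
                            - dP - alphaP P

``F0/q`` acts as the carrying capacity of every exploiter: the exploiters
free-ride on the resource flow generated by the mutualism, so their
capacity collapses when the mutualist collapses, and the scale coefficient
``q`` sets how strongly the community depends on the mutualism.  As
``q -> 0`` the capacity diverges and the exploiter growth term reduces to
``ri Fi``, independent of the mutualist — the food-web model without
mutualistic interactions.

Foraging-preference dynamics
----------------------------
The top predator divides a unit foraging budget over its prey
``{F0, F1..Fn, C}``.  The stored coordinates are ``theta0..thetan``; the
effort on ``C`` is always the simplex remainder ``thetaC = 1 - sum theta``.
Preferences evolve by the replicator equation driven by the per-effort
fitness returns ``w_j = eP u_j F_j`` (and ``w_C = eP uC C``)::

    dthetaj/dt = g thetaj ( w_j - wbar ),    wbar = sum_k theta_k w_k

where the mean ``wbar`` runs over *all* prey including ``C``.  Under this
full-simplex reading the total effort ``sum theta + thetaC`` is exactly
conserved, and setting the adaptation intensity ``g = 0`` freezes the diet
(the fixed-preference model).

State packing
-------------
Vectorised routines operate on the flat layout
``x = [F0, F1..Fn, C, P, theta0..thetan]`` of length ``2 n + 4``;
``thetaC`` is derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EPS_CAP",
    "TABLE_DEFAULTS",
    "ModelParams",
    "CommunityState",
    "Derivative",
    "four_species_params",
    "rhs",
    "rhs_vector",
    "rhs_jacobian",
    "predator_fitness",
    "fitness_gradients",
]

#: Lower clamp applied to F0 inside the capacity term F0/q only.  Keeps the
#: field finite when the mutualist goes extinct while preserving the
#: biological consequence: exploiter capacity collapses to ~0 with F0.
EPS_CAP = 1e-12

#: Baseline rate constants of the four-species community (dimensionless).
TABLE_DEFAULTS: dict[str, float] = {
    "r0": 0.5,       # mutualist growth rate
    "alpha0": 0.13,  # mutualist density dependence
    "aC": 0.2,       # consumption rate of C on F0
    "u0": 0.11,      # consumption rate of P on F0
    "d0": 0.05,      # mutualist mortality
    "q": 0.25,       # mutualism scale coefficient
    "eC": 1.0,       # conversion efficiency of C
    "uC": 0.2,       # consumption rate of P on C
    "dC": 0.05,      # mortality of C
    "alphaC": 0.12,  # density dependence of C
    "eP": 1.0,       # conversion efficiency of P
    "dP": 0.05,      # mortality of P
    "alphaP": 0.1,   # density dependence of P
}

#: Per-exploiter defaults used throughout the ensemble experiments.
EXPLOITER_DEFAULTS = {"di": 0.05, "ui": 0.15}


def _as_beta_matrix(beta, n: int) -> np.ndarray:
    """Expand a scalar competition coefficient to the (n+1)x(n+1) matrix
    over {F0, F1..Fn}; entry [j, i] is the effect of j on i, diagonal zero."""
    if np.isscalar(beta):
        mat = np.full((n + 1, n + 1), float(beta))
        np.fill_diagonal(mat, 0.0)
        return mat
    mat = np.array(beta, dtype=float)
    if mat.shape != (n + 1, n + 1):
        raise ValueError(
            f"beta matrix must have shape {(n + 1, n + 1)}, got {mat.shape}"
        )
    return mat


@dataclass
class ModelParams:
    """All rate constants of the MEST model plus the adaptation intensity.

    Vector fields (``ri``, ``ui``, ``di``) have one entry per exploiter;
    ``beta`` is the interspecific competition matrix over ``{F0, F1..Fn}``
    with ``beta[j, i]`` the per-capita effect of species ``j`` on ``i``
    (diagonal unused and kept at zero).
    """

    n: int
    r0: float = TABLE_DEFAULTS["r0"]
    alpha0: float = TABLE_DEFAULTS["alpha0"]
    alphaC: float = TABLE_DEFAULTS["alphaC"]
    alphaP: float = TABLE_DEFAULTS["alphaP"]
    aC: float = TABLE_DEFAULTS["aC"]
    u0: float = TABLE_DEFAULTS["u0"]
    uC: float = TABLE_DEFAULTS["uC"]
    q: float = TABLE_DEFAULTS["q"]
    eC: float = TABLE_DEFAULTS["eC"]
    eP: float = TABLE_DEFAULTS["eP"]
    d0: float = TABLE_DEFAULTS["d0"]
    dC: float = TABLE_DEFAULTS["dC"]
    dP: float = TABLE_DEFAULTS["dP"]
    g: float = 0.28
    ri: np.ndarray = None
    ui: np.ndarray = None
    di: np.ndarray = None
    beta: np.ndarray = None

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("exploiter count n must be >= 0")
        if self.ri is None:
            self.ri = np.full(self.n, 0.35)
        if self.ui is None:
            self.ui = np.full(self.n, EXPLOITER_DEFAULTS["ui"])
        if self.di is None:
            self.di = np.full(self.n, EXPLOITER_DEFAULTS["di"])
        if self.beta is None:
            self.beta = _as_beta_matrix(0.0, self.n)
        self.ri = np.atleast_1d(np.asarray(self.ri, dtype=float))
        self.ui = np.atleast_1d(np.asarray(self.ui, dtype=float))
        self.di = np.atleast_1d(np.asarray(self.di, dtype=float))
        self.beta = _as_beta_matrix(self.beta, self.n)
        for name in ("ri", "ui", "di"):
            v = getattr(self, name)
            if v.shape != (self.n,):
                raise ValueError(f"{name} must have length n={self.n}, got {v.shape}")
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        scalars = [self.r0, self.alpha0, self.alphaC, self.alphaP, self.aC,
                   self.u0, self.uC, self.q, self.d0, self.dC, self.dP, self.g]
        if any(s < 0 for s in scalars):
            raise ValueError("all rate parameters must be nonnegative")
        if np.any(self.ri < 0) or np.any(self.ui < 0) or np.any(self.di < 0):
            raise ValueError("per-exploiter rates must be nonnegative")
        if np.any(self.beta < 0):
            raise ValueError("competition coefficients must be nonnegative")
        if not (0 < self.eC <= 1) or not (0 < self.eP <= 1):
            raise ValueError("conversion efficiencies must lie in (0, 1]")

    # -- layout helpers ----------------------------------------------------
    @property
    def dim(self) -> int:
        """Length of the packed state vector: n+3 biomasses + n+1 efforts."""
        return 2 * self.n + 4

    @property
    def n_species(self) -> int:
        return self.n + 3

    def variable_names(self) -> list[str]:
        names = ["F0"] + [f"F{i}" for i in range(1, self.n + 1)] + ["C", "P"]
        names += [f"theta{j}" for j in range(self.n + 1)]
        return names

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def four_species_params(r1: float = 0.35, u1: float = 0.15,
                        beta: float = 0.18, g: float = 0.28,
                        d1: float = 0.05, **overrides) -> ModelParams:
    """The four-species MEST configuration (one exploiter).

    Defaults are the chaos/bifurcation study setting: ``r1 = 0.35``,
    ``u1 = 0.15``, symmetric competition ``beta10 = beta01 = beta = 0.18``
    and intermediate adaptation ``g = 0.28``.
    """
    return ModelParams(n=1, ri=[r1], ui=[u1], di=[d1],
                       beta=beta, g=g, **overrides)


@dataclass
class CommunityState:
    """Biomasses and foraging efforts of a MEST community.

    ``theta`` holds the efforts of P on ``F0..Fn``; the effort on ``C`` is
    the simplex remainder and is exposed as :attr:`thetaC`.
    """

    F0: float
    F: np.ndarray
    C: float
    P: float
    theta: np.ndarray

    def __post_init__(self):
        self.F = np.atleast_1d(np.asarray(self.F, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.theta.shape[0] != self.F.shape[0] + 1:
            raise ValueError("theta must have length n+1 (efforts on F0..Fn)")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def thetaC(self) -> float:
        return 1.0 - float(np.sum(self.theta))

    def validate(self, tol: float = 1e-9) -> None:
        if self.F0 < 0 or self.C < 0 or self.P < 0 or np.any(self.F < 0):
            raise ValueError("biomasses must be nonnegative")
        if np.any(self.theta < 0):
            raise ValueError("foraging efforts must be nonnegative")
        if np.sum(self.theta) > 1 + tol:
            raise ValueError("foraging efforts must sum to at most 1")

    # -- packing -----------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.F0], self.F, [self.C, self.P], self.theta))

    @classmethod
    def from_vector(cls, x: np.ndarray, n: int) -> "CommunityState":
        x = np.asarray(x, dtype=float)
        if x.shape[0] != 2 * n + 4:
            raise ValueError(f"state vector must have length {2 * n + 4}")
        return cls(F0=float(x[0]), F=x[1:1 + n].copy(), C=float(x[n + 1]),
                   P=float(x[n + 2]), theta=x[n + 3:].copy())


class Derivative(CommunityState):
    """Time derivative of a :class:`CommunityState` (same layout; the
    ``theta`` block is d(theta)/dt, so simplex bounds do not apply)."""

    def __post_init__(self):
        CommunityState.__post_init__(self)

    def validate(self, tol: float = 1e-9) -> None:  # derivatives are signed
        if not np.all(np.isfinite(self.to_vector())):
            raise ValueError("derivative contains non-finite entries")


# ---------------------------------------------------------------------------
# vector field


def rhs_vector(x: np.ndarray, p: ModelParams) -> np.ndarray:
    """Packed-vector form of the MEST vector field.

    No contract checking; this is the hot path shared by the integrators,
    the equilibrium solver and the variational (Lyapunov) system.
    """
    n = p.n
    F0 = x[0]
    F = x[1:1 + n]
    C = x[n + 1]
    P = x[n + 2]
    th = x[n + 3:]
    th0 = th[0]
    thi = th[1:]
    s = th.sum()
    thC = 1.0 - s

    Fall = x[:n + 1]                       # (F0, F1..Fn)

    b0 = (p.r0 - p.alpha0 * F0 - p.beta[1:, 0] @ F - p.aC * C
          - th0 * p.u0 * P - p.d0)
    dF0 = F0 * b0

    comp = p.beta[:, 1:].T @ Fall          # competition felt by each exploiter
    if p.q > 0:
        cap = max(F0, EPS_CAP) / p.q
        self_lim = F / cap
    else:                                  # q -> 0: capacity diverges
        self_lim = 0.0
    bi = p.ri * (1.0 - self_lim) - comp - thi * p.ui * P - p.di
    dF = F * bi

    dC = C * (p.eC * p.aC * F0 - thC * p.uC * P - p.dC - p.alphaC * C)

    WP = (p.eP * (th0 * p.u0 * F0 + thi @ (p.ui * F))
          + p.eP * thC * p.uC * C - p.dP - p.alphaP * P)
    dP = P * WP

    w = p.eP * np.concatenate(([p.u0 * F0], p.ui * F))
    wC = p.eP * p.uC * C
    wbar = th @ w + thC * wC
    dth = p.g * th * (w - wbar)

    out = np.empty_like(x)
    out[0] = dF0
    out[1:1 + n] = dF
    out[n + 1] = dC
    out[n + 2] = dP
    out[n + 3:] = dth
    return out


def rhs(state: CommunityState, params: ModelParams) -> Derivative:
    """Evaluate the full vector field at a validated community state."""
    if state.n != params.n:
        raise ValueError(
            f"state has {state.n} exploiters but params expect {params.n}"
        )
    state.validate()
    dx = rhs_vector(state.to_vector(), params)
    if not np.all(np.isfinite(dx)):
        raise FloatingPointError("vector field returned non-finite entries")
    n = params.n
    return Derivative(F0=float(dx[0]), F=dx[1:1 + n].copy(),
                      C=float(dx[n + 1]), P=float(dx[n + 2]),
                      theta=dx[n + 3:].copy())


def predator_fitness(state: CommunityState, params: ModelParams) -> float:
    """Per-capita growth rate W_P of the top predator.

    ``W_P = eP sum_k theta_k u_k F_k + eP thetaC uC C - dP - alphaP P``;
    the identity ``dP/dt = P * W_P`` holds exactly.
    """
    th = state.theta
    thC = 1.0 - th.sum()
    gain = params.eP * (th[0] * params.u0 * state.F0
                        + th[1:] @ (params.ui * state.F))
    gain += params.eP * thC * params.uC * state.C
    return float(gain - params.dP - params.alphaP * state.P)


def fitness_gradients(state: CommunityState, params: ModelParams) -> np.ndarray:
    """Per-effort fitness returns over P's prey ``{F0, F1..Fn, C}``.

    Entry ``j <= n`` is ``w_j = eP u_j F_j``; the last entry is
    ``w_C = eP uC C``.  The replicator mean is ``sum_k theta_k w_k`` with
    ``thetaC`` taking the final slot.
    """
    w = params.eP * np.concatenate(
        ([params.u0 * state.F0], params.ui * state.F, [params.uC * state.C])
    )
    return w


# ---------------------------------------------------------------------------
# analytic Jacobian


def rhs_jacobian(x: np.ndarray, p: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_vector` at an arbitrary state.

    Layout matches the packed state: rows/columns are
    ``(F0, F1..Fn, C, P, theta0..thetan)``.  The top-left
    ``(n+3) x (n+3)`` block is the "ecological" Jacobian — the biomass
    equations differentiated with foraging efforts frozen — used for the
    local-stability maps; the remaining rows/columns carry the replicator
    coupling.  Validated against central finite differences in the tests.
    """
    n = p.n
    F0 = x[0]
    F = x[1:1 + n]
    C = x[n + 1]
    P = x[n + 2]
    th = x[n + 3:]
    th0 = th[0]
    thi = th[1:]
    s = th.sum()
    thC = 1.0 - s
    Fall = x[:n + 1]

    if p.q > 0:
        F0c = max(F0, EPS_CAP)
        cap = F0c / p.q
        # derivative of F0/q w.r.t. F0, zero inside the clamp
        dcap = 1.0 / p.q if F0 > EPS_CAP else 0.0
    else:
        cap = np.inf
        dcap = 0.0

    D = p.dim
    J = np.zeros((D, D))
    iC, iP = n + 1, n + 2
    iT = n + 3

    # --- dF0 row ---------------------------------------------------------
    b0 = (p.r0 - p.alpha0 * F0 - p.beta[1:, 0] @ F - p.aC * C
          - th0 * p.u0 * P - p.d0)
    J[0, 0] = b0 - p.alpha0 * F0
    J[0, 1:1 + n] = -p.beta[1:, 0] * F0
    J[0, iC] = -p.aC * F0
    J[0, iP] = -th0 * p.u0 * F0
    J[0, iT] = -p.u0 * F0 * P

    # --- exploiter rows ---------------------------------------------------
    comp = p.beta[:, 1:].T @ Fall
    bi = p.ri * (1.0 - F / cap) - comp - thi * p.ui * P - p.di
    for k in range(n):
        i = 1 + k
        dcap_term = p.ri[k] * F[k] ** 2 * dcap / cap ** 2 if np.isfinite(cap) else 0.0
        J[i, 0] = dcap_term - p.beta[0, i] * F[k]
        J[i, 1:1 + n] = -p.beta[1:, i] * F[k]
        J[i, i] = bi[k] - (p.ri[k] * F[k] / cap if np.isfinite(cap) else 0.0)
        J[i, iP] = -thi[k] * p.ui[k] * F[k]
        J[i, iT + 1 + k] = -p.ui[k] * F[k] * P

    # --- dC row -----------------------------------------------------------
    bC = p.eC * p.aC * F0 - thC * p.uC * P - p.dC - p.alphaC * C
    J[iC, 0] = p.eC * p.aC * C
    J[iC, iC] = bC - p.alphaC * C
    J[iC, iP] = -thC * p.uC * C
    J[iC, iT:] = p.uC * C * P          # d(thetaC)/d(thetaj) = -1

    # --- dP row -----------------------------------------------------------
    w = p.eP * np.concatenate(([p.u0 * F0], p.ui * F))
    wC = p.eP * p.uC * C
    WP = th @ w + thC * wC - p.dP - p.alphaP * P
    J[iP, 0] = p.eP * th0 * p.u0 * P
    J[iP, 1:1 + n] = p.eP * thi * p.ui * P
    J[iP, iC] = p.eP * thC * p.uC * P
    J[iP, iP] = WP - p.alphaP * P
    J[iP, iT:] = P * (w - wC)

    # --- replicator rows --------------------------------------------------
    wbar = th @ w + thC * wC
    dwdF = p.eP * np.concatenate(([p.u0], p.ui))   # dw_j/dF_j
    for j in range(n + 1):
        r = iT + j
        # biomass columns: d/dF_k [ g th_j (w_j - wbar) ]
        for k_col in range(n + 1):
            dw_j = dwdF[k_col] if k_col == j else 0.0
            J[r, k_col] = p.g * th[j] * (dw_j - th[k_col] * dwdF[k_col])
        J[r, iC] = -p.g * th[j] * thC * p.eP * p.uC
        # effort columns
        for m in range(n + 1):
            term = -th[j] * (w[m] - wC)
            if m == j:
                term += w[j] - wbar
            J[r, iT + m] = p.g * term
    return J
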