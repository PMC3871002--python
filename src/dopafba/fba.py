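"""Steady-state linear-programming core.

Flux balance analysis (FBA) optimizes a linear objective c·v over flux
vectors v satisfying the steady-state constraint S·v = 0 and per-reaction
bounds lb ≤ v ≤ ub.  Because LPs routinely have alternate optima, the
reported flux vector is canonicalized: after the primary solve the
objective is fixed at its optimum and the total flux Σv is minimized
(a parsimonious solution), which makes outputs reproducible across runs
and solver versions.  Flux variability analysis (FVA) quantifies the
remaining per-reaction freedom at the optimum, and its degenerate ranges
mark fluxes that are unique.

``enumerate_vertices`` is an independent brute-force oracle for small
instances: it enumerates candidate basic feasible solutions of the flux
polytope by fixing subsets of reactions at their bounds and solving the
remaining square/overdetermined linear systems.  Exponential cost is
accepted; a hard size cap refuses anything larger.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import SizeError, SolverError
from .network import (
    APOPTOSIS_GROUPS,
    DEGRADATION_GROUPS,
    CellModel,
    FluxGroups,
    build_stoichiometric_matrix,
)

__all__ = [
    "Objective",
    "FBASolution",
    "FVARange",
    "Tolerances",
    "solve_fba",
    "flux_variability",
    "enumerate_vertices",
    "canonical_objectives",
]

OBJECTIVE_LABELS = ("maxApo", "minApo", "maxDeg", "minDeg")


@dataclass(frozen=True)
class Tolerances:
    """Numerical tolerances, configurable but defaulted.

    feasibility: slack allowed on bound containment checks.
    steady_state: allowed |S·v|∞ residual.
    fva_uniqueness: an FVA range narrower than this counts as unique.
    """

    feasibility: float = 1e-9
    steady_state: float = 1e-6
    fva_uniqueness: float = 1e-6


DEFAULT_TOLERANCES = Tolerances()


@dataclass(frozen=True)
class Objective:
    """Optimization sense plus per-reaction weights.

    Listed reactions default to weight 1; unlisted reactions weigh 0.
    """

    sense: str  # "minimize" | "maximize"
    weights: Mapping[str, float]
    label: str = "custom"

    def __post_init__(self):
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"unknown sense {self.sense!r}")
        if not self.weights:
            raise ValueError("objective weights must be non-empty")
        object.__setattr__(self, "weights", dict(self.weights))

    @classmethod
    def over_groups(
        cls,
        groups: FluxGroups,
        labels: Sequence[str],
        sense: str,
        name: str = "custom",
    ) -> "Objective":
        """Unit-weight objective over all reactions of the given groups."""
        weights = {rid: 1.0 for rid in groups.reactions_in(labels)}
        return cls(sense=sense, weights=weights, label=name)

    def vector(self, model: CellModel) -> np.ndarray:
        ids = model.reaction_ids
        unknown = set(self.weights) - set(ids)
        if unknown:
            raise KeyError(f"objective references unknown reaction(s): {sorted(unknown)}")
        return np.array([self.weights.get(r, 0.0) for r in ids])

    def value(self, fluxes: Mapping[str, float]) -> float:
        return float(sum(w * fluxes.get(r, 0.0) for r, w in self.weights.items()))


def canonical_objectives(groups: FluxGroups) -> dict[str, Objective]:
    """The four grouped target functions: min/max apoptosis and degradation.

    minApo/maxApo put weight 1 on every reaction in the two apoptosis
    groups (Lewy-body induced and mitochondria induced); minDeg/maxDeg on
    the lysosome, proteasome and mitophagy degradation groups.
    """
    apo = [g for g in APOPTOSIS_GROUPS if g in groups]
    deg = [g for g in DEGRADATION_GROUPS if g in groups]
    if not apo or not deg:
        raise KeyError("model groups lack apoptosis and/or degradation labels")
    return {
        "maxApo": Objective.over_groups(groups, apo, "maximize", "maxApo"),
        "minApo": Objective.over_groups(groups, apo, "minimize", "minApo"),
        "maxDeg": Objective.over_groups(groups, deg, "maximize", "maxDeg"),
        "minDeg": Objective.over_groups(groups, deg, "minimize", "minDeg"),
    }


@dataclass(frozen=True)
class FBASolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    fluxes: Mapping[str, float] | None = None
    objective_value: float | None = None
    uniqueness_flags: Mapping[str, bool] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FVARange:
    reaction_id: str
    min_flux: float
    max_flux: float

    @property
    def unique(self) -> bool:
        return self.max_flux - self.min_flux <= DEFAULT_TOLERANCES.fva_uniqueness


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _linprog(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status in (1, 4):  # iteration limit / numerical trouble
        raise SolverError(f"LP backend failure: {res.message}")
    return res


def _model_arrays(model: CellModel):
    S = build_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


def solve_fba(
    model: CellModel,
    objective: Objective,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
    uniqueness: bool = False,
) -> FBASolution:
    """Solve max/min c·v subject to S·v = 0 and lb ≤ v ≤ ub.

    When optimal, a second LP fixes c·v at the optimum and minimizes Σv so
    the reported flux vector is deterministic (parsimonious tie-break).
    With ``uniqueness=True`` an FVA pass flags which reported fluxes are
    unique at the optimum.
    """
    S, lb, ub = _model_arrays(model)
    c = objective.vector(model)
    sign = -1.0 if objective.sense == "maximize" else 1.0
    bounds = list(zip(lb, ub))
    res = _linprog(sign * c, S, np.zeros(S.shape[0]), bounds)
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FBASolution(status=status)

    opt = float(c @ res.x)
    # Parsimonious tie-break: fix the objective, minimize total flux.
    A_eq = np.vstack([S, c])
    b_eq = np.append(np.zeros(S.shape[0]), opt)
    res2 = _linprog(np.ones(len(c)), A_eq, b_eq, bounds)
    x = res2.x if res2.status == 0 else res.x
    x = np.clip(x, lb, ub)  # strip solver round-off outside the bounds
    fluxes = {rid: float(v) for rid, v in zip(model.reaction_ids, x)}

    flags: dict[str, bool] = {}
    if uniqueness:
        ranges = flux_variability(model, objective, tolerances)
        flags = {
            fr.reaction_id: (fr.max_flux - fr.min_flux) <= tolerances.fva_uniqueness
            for fr in ranges
        }
    sol = FBASolution(
        status="optimal",
        fluxes=fluxes,
        objective_value=opt,
        uniqueness_flags=flags,
    )
    _check_solution(model, S, lb, ub, x, tolerances)
    return sol


def _check_solution(model, S, lb, ub, x, tol: Tolerances):
    resid = float(np.max(np.abs(S @ x))) if S.size else 0.0
    if resid > tol.steady_state:
        raise SolverError(f"steady-state residual {resid:.2e} exceeds tolerance")
    if np.any(x < lb - 1e-6) or np.any(x > ub + 1e-6):
        raise SolverError("solution violates flux bounds beyond tolerance")


def flux_variability(
    model: CellModel,
    objective: Objective,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[FVARange]:
    """Per-reaction min/max flux with the objective fixed at its optimum."""
    S, lb, ub = _model_arrays(model)
    c = objective.vector(model)
    sign = -1.0 if objective.sense == "maximize" else 1.0
    bounds = list(zip(lb, ub))
    base = _linprog(sign * c, S, np.zeros(S.shape[0]), bounds)
    if base.status != 0:
        raise SolverError(
            f"FVA base problem is {_STATUS.get(base.status, 'failed')}"
        )
    opt = float(c @ base.x)
    A_eq = np.vstack([S, c])
    b_eq = np.append(np.zeros(S.shape[0]), opt)
    n = len(model.reactions)
    out = []
    for j, rid in enumerate(model.reaction_ids):
        e = np.zeros(n)
        e[j] = 1.0
        lo = _linprog(e, A_eq, b_eq, bounds)
        hi = _linprog(-e, A_eq, b_eq, bounds)
        # The equality c·v = opt can be marginally infeasible numerically;
        # fall back to the base vertex value in that case.
        vmin = float(lo.x[j]) if lo.status == 0 else float(base.x[j])
        vmax = float(hi.x[j]) if hi.status == 0 else float(base.x[j])
        if vmin > vmax:
            vmin, vmax = vmax, vmin
        out.append(FVARange(rid, min_flux=vmin, max_flux=vmax))
    return out


@dataclass(frozen=True)
class EnumerationResult:
    status: str
    objective_value: float | None = None
    fluxes: Mapping[str, float] | None = None


def enumerate_vertices(
    model: CellModel,
    objective: Objective,
    cap: int = 12,
    residual_tol: float = 1e-8,
    bound_tol: float = 1e-9,
) -> EnumerationResult:
    """Exhaustive oracle: best objective over basic feasible solutions.

    Every vertex of {S·v = 0, lb ≤ v ≤ ub} has at most rank(S) reactions
    strictly between their bounds.  All subsets F of "free" reactions up to
    that size are enumerated; the remaining reactions take every lb/ub
    combination and the free block is solved by least squares.  Candidates
    with nonzero residual or out-of-bounds entries are discarded.  The cap
    is hard: larger instances raise, never silently approximate.
    """
    n = len(model.reactions)
    if n > cap:
        raise SizeError(f"{n} reactions exceed the enumeration cap of {cap}")
    S, lb, ub = _model_arrays(model)
    if not np.all(np.isfinite(lb)) or not np.all(np.isfinite(ub)):
        raise SizeError("vertex enumeration requires finite bounds")
    c = objective.vector(model)
    maximize = objective.sense == "maximize"
    m = S.shape[0]
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0

    best_val: float | None = None
    best_x: np.ndarray | None = None
    cols = list(range(n))
    for k in range(0, min(n, rank) + 1):
        for F in itertools.combinations(cols, k):
            N = [j for j in cols if j not in F]
            if N:
                grids = np.array(
                    list(itertools.product(*[(lb[j], ub[j]) for j in N]))
                )  # (batch, |N|)
            else:
                grids = np.zeros((1, 0))
            rhs = -S[:, N] @ grids.T if N else np.zeros((m, 1))
            if k:
                XF, *_ = np.linalg.lstsq(S[:, F], rhs, rcond=None)
                resid = S[:, F] @ XF - rhs
            else:
                XF = np.zeros((0, grids.shape[0]))
                resid = -rhs
            ok = np.max(np.abs(resid), axis=0) <= residual_tol if m else np.ones(
                grids.shape[0], bool
            )
            if k:
                in_bounds = np.all(
                    (XF >= lb[list(F)][:, None] - bound_tol)
                    & (XF <= ub[list(F)][:, None] + bound_tol),
                    axis=0,
                )
                ok = ok & in_bounds
            for b_idx in np.nonzero(ok)[0]:
                x = np.empty(n)
                if N:
                    x[N] = grids[b_idx]
                if k:
                    x[list(F)] = np.clip(XF[:, b_idx], lb[list(F)], ub[list(F)])
                val = float(c @ x)
                if (
                    best_val is None
                    or (maximize and val > best_val)
                    or (not maximize and val < best_val)
                ):
                    best_val = val
                    best_x = x
    if best_val is None:
        return EnumerationResult(status="infeasible")
    fluxes = {rid: float(v) for rid, v in zip(model.reaction_ids, best_x)}
    return EnumerationResult(status="optimal", objective_value=best_val, fluxes=fluxes)
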