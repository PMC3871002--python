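"""The in-silico experiment suite.

Two analysis shapes are provided:

* the *basic* four-objective suite — the model is solved under maximal and
  minimal apoptosis and maximal and minimal degradation, and every flux
  group is reported as its summed flux per objective (the group × objective
  grid of the normal-cell experiment); and
* *input-flux scans* — one boundary input reaction (O₂, ATP, MPTP, αSYN or
  tyrosine) is pinned to each value of a sweep (default step 1 µM·h⁻¹),
  the model is re-solved under a chosen target function at every value,
  and the grouped fluxes are recorded.  Infeasible points are recorded,
  not skipped, so feasibility windows are computable.  Two read-outs
  extract the headline numbers: the feasibility window of an input (the
  range of pinned values admitting any steady state) and the onset value
  at which a group's flux appears or durably vanishes.

Scans are pure: the model object is never mutated, and rerunning a spec
gives an identical result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .errors import AnalysisError, SpecError
from .fba import (
    OBJECTIVE_LABELS,
    FBASolution,
    Objective,
    Tolerances,
    DEFAULT_TOLERANCES,
    canonical_objectives,
    solve_fba,
)
from .network import CellModel, FluxGroups, group_sums, normalize_group_label

__all__ = [
    "ObjectiveSuiteResult",
    "ScanSpec",
    "ScanPoint",
    "ScanResult",
    "FeasibilityWindow",
    "OnsetReport",
    "run_objective_suite",
    "run_scan",
    "find_feasibility_window",
    "find_onset",
]


@dataclass(frozen=True)
class ObjectiveSuiteResult:
    """Group sums (µM·h⁻¹) per objective, plus the objective optima."""

    values: Mapping[str, Mapping[str, float]]  # objective label → group → flux
    objective_values: Mapping[str, float]
    uniqueness: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.values) != set(OBJECTIVE_LABELS):
            raise AnalysisError(
                f"suite must contain exactly the objectives {OBJECTIVE_LABELS}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Group × objective grid in the canonical column order."""
        return pd.DataFrame(
            {lab: pd.Series(self.values[lab]) for lab in OBJECTIVE_LABELS}
        ).rename_axis("group")


def run_objective_suite(
    model: CellModel,
    groups: FluxGroups,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
    uniqueness: bool = False,
) -> ObjectiveSuiteResult:
    """Solve the four canonical target functions on the basic model.

    Each objective is an independent solve with the parsimonious
    tie-break; an infeasible basic model is an error, not a data point.
    With ``uniqueness=True`` each solve also runs FVA and the per-group
    uniqueness flag is the conjunction over member reactions.
    """
    objectives = canonical_objectives(groups)
    values: dict[str, dict[str, float]] = {}
    optima: dict[str, float] = {}
    uniq: dict[str, dict[str, bool]] = {}
    for label, obj in objectives.items():
        sol = solve_fba(model, obj, tolerances=tolerances, uniqueness=uniqueness)
        if not sol.optimal:
            raise AnalysisError(f"basic model is {sol.status} under {label}")
        values[label] = group_sums(groups, sol.fluxes)
        optima[label] = float(sol.objective_value)
        if uniqueness:
            uniq[label] = {
                g: all(sol.uniqueness_flags.get(r, False) for r in members)
                for g, members in groups.members.items()
            }
    return ObjectiveSuiteResult(values=values, objective_values=optima, uniqueness=uniq)


@dataclass(frozen=True)
class ScanSpec:
    """One pinned-input sweep.

    pin_mode ``pin`` fixes lb = ub = value (the default: two-sided
    requirements such as a forced surplus are only visible when the input
    is pinned, not merely allowed); ``relax_ub`` sets only ub = value.
    ``augment_objective`` adds the scanned input reaction to the target
    function with weight 1 in the primary sense (used by the O₂ preset).
    """

    input_reaction_id: str
    values: tuple[float, ...]
    objective_label: str = "maxDeg"  # minApo | maxDeg
    pin_mode: str = "pin"  # pin | relax_ub
    augment_objective: bool = False

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise SpecError("scan needs at least one value")
        if any(v < 0 for v in vals):
            raise SpecError("scan values must be >= 0")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise SpecError("scan values must be strictly increasing")
        if self.pin_mode not in ("pin", "relax_ub"):
            raise SpecError(f"unknown pin mode {self.pin_mode!r}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def sweep(cls, input_reaction_id: str, stop: float = 100.0, step: float = 1.0,
              start: float = 0.0, **kw) -> "ScanSpec":
        n = int(round((stop - start) / step))
        values = tuple(start + i * step for i in range(n + 1))
        return cls(input_reaction_id=input_reaction_id, values=values, **kw)


@dataclass(frozen=True)
class ScanPoint:
    input_value: float
    status: str
    group_fluxes: Mapping[str, float] | None = None
    objective_value: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class ScanResult:
    spec: ScanSpec
    points: tuple[ScanPoint, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: input_value, group, flux (optimal points only)."""
        rows = []
        for p in self.points:
            if not p.optimal:
                rows.append(
                    {"input_value": p.input_value, "group": "(status)",
                     "flux": float("nan"), "status": p.status}
                )
                continue
            for g, f in p.group_fluxes.items():
                rows.append(
                    {"input_value": p.input_value, "group": g, "flux": f,
                     "status": p.status}
                )
        return pd.DataFrame(rows, columns=["input_value", "group", "flux", "status"])

    def series(self, group: str) -> list[tuple[float, float | None]]:
        """(value, group flux) pairs; None where the point is infeasible."""
        g = normalize_group_label(group)
        out = []
        for p in self.points:
            if p.optimal:
                if g not in p.group_fluxes:
                    raise KeyError(f"unknown group {group!r}")
                out.append((p.input_value, p.group_fluxes[g]))
            else:
                out.append((p.input_value, None))
        return out


def _objective_for_scan(
    spec: ScanSpec, groups: FluxGroups, model: CellModel
) -> Objective:
    objectives = canonical_objectives(groups)
    if spec.objective_label not in objectives:
        raise SpecError(f"unknown objective label {spec.objective_label!r}")
    obj = objectives[spec.objective_label]
    if spec.augment_objective:
        weights = dict(obj.weights)
        weights[spec.input_reaction_id] = weights.get(spec.input_reaction_id, 0.0) + 1.0
        obj = Objective(sense=obj.sense, weights=weights,
                        label=f"{obj.label}+{spec.input_reaction_id}")
    return obj


def run_scan(
    model: CellModel,
    spec: ScanSpec,
    groups: FluxGroups,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> ScanResult:
    """Sweep one input reaction and solve at every value.

    The scanned reaction must be a boundary input.  At each value a copy
    of the model with adjusted bounds is solved; the input model is never
    mutated.
    """
    try:
        rxn = model.reaction(spec.input_reaction_id)
    except KeyError as exc:
        raise SpecError(f"unknown reaction {spec.input_reaction_id!r}") from exc
    if rxn.boundary_kind != "input":
        raise SpecError(
            f"reaction {rxn.id} is {rxn.boundary_kind}, not a boundary input"
        )
    objective = _objective_for_scan(spec, groups, model)
    points = []
    for value in spec.values:
        if spec.pin_mode == "pin":
            pinned = replace(rxn, lower_bound=value, upper_bound=value)
        else:
            pinned = replace(rxn, lower_bound=min(rxn.lower_bound, value),
                             upper_bound=value)
        sol: FBASolution = solve_fba(
            model.with_reaction(pinned), objective, tolerances=tolerances
        )
        if sol.optimal:
            points.append(
                ScanPoint(
                    input_value=value,
                    status="optimal",
                    group_fluxes=group_sums(groups, sol.fluxes),
                    objective_value=float(sol.objective_value),
                )
            )
        else:
            points.append(ScanPoint(input_value=value, status=sol.status))
    return ScanResult(spec=spec, points=tuple(points))


@dataclass(frozen=True)
class FeasibilityWindow:
    min_feasible: float | None
    max_feasible: float | None


def find_feasibility_window(scan: ScanResult) -> FeasibilityWindow:
    """Contiguous feasible range of the scanned input.

    min_feasible is the smallest scanned value with an optimal solve;
    max_feasible the end of the maximal contiguous optimal run starting
    there.  Both are None when no point is feasible.
    """
    points = scan.points
    start = next((i for i, p in enumerate(points) if p.optimal), None)
    if start is None:
        return FeasibilityWindow(None, None)
    end = start
    while end + 1 < len(points) and points[end + 1].optimal:
        end += 1
    return FeasibilityWindow(points[start].input_value, points[end].input_value)


@dataclass(frozen=True)
class OnsetReport:
    group: str
    direction: str  # "appears" | "vanishes"
    threshold: float | None
    tolerance: float


def find_onset(
    scan: ScanResult, group: str, direction: str, tol: float = 1e-6
) -> OnsetReport:
    """Threshold value at which a group flux appears or durably vanishes.

    ``appears``: first scanned value whose group flux exceeds tol.
    ``vanishes``: first scanned value from which the flux stays ≤ tol at
    every larger scanned value (persistence guards against the transient
    fluctuations such scans can show).  Infeasible points carry no flux
    and are ignored for ``appears``; for ``vanishes`` they interrupt
    persistence runs.  None when no value qualifies.
    """
    if direction not in ("appears", "vanishes"):
        raise SpecError(f"unknown onset direction {direction!r}")
    series = scan.series(group)  # raises KeyError on unknown group
    threshold = None
    if direction == "appears":
        for value, flux in series:
            if flux is not None and flux > tol:
                threshold = value
                break
    else:
        # walk backwards: extend the trailing run of certified-quiet points
        run_start = None
        for value, flux in reversed(series):
            if flux is not None and flux <= tol:
                run_start = value
            else:
                break
        threshold = run_start
    return OnsetReport(
        group=normalize_group_label(group),
        direction=direction,
        threshold=threshold,
        tolerance=tol,
    )


def scan_summary(scan: ScanResult, onset_groups: Sequence[str] = ()) -> dict:
    """JSON-ready summary of a scan: window plus onsets for chosen groups."""
    window = find_feasibility_window(scan)
    out = {
        "input_reaction": scan.spec.input_reaction_id,
        "objective": scan.spec.objective_label,
        "pin_mode": scan.spec.pin_mode,
        "n_points": len(scan.points),
        "n_feasible": sum(p.optimal for p in scan.points),
        "feasibility_window": {
            "min_feasible": window.min_feasible,
            "max_feasible": window.max_feasible,
        },
        "onsets": {},
    }
    for g in onset_groups:
        appear = find_onset(scan, g, "appears")
        vanish = find_onset(scan, g, "vanishes")
        out["onsets"][normalize_group_label(g)] = {
            "appears": appear.threshold,
            "vanishes": vanish.threshold,
        }
    return out
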