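"""Domain types for the stoichiometric process network.

The model is a set of metabolites and *irreversible* reactions with finite
non-negative flux bounds in µM·h⁻¹.  Reversibility, where biologically
needed, is represented as a forward/backward reaction pair.  Compartments
are metadata only: flux balance here is purely stoichiometric, with no
compartment-volume scaling.

Boundary reactions follow the IN/OUT convention of the source network:
*input* reactions have only positive stoichiometric coefficients (they
create matter), *output* reactions only negative ones (they remove it).

Reaction groups carry the biological read-out of a solution: apoptosis
initiation, degradation routes, ROS production and damage, dopamine
release, α-synuclein handling.  Objectives and all reported tables are
sums over these groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import GroupingError, ModelIntegrityError, PolicyError

__all__ = [
    "COMPARTMENTS",
    "CURRENCY_METABOLITES",
    "CANONICAL_GROUPS",
    "ALPHA_SYN",
    "normalize_group_label",
    "Metabolite",
    "Reaction",
    "CellModel",
    "FluxGroups",
    "BoundsPolicy",
    "DEFAULT_BOUNDS_POLICY",
    "build_stoichiometric_matrix",
    "apply_bounds_policy",
    "assign_groups",
    "group_sums",
]

COMPARTMENTS = frozenset(
    {"cytosol", "mitochondrion", "vesicle", "extracellular", "lysosome"}
)

#: Molecular units of currency: ubiquitous cofactors allowed to flow in and
#: out of the cell within their defined ranges.
CURRENCY_METABOLITES = frozenset(
    {"O2", "H2O", "NAD+", "NADH", "Fe3+", "Fe2+", "ADP+Pi", "ATP"}
)

ALPHA_SYN = "αSYN"  # αSYN

#: The 18 canonical flux-group labels used in all reports.
CANONICAL_GROUPS = (
    "ROS production (DA)",
    "ROS production (mitochondria, complex I)",
    "ROS production (mitochondria, complex III)",
    "ROS elimination (DJ-1)",
    "ROS damage (protein)",
    "ROS damage (mitochondria)",
    "ROS damage (DNA)",
    "Apoptosis (LBs)",
    "Apoptosis (mitochondria)",
    "Degradation (lysosome)",
    "Degradation (proteasome)",
    "Degradation (mitophagy)",
    "Biogenesis of mitochondria",
    "Extracellular DA",
    f"{ALPHA_SYN} aggregation",
    f"{ALPHA_SYN} output reaction",
    f"Toxic effect of {ALPHA_SYN} aggregates",
    f"Inhibition of {ALPHA_SYN} aggregation by DJ-1",
)

APOPTOSIS_GROUPS = ("Apoptosis (LBs)", "Apoptosis (mitochondria)")
DEGRADATION_GROUPS = (
    "Degradation (lysosome)",
    "Degradation (proteasome)",
    "Degradation (mitophagy)",
)


def normalize_group_label(label: str) -> str:
    """Return the canonical group label, accepting the ASCII alias ``aSYN``.

    Labels that are not canonical are returned unchanged (custom groups are
    allowed); only the αSYN spelling is normalized.
    """
    return label.replace("aSYN", ALPHA_SYN)


@dataclass(frozen=True)
class Metabolite:
    """A model species.

    ``is_currency`` marks the molecular units of currency (O₂, H₂O, NAD⁺,
    NADH, Fe3+, Fe2+, ADP+Pi, ATP) that may freely cross the boundary
    within their bounds.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    is_currency: bool = False


@dataclass(frozen=True)
class Reaction:
    """An irreversible bounded reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative
    means consumed, positive produced.  Bounds are fluxes in µM·h⁻¹ with
    ``0 <= lower_bound <= upper_bound``.

    ``speed_tag`` drives the bound policy: ``default`` reactions get the
    full (0, 100) range, ``slow`` reactions are capped at 30 (reactions
    known to occur rarely or proceed slowly), and ``best_et_al`` reactions
    of the dopamine pathway are constrained to ±10 % of a measured
    reference flux carried in ``best_reference_flux``.
    """

    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 100.0
    boundary_kind: str = "internal"  # input | output | internal
    speed_tag: str = "default"  # default | slow | best_et_al
    best_reference_flux: float | None = None
    groups: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(
            self, "groups", frozenset(normalize_group_label(g) for g in self.groups)
        )


@dataclass
class CellModel:
    """An ordered stoichiometric network with provenance.

    ``provenance`` records which network is in use: ``deposited`` (a file
    from the public model repository), ``curated-skeleton`` (the packaged
    reconstruction) or ``synthetic`` (generated).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    provenance: str = "synthetic"

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def with_reaction(self, rxn: Reaction) -> "CellModel":
        """Return a copy with one reaction replaced (matched by id)."""
        reactions = [rxn if r.id == rxn.id else r for r in self.reactions]
        if rxn.id not in {r.id for r in self.reactions}:
            raise KeyError(rxn.id)
        return CellModel(list(self.metabolites), reactions, self.provenance)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise ModelIntegrityError."""
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate metabolite id(s): {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate reaction id(s): {dup}")
        known = set(met_ids)
        kinds = {"input", "output", "internal"}
        for m in self.metabolites:
            if m.compartment not in COMPARTMENTS:
                raise ModelIntegrityError(
                    f"metabolite {m.id}: unknown compartment {m.compartment!r}"
                )
        for r in self.reactions:
            if r.boundary_kind not in kinds:
                raise ModelIntegrityError(
                    f"reaction {r.id}: unknown boundary kind {r.boundary_kind!r}"
                )
            if not (0.0 <= r.lower_bound <= r.upper_bound):
                raise ModelIntegrityError(
                    f"reaction {r.id}: bounds ({r.lower_bound}, {r.upper_bound}) "
                    "violate 0 <= lb <= ub"
                )
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id}: unresolved metabolite reference(s) "
                    f"{sorted(missing)}"
                )
            if r.boundary_kind == "internal" and not r.stoichiometry:
                raise ModelIntegrityError(
                    f"internal reaction {r.id} has empty stoichiometry"
                )
            coeffs = r.stoichiometry.values()
            if r.boundary_kind == "input" and any(c <= 0 for c in coeffs):
                raise ModelIntegrityError(
                    f"input reaction {r.id} has non-positive coefficients"
                )
            if r.boundary_kind == "output" and any(c >= 0 for c in coeffs):
                raise ModelIntegrityError(
                    f"output reaction {r.id} has non-negative coefficients"
                )
        if self.reactions:
            kinds_present = {r.boundary_kind for r in self.reactions}
            if "input" not in kinds_present or "output" not in kinds_present:
                raise ModelIntegrityError(
                    "model must contain at least one input and one output reaction"
                )


@dataclass(frozen=True)
class FluxGroups:
    """Mapping from group label to the set of member reaction ids."""

    members: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self,
            "members",
            {
                normalize_group_label(k): frozenset(v)
                for k, v in dict(self.members).items()
            },
        )

    def labels(self) -> tuple[str, ...]:
        return tuple(self.members)

    def __getitem__(self, label: str) -> frozenset[str]:
        return self.members[normalize_group_label(label)]

    def __contains__(self, label: str) -> bool:
        return normalize_group_label(label) in self.members

    def reactions_in(self, labels: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for lab in labels:
            out |= set(self[lab])
        return frozenset(out)


@dataclass(frozen=True)
class BoundsPolicy:
    """Flux-bound assignment policy.

    default_range
        (0, 100) µM·h⁻¹ for ordinary reactions.
    slow_max
        30 µM·h⁻¹ upper bound for reactions tagged slow.
    best_tolerance
        ±fraction applied around a measured dopamine-pathway reference flux.
    zero_lb_overrides
        Reactions whose lower bound is forced to 0 after the ±10 % window,
        because the cell model routes their substrate through additional
        reactions absent from the original kinetic study.
    """

    default_range: tuple[float, float] = (0.0, 100.0)
    slow_max: float = 30.0
    best_tolerance: float = 0.10
    zero_lb_overrides: frozenset[str] = frozenset(
        {"OMSynthesis1", "OMSynthesis2", "HVASynthesis3", "HVASynthesis4"}
    )

    def __post_init__(self):
        if not (0.0 <= self.best_tolerance < 1.0):
            raise PolicyError("best_tolerance must be in [0, 1)")
        if self.slow_max > self.default_range[1]:
            raise PolicyError("slow_max must not exceed the default upper bound")


DEFAULT_BOUNDS_POLICY = BoundsPolicy()


def build_stoichiometric_matrix(model: CellModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites × reactions).

    Entry (i, j) is the signed coefficient of metabolite i in reaction j,
    zero when absent; row order follows ``model.metabolites`` and column
    order ``model.reactions``, so steady state is ``S @ v == 0`` for a flux
    vector ``v`` in reaction order.
    """
    model.validate()
    index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[index[met_id], j] = coeff
    return S


def apply_bounds_policy(
    model: CellModel, policy: BoundsPolicy = DEFAULT_BOUNDS_POLICY
) -> CellModel:
    """Return a copy of the model with policy bounds applied.

    default → (0, 100); slow → (0, 30); best_et_al with reference f →
    (f·(1−tol), f·(1+tol)); finally the zero-lb overrides force their lower
    bound to 0.  Idempotent: bounds depend only on tags and references.
    """
    lo_d, hi_d = policy.default_range
    new_reactions = []
    for r in model.reactions:
        if r.speed_tag == "default":
            lb, ub = lo_d, hi_d
        elif r.speed_tag == "slow":
            lb, ub = lo_d, policy.slow_max
        elif r.speed_tag == "best_et_al":
            if r.best_reference_flux is None:
                raise PolicyError(
                    f"reaction {r.id} tagged best_et_al without a reference flux"
                )
            f = r.best_reference_flux
            lb = f * (1.0 - policy.best_tolerance)
            ub = f * (1.0 + policy.best_tolerance)
        else:
            raise PolicyError(f"reaction {r.id}: unknown speed tag {r.speed_tag!r}")
        if r.id in policy.zero_lb_overrides:
            lb = 0.0
        new_reactions.append(replace(r, lower_bound=lb, upper_bound=ub))
    return CellModel(list(model.metabolites), new_reactions, model.provenance)


def assign_groups(
    model: CellModel, tag_table: Mapping[str, Iterable[str]]
) -> FluxGroups:
    """Build FluxGroups from a reaction-id → labels table.

    Reactions not mentioned in the table belong to no group; a reaction may
    carry several labels.
    """
    known = set(model.reaction_ids)
    unknown = set(tag_table) - known
    if unknown:
        raise GroupingError(f"unknown reaction id(s) in tag table: {sorted(unknown)}")
    members: dict[str, set[str]] = {}
    for rxn_id, labels in tag_table.items():
        for label in labels:
            members.setdefault(normalize_group_label(label), set()).add(rxn_id)
    return FluxGroups({k: frozenset(v) for k, v in members.items()})


def groups_from_model(model: CellModel) -> FluxGroups:
    """Collect FluxGroups from the ``groups`` field of each reaction."""
    table = {r.id: sorted(r.groups) for r in model.reactions if r.groups}
    return assign_groups(model, table)


def group_sums(
    groups: FluxGroups, fluxes: Mapping[str, float]
) -> dict[str, float]:
    """Summed flux per group label for one flux vector."""
    return {
        label: float(sum(fluxes.get(rid, 0.0) for rid in members))
        for label, members in groups.members.items()
    }
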