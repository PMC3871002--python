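"""Seeded generators of networks with known structure and planted solutions.

These emulate the structural assumptions of the neuronal network —
irreversible reactions with finite bounds in µM·h⁻¹, boundary input and
output reactions, currency metabolites and tagged reaction groups —
without attempting to regenerate the actual curated network.

Feasibility is guaranteed *by planting*: a non-negative flux vector v* is
drawn first, boundary reactions are added whose planted fluxes absorb each
metabolite's net imbalance so that S·v* = 0 holds exactly, and bounds are
then placed around v* with a configurable slack.  Generation is a pure
function of the spec and seed and never calls a solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .network import (
    ALPHA_SYN,
    CellModel,
    FluxGroups,
    Metabolite,
    Reaction,
    groups_from_model,
)

__all__ = [
    "SyntheticSpec",
    "generate_random_network",
    "generate_neuronlike_network",
    "NeuronlikeNetwork",
    "micro_fixtures",
    "MicroFixture",
]

_SINK_LABELS = (
    "Apoptosis (mitochondria)",
    "Degradation (lysosome)",
    "Apoptosis (LBs)",
    "Degradation (proteasome)",
    "Degradation (mitophagy)",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of seeded random-network generation.

    bound_slack is the µM·h⁻¹ margin placed around the planted flux:
    lb = max(0, v*−slack), ub = v*+slack.  With slack 0 every reaction is
    pinned at its planted flux.
    """

    n_metabolites: int = 5
    n_reactions: int = 8
    density: float = 0.5
    n_inputs: int = 1
    n_outputs: int = 1
    bound_slack: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < self.n_inputs + self.n_outputs:
            raise ValueError("n_reactions must cover n_inputs + n_outputs")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if self.bound_slack < 0:
            raise ValueError("bound_slack must be >= 0")
        if self.n_metabolites < 1 or self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("need at least one metabolite, input and output")


class PlantedNetwork(NamedTuple):
    model: CellModel
    planted_fluxes: dict[str, float]


def generate_random_network(spec: SyntheticSpec) -> PlantedNetwork:
    """Random bounded irreversible network with a planted feasible flux.

    Internal reactions get sparse integer stoichiometry (coefficients in
    ±{1, 2}, resampled if all-zero) and planted fluxes uniform on [0, 10].
    The requested numbers of input and output boundary reactions then
    absorb each metabolite's net imbalance: supply needs are distributed
    round-robin over the inputs (as positive coefficients at planted flux
    1), surpluses over the outputs.  Surplus boundary reactions touch the
    first metabolite at planted flux 0 so the reaction count is exact.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_metabolites, spec.n_reactions
    n_internal = n - spec.n_inputs - spec.n_outputs
    met_ids = [f"M{i}" for i in range(m)]
    metabolites = [
        Metabolite(id=mid, name=mid, compartment="cytosol", is_currency=(i == 0))
        for i, mid in enumerate(met_ids)
    ]

    internal: list[Reaction] = []
    S_int = np.zeros((m, n_internal))
    for j in range(n_internal):
        while True:
            mask = rng.random(m) < spec.density
            if mask.any():
                break
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=m) * mask
        S_int[:, j] = coeffs
        internal.append(
            Reaction(
                id=f"R{j}",
                name=f"internal reaction {j}",
                stoichiometry={
                    met_ids[i]: float(coeffs[i]) for i in range(m) if coeffs[i]
                },
                boundary_kind="internal",
            )
        )
    # Dyadic-rational planted fluxes (multiples of 1/64 on [0, 10]) keep all
    # stoichiometric sums exact in binary floating point, so S·v* is zero
    # bit-for-bit irrespective of summation order.
    v_int = rng.integers(0, 641, size=n_internal) / 64.0

    # Net imbalance of the internal block; boundary reactions absorb it.
    d = S_int @ v_int if n_internal else np.zeros(m)
    supply = np.where(d < 0, -d, 0.0)
    surplus = np.where(d > 0, d, 0.0)
    if not supply.any() and not surplus.any():
        supply[0] = surplus[0] = 1.0  # token flow-through keeps boundaries real

    def _distribute(needs: np.ndarray, count: int, make_input: bool):
        buckets: list[dict[str, float]] = [dict() for _ in range(count)]
        sign = 1.0 if make_input else -1.0
        for pos, i in enumerate(i for i in range(m) if needs[i] > 0):
            buckets[pos % count][met_ids[i]] = sign * float(needs[i])
        reactions, fluxes = [], []
        for k, stoich in enumerate(buckets):
            fluxes.append(1.0 if stoich else 0.0)
            if not stoich:  # spare boundary reaction, planted at zero flux
                stoich = {met_ids[0]: sign}
            prefix = "IN" if make_input else "OUT"
            label = None if make_input else _SINK_LABELS[k % len(_SINK_LABELS)]
            reactions.append(
                Reaction(
                    id=f"{prefix}{k}",
                    name=f"{'input' if make_input else 'output'} {k}",
                    stoichiometry=stoich,
                    boundary_kind="input" if make_input else "output",
                    groups=frozenset([label] if label else []),
                )
            )
        return reactions, fluxes

    inputs, v_in = _distribute(supply, spec.n_inputs, make_input=True)
    outputs, v_out = _distribute(surplus, spec.n_outputs, make_input=False)

    reactions = internal + inputs + outputs
    v_star = np.concatenate([v_int, np.array(v_in), np.array(v_out)])
    slack = spec.bound_slack
    bounded = [
        Reaction(
            id=r.id,
            name=r.name,
            stoichiometry=r.stoichiometry,
            lower_bound=max(0.0, float(v) - slack),
            upper_bound=float(v) + slack,
            boundary_kind=r.boundary_kind,
            speed_tag=r.speed_tag,
            groups=r.groups,
        )
        for r, v in zip(reactions, v_star)
    ]
    model = CellModel(metabolites, bounded, provenance="synthetic")
    planted = {r.id: float(v) for r, v in zip(bounded, v_star)}
    return PlantedNetwork(model, planted)


class NeuronlikeNetwork(NamedTuple):
    model: CellModel
    groups: FluxGroups
    window_input_id: str
    window: tuple[float, float]


def generate_neuronlike_network(seed: int = 0) -> NeuronlikeNetwork:
    """Mid-size network shaped like the neuronal model, with a known window.

    The network (~30 reactions) has currency metabolites, sinks tagged with
    all five apoptosis/degradation group labels plus ROS and aggregation
    groups, and a designated substrate input ``SUBST_IN`` whose only
    consumer carries bounds (a, b): pinning the input at value v admits a
    steady state iff a ≤ v ≤ b, so a step-1 pinned scan must recover the
    window exactly.  a and b are integers derived from the seed and are
    returned.  A lysosomal bypass guarantees a zero-apoptosis steady state,
    so minimal-apoptosis solutions report apoptosis 0.
    """
    a = float(10 + seed % 5)
    b = float(40 + seed % 7)
    M = Metabolite
    metabolites = [
        M("SUB_c", "window substrate", "cytosol"),
        M("PRD_c", "substrate product", "cytosol"),
        M("ASYN_c", f"{ALPHA_SYN} (monomeric)", "cytosol"),
        M("AGG_c", f"{ALPHA_SYN} aggregate", "cytosol"),
        M("ROS_c", "reactive oxygen species", "cytosol"),
        M("PROT_c", "functional protein", "cytosol"),
        M("DPROT_c", "damaged protein", "cytosol"),
        M("MITO_m", "functional mitochondrion", "mitochondrion"),
        M("DMITO_m", "damaged mitochondrion", "mitochondrion"),
        M("CYTC_c", "released cytochrome C", "cytosol"),
        M("O2", "O2", "cytosol", is_currency=True),
        M("H2O", "H2O", "cytosol", is_currency=True),
        M("NADH", "NADH", "cytosol", is_currency=True),
        M("NAD", "NAD+", "cytosol", is_currency=True),
        M("ATP", "ATP", "cytosol", is_currency=True),
        M("ADP", "ADP+Pi", "cytosol", is_currency=True),
    ]
    R = Reaction
    reactions = [
        R("SUBST_IN", "substrate input", {"SUB_c": 1}, boundary_kind="input",
          upper_bound=200.0),
        R("SubstConversion", "obligatory substrate conversion",
          {"SUB_c": -1, "ATP": -1, "PRD_c": 1, "ADP": 1},
          lower_bound=a, upper_bound=b),
        R("PRD_OUT", "product export", {"PRD_c": -1}, boundary_kind="output",
          upper_bound=200.0),
        R("ASYN_IN", f"{ALPHA_SYN} input", {"ASYN_c": 1}, boundary_kind="input"),
        R("O2_IN", "O2 input", {"O2": 1}, boundary_kind="input", upper_bound=200.0),
        R("NADH_IN", "NADH input", {"NADH": 1}, boundary_kind="input",
          upper_bound=200.0),
        R("ATP_IN", "ATP input", {"ATP": 1}, boundary_kind="input",
          upper_bound=200.0),
        R("ADP_OUT", "ADP+Pi output", {"ADP": -1}, boundary_kind="output",
          upper_bound=200.0),
        R("H2O_OUT", "H2O output", {"H2O": -1}, boundary_kind="output",
          upper_bound=200.0),
        R("NAD_OUT", "NAD+ output", {"NAD": -1}, boundary_kind="output",
          upper_bound=200.0),
        R("Respiration", "respiration",
          {"NADH": -1, "O2": -1, "ADP": -1, "NAD": 1, "H2O": 1, "ATP": 1}),
        R("ComplexIROS", "ROS production by complex I",
          {"NADH": -1, "O2": -1, "NAD": 1, "ROS_c": 1}, upper_bound=30.0,
          groups=frozenset({"ROS production (mitochondria, complex I)"})),
        R("ROSDamageProtein", "ROS damage to proteins",
          {"ROS_c": -1, "PROT_c": -1, "DPROT_c": 1},
          groups=frozenset({"ROS damage (protein)"})),
        R("ROSDamageMito", "ROS damage to mitochondria",
          {"ROS_c": -1, "MITO_m": -1, "DMITO_m": 1},
          groups=frozenset({"ROS damage (mitochondria)"})),
        R("ROSElimination", "ROS scavenging",
          {"ROS_c": -1, "NADH": -1, "H2O": 1, "NAD": 1},
          groups=frozenset({"ROS elimination (DJ-1)"})),
        R("ProteinSynthesis", "protein synthesis",
          {"ATP": -1, "PROT_c": 1, "ADP": 1}),
        R("MitoBiogenesis", "mitochondrial biogenesis",
          {"PROT_c": -1, "ATP": -1, "MITO_m": 1, "ADP": 1}, upper_bound=30.0,
          groups=frozenset({"Biogenesis of mitochondria"})),
        R("Aggregation", f"{ALPHA_SYN} aggregation",
          {"ASYN_c": -1, "ROS_c": -1, "AGG_c": 1},
          groups=frozenset({f"{ALPHA_SYN} aggregation"})),
        R("ASYN_OUT", f"{ALPHA_SYN} export", {"ASYN_c": -1, "ATP": -1},
          boundary_kind="output",
          groups=frozenset({f"{ALPHA_SYN} output reaction"})),
        R("LysoAggDegradation", "lysosomal aggregate degradation",
          {"AGG_c": -1, "ATP": -1, "ADP": 1},
          groups=frozenset({"Degradation (lysosome)"})),
        R("LysoProteinDegradation", "lysosomal protein degradation",
          {"DPROT_c": -1, "ATP": -1, "ADP": 1},
          groups=frozenset({"Degradation (lysosome)"})),
        R("ProteasomeDegradation", "proteasomal degradation",
          {"DPROT_c": -1, "ATP": -1, "ADP": 1}, upper_bound=30.0,
          groups=frozenset({"Degradation (proteasome)"})),
        R("Mitophagy", "mitophagy", {"DMITO_m": -1, "ATP": -1, "ADP": 1},
          upper_bound=30.0, groups=frozenset({"Degradation (mitophagy)"})),
        R("MitoRepair", "mitochondrial repair",
          {"DMITO_m": -1, "ATP": -1, "MITO_m": 1, "ADP": 1}),
        R("CytCRelease", "cytochrome C release", {"DMITO_m": -1, "CYTC_c": 1}),
        R("Apoptosis_Mito_OUT", "mitochondria induced apoptosis",
          {"CYTC_c": -1}, boundary_kind="output",
          groups=frozenset({"Apoptosis (mitochondria)"})),
        R("Apoptosis_LB_OUT", "Lewy-body induced apoptosis", {"AGG_c": -1},
          boundary_kind="output", groups=frozenset({"Apoptosis (LBs)"})),
    ]
    model = CellModel(metabolites, reactions, provenance="synthetic")
    return NeuronlikeNetwork(
        model, groups_from_model(model), "SUBST_IN", (a, b)
    )


@dataclass(frozen=True)
class MicroFixture:
    """A tiny model with hand-derived expectations."""

    model: CellModel
    objective_reaction: str
    sense: str
    expected_status: str
    expected_optimum: float | None = None
    expected_fva: dict[str, tuple[float, float]] | None = None


def micro_fixtures() -> dict[str, MicroFixture]:
    """Named ≤6-reaction models with closed-form optima.

    chain
        ∅→A (0,10), A→∅ (0,10); the maximal throughput is the minimum of
        the bounds along the path, 10, and every flux is unique.
    diamond
        A reaches B through two parallel branches of capacity 10 each with
        the demand pinned at 10; the split is free, so each branch has FVA
        range (0, 10) while total throughput is fixed.
    infeasible
        An input pinned at 5 with no outlet for its product.
    unbounded
        A flow-through path with no finite upper bounds.
    """
    M, R = Metabolite, Reaction
    chain = CellModel(
        [M("A", "A")],
        [
            R("IN", "in", {"A": 1}, upper_bound=10.0, boundary_kind="input"),
            R("OUT", "out", {"A": -1}, upper_bound=10.0, boundary_kind="output"),
        ],
        provenance="synthetic",
    )
    diamond = CellModel(
        [M("A", "A"), M("B", "B")],
        [
            R("IN", "in", {"A": 1}, upper_bound=20.0, boundary_kind="input"),
            R("P1", "branch 1", {"A": -1, "B": 1}, upper_bound=10.0),
            R("P2", "branch 2", {"A": -1, "B": 1}, upper_bound=10.0),
            R("DEMAND", "demand", {"B": -1}, lower_bound=10.0, upper_bound=10.0,
              boundary_kind="output"),
        ],
        provenance="synthetic",
    )
    infeasible = CellModel(
        [M("A", "A"), M("B", "B")],
        [
            R("IN", "pinned input", {"A": 1}, lower_bound=5.0, upper_bound=5.0,
              boundary_kind="input"),
            R("B_OUT", "unused outlet", {"B": -1}, upper_bound=10.0,
              boundary_kind="output"),
        ],
        provenance="synthetic",
    )
    unbounded = CellModel(
        [M("A", "A")],
        [
            R("IN", "in", {"A": 1}, upper_bound=float("inf"), boundary_kind="input"),
            R("OUT", "out", {"A": -1}, upper_bound=float("inf"),
              boundary_kind="output"),
        ],
        provenance="synthetic",
    )
    return {
        "chain": MicroFixture(chain, "OUT", "maximize", "optimal", 10.0),
        "diamond": MicroFixture(
            diamond,
            "DEMAND",
            "maximize",
            "optimal",
            10.0,
            expected_fva={"P1": (0.0, 10.0), "P2": (0.0, 10.0)},
        ),
        "infeasible": MicroFixture(infeasible, "IN", "maximize", "infeasible"),
        "unbounded": MicroFixture(unbounded, "OUT", "maximize", "unbounded"),
    }
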