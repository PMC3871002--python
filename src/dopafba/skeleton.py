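"""Curated reconstruction of the dopaminergic nerve-cell network.

This is a documented ~50-reaction process network covering the cell's
functional sub-systems: dopamine (DA) synthesis from tyrosine via L-DOPA,
DA metabolism to homovanillic acid (with the four catechol-O-methyl
transferase / monoamine-oxidase reactions OMSynthesis1/2 and
HVASynthesis3/4), vesicular packaging, release and DAT re-uptake of DA;
MPTP import and its complex-I poisoning product MPP+; two apoptosis
initiation sinks (Lewy-body induced and cytochrome-C/mitochondria
induced); lysosomal, proteasomal and mitophagy degradation routes;
α-synuclein input, aggregation (DA- and ROS-driven), DJ-1 protection and
ATP-coupled export; ROS production by DA metabolism and by respiratory
complexes I/III, with protein/mitochondrion/DNA damage targets;
mitochondrial biogenesis and repair; and boundary exchange for the
molecular units of currency (O₂, H₂O, NAD⁺/NADH, Fe²⁺/Fe³⁺, ATP/ADP+Pi).

It is declared a *reconstruction*: the deposited 139-reaction network
exists only in its public repository entry, so this skeleton covers every
sub-system and every canonical flux group without claiming reaction-count
parity.  Its dopamine-pathway reference fluxes are curated choices on the
scale of the original kinetic study, selected so that the basic model is
feasible; the provenance field says ``curated-skeleton``.

All reactions are irreversible with policy bounds in µM·h⁻¹:
default (0, 100), slow (0, 30), and ±10 % around the reference flux for
the measured DA-pathway reactions (with the four documented zero
lower-bound overrides).
"""

from __future__ import annotations

from .network import (
    ALPHA_SYN,
    CellModel,
    FluxGroups,
    Metabolite,
    Reaction,
    apply_bounds_policy,
    groups_from_model,
)

__all__ = ["make_skeleton_model", "skeleton_groups", "skeleton_tag_table"]

_M = Metabolite

_METABOLITES = [
    _M("TYR_c", "L-tyrosine", "cytosol"),
    _M("LDOPA_c", "L-DOPA", "cytosol"),
    _M("DA_c", "dopamine", "cytosol"),
    _M("DA_v", "dopamine (vesicular)", "vesicle"),
    _M("DA_e", "dopamine (extracellular)", "extracellular"),
    _M("OMD_c", "3-methoxytyramine", "cytosol"),
    _M("HVA_c", "homovanillic acid", "cytosol"),
    _M("SAL_c", "salsolinol", "cytosol"),
    _M("ASYN_c", f"{ALPHA_SYN} (monomeric)", "cytosol"),
    _M("AGG_c", f"{ALPHA_SYN} aggregate (Lewy body)", "cytosol"),
    _M("ROS_c", "reactive oxygen species", "cytosol"),
    _M("PROT_c", "functional protein", "cytosol"),
    _M("DPROT_c", "damaged protein", "cytosol"),
    _M("UBPROT_c", "ubiquitinated damaged protein", "cytosol"),
    _M("DDNA_c", "damaged DNA", "cytosol"),
    _M("MITO_m", "functional mitochondrion", "mitochondrion"),
    _M("DMITO_m", "damaged mitochondrion", "mitochondrion"),
    _M("CYTC_c", "released cytochrome C", "cytosol"),
    _M("MPTP_e", "MPTP", "extracellular"),
    _M("MPP_c", "MPP+", "cytosol"),
    # molecular units of currency
    _M("O2", "O2", "cytosol", is_currency=True),
    _M("H2O", "H2O", "cytosol", is_currency=True),
    _M("NAD", "NAD+", "cytosol", is_currency=True),
    _M("NADH", "NADH", "cytosol", is_currency=True),
    _M("FE2", "Fe2+", "cytosol", is_currency=True),
    _M("FE3", "Fe3+", "cytosol", is_currency=True),
    _M("ATP", "ATP", "cytosol", is_currency=True),
    _M("ADP", "ADP+Pi", "cytosol", is_currency=True),
]


def _rxn(
    rid: str,
    name: str,
    stoich: dict[str, float],
    kind: str = "internal",
    speed: str = "default",
    ref: float | None = None,
    groups: tuple[str, ...] = (),
) -> Reaction:
    return Reaction(
        id=rid,
        name=name,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=100.0,  # placeholder; policy bounds applied below
        boundary_kind=kind,
        speed_tag=speed,
        best_reference_flux=ref,
        groups=frozenset(groups),
    )


_REACTIONS = [
    # --- dopamine synthesis, metabolism and transport (measured pathway) ---
    _rxn("TYR_IN", "tyrosine input", {"TYR_c": 1}, kind="input"),
    _rxn("THSynthesis", "tyrosine hydroxylase",
         {"TYR_c": -1, "O2": -1, "LDOPA_c": 1, "H2O": 1},
         speed="best_et_al", ref=2.0),
    _rxn("AADCSynthesis", "aromatic L-amino acid decarboxylase",
         {"LDOPA_c": -1, "DA_c": 1}, speed="best_et_al", ref=2.0),
    _rxn("OMSynthesis1", "COMT O-methylation of DA",
         {"DA_c": -1, "OMD_c": 1}, speed="best_et_al", ref=10.0),
    _rxn("OMSynthesis2", "COMT O-methylation of L-DOPA",
         {"LDOPA_c": -1, "OMD_c": 1}, speed="best_et_al", ref=10.0),
    _rxn("HVASynthesis3", "MAO oxidation of 3-methoxytyramine",
         {"OMD_c": -1, "O2": -1, "HVA_c": 1, "ROS_c": 1},
         speed="best_et_al", ref=10.0, groups=("ROS production (DA)",)),
    _rxn("HVASynthesis4", "MAO/COMT route from DA to HVA",
         {"DA_c": -1, "O2": -1, "HVA_c": 1, "ROS_c": 1},
         speed="best_et_al", ref=10.0, groups=("ROS production (DA)",)),
    _rxn("HVA_OUT", "homovanillic acid export", {"HVA_c": -1}, kind="output"),
    _rxn("SALSynthesis", "salsolinol formation", {"DA_c": -1, "SAL_c": 1},
         speed="slow"),
    _rxn("SAL_OUT", "salsolinol export", {"SAL_c": -1}, kind="output"),
    _rxn("VMATTransport", "vesicular monoamine transporter",
         {"DA_c": -1, "DA_v": 1}, speed="best_et_al", ref=1.0),
    _rxn("DARelease", "vesicular DA release",
         {"DA_v": -1, "DA_e": 1}, speed="best_et_al", ref=1.0),
    _rxn("DATUptake", "DAT re-uptake of DA",
         {"DA_e": -1, "DA_c": 1}, speed="best_et_al", ref=0.1),
    _rxn("DA_OUT", "extracellular DA clearance", {"DA_e": -1}, kind="output",
         speed="best_et_al", ref=0.8, groups=("Extracellular DA",)),
    _rxn("DAOxidation", "DA autoxidation",
         {"DA_c": -1, "O2": -1, "ROS_c": 1},
         speed="best_et_al", ref=1.0, groups=("ROS production (DA)",)),
    # --- alpha-synuclein handling ---
    _rxn("ASYN_IN", f"{ALPHA_SYN} input", {"ASYN_c": 1}, kind="input",
         speed="slow"),
    _rxn("DAASYNInteraction", f"DA-promoted {ALPHA_SYN} aggregation",
         {"DA_c": -1, "ASYN_c": -1, "AGG_c": 1},
         groups=(f"{ALPHA_SYN} aggregation",)),
    _rxn("ASYNAggregation", f"ROS-promoted {ALPHA_SYN} aggregation",
         {"ASYN_c": -1, "ROS_c": -1, "AGG_c": 1},
         groups=(f"{ALPHA_SYN} aggregation",)),
    _rxn("DJ1InhibitAggregation", f"DJ-1 chaperoning of {ALPHA_SYN}",
         {"ASYN_c": -1, "NADH": -1, "NAD": 1}, speed="slow",
         groups=(f"Inhibition of {ALPHA_SYN} aggregation by DJ-1",)),
    _rxn("ASYN_OUT", f"ATP-coupled {ALPHA_SYN} export",
         {"ASYN_c": -1, "ATP": -1}, kind="output",
         groups=(f"{ALPHA_SYN} output reaction",)),
    _rxn("AggToxicity", f"ROS production by {ALPHA_SYN} aggregates",
         {"AGG_c": -1, "O2": -1, "ROS_c": 1}, speed="slow",
         groups=(f"Toxic effect of {ALPHA_SYN} aggregates",)),
    _rxn("Apoptosis_LB_OUT", "Lewy-body induced apoptosis initiation",
         {"AGG_c": -1}, kind="output", groups=("Apoptosis (LBs)",)),
    _rxn("LysoAggDegradation", "lysosomal aggregate degradation",
         {"AGG_c": -1, "ATP": -1, "ADP": 1},
         groups=("Degradation (lysosome)",)),
    # --- oxidative stress ---
    _rxn("DJ1ROSElimination", "DJ-1 ROS scavenging",
         {"ROS_c": -1, "NADH": -1, "H2O": 1, "NAD": 1}, speed="slow",
         groups=("ROS elimination (DJ-1)",)),
    _rxn("ROSDamageProtein", "ROS damage to proteins",
         {"ROS_c": -1, "PROT_c": -1, "DPROT_c": 1},
         groups=("ROS damage (protein)",)),
    _rxn("ROSDamageMito", "ROS damage to mitochondria",
         {"ROS_c": -1, "MITO_m": -1, "DMITO_m": 1},
         groups=("ROS damage (mitochondria)",)),
    _rxn("ROSDamageDNA", "ROS damage to DNA",
         {"ROS_c": -1, "DDNA_c": 1}, speed="slow",
         groups=("ROS damage (DNA)",)),
    _rxn("DNARepair", "DNA repair", {"DDNA_c": -1, "ATP": -1, "ADP": 1}),
    _rxn("FentonReaction", "iron-catalyzed ROS formation",
         {"FE2": -1, "O2": -1, "FE3": 1, "ROS_c": 1}, speed="slow"),
    _rxn("FeReduction", "ferric iron reduction",
         {"FE3": -1, "NADH": -1, "FE2": 1, "NAD": 1}, speed="slow"),
    # --- proteostasis ---
    _rxn("ProteinSynthesis", "protein synthesis",
         {"ATP": -1, "PROT_c": 1, "ADP": 1}),
    _rxn("ParkinUbiquitylation", "Parkin ubiquitylation of damaged protein",
         {"DPROT_c": -1, "ATP": -1, "UBPROT_c": 1, "ADP": 1}),
    _rxn("ProteasomeDegradation", "proteasomal degradation",
         {"UBPROT_c": -1, "ATP": -1, "ADP": 1}, speed="slow",
         groups=("Degradation (proteasome)",)),
    _rxn("LysoProteinDegradation", "lysosomal protein degradation",
         {"DPROT_c": -1, "ATP": -1, "ADP": 1},
         groups=("Degradation (lysosome)",)),
    # --- mitochondria, respiration, quality control ---
    _rxn("Respiration", "respiratory chain ATP production",
         {"NADH": -1, "O2": -1, "ADP": -1, "NAD": 1, "H2O": 1, "ATP": 1}),
    _rxn("ComplexIROS", "ROS production by complex I",
         {"NADH": -1, "O2": -1, "NAD": 1, "ROS_c": 1}, speed="slow",
         groups=("ROS production (mitochondria, complex I)",)),
    _rxn("ComplexIIIROS", "ROS production by complex III",
         {"NADH": -1, "O2": -1, "NAD": 1, "ROS_c": 1},
         groups=("ROS production (mitochondria, complex III)",)),
    _rxn("MitoBiogenesis", "mitochondrial biogenesis",
         {"PROT_c": -1, "ATP": -1, "MITO_m": 1, "ADP": 1},
         groups=("Biogenesis of mitochondria",)),
    _rxn("MitoRepair", "molecular quality control (PINK1/Parkin/TRAP1)",
         {"DMITO_m": -1, "ATP": -1, "MITO_m": 1, "ADP": 1}, speed="slow"),
    _rxn("Mitophagy", "autophagic removal of damaged mitochondria",
         {"DMITO_m": -1, "ATP": -1, "ADP": 1}, speed="slow",
         groups=("Degradation (mitophagy)",)),
    _rxn("CytCRelease", "cytochrome C release by failing mitochondria",
         {"DMITO_m": -1, "CYTC_c": 1}),
    _rxn("Apoptosis_Mito_OUT", "mitochondria induced apoptosis initiation",
         {"CYTC_c": -1}, kind="output", groups=("Apoptosis (mitochondria)",)),
    # --- MPTP neurotoxin ---
    _rxn("MPTP_IN", "MPTP exposure", {"MPTP_e": 1}, kind="input"),
    _rxn("MPTPUptake", "DAT import and MAO-B conversion to MPP+",
         {"MPTP_e": -1, "MPP_c": 1}),
    _rxn("MPPComplexIInhibition", "complex I inhibition by MPP+",
         {"MPP_c": -1, "NADH": -1, "O2": -1, "NAD": 1, "ROS_c": 1},
         speed="slow", groups=("ROS production (mitochondria, complex I)",)),
    _rxn("MPPMitoDamage", "mitochondrial injury by MPP+",
         {"MPP_c": -1, "MITO_m": -1, "DMITO_m": 1}),
    # --- currency exchange ---
    _rxn("O2_IN", "O2 input", {"O2": 1}, kind="input"),
    _rxn("H2O_OUT", "H2O output", {"H2O": -1}, kind="output"),
    _rxn("NADH_IN", "NADH input", {"NADH": 1}, kind="input"),
    _rxn("NAD_OUT", "NAD+ output", {"NAD": -1}, kind="output"),
    _rxn("ATP_IN", "ATPase ATP input", {"ATP": 1}, kind="input"),
    _rxn("ATP_OUT", "ATP surplus export", {"ATP": -1}, kind="output"),
    _rxn("ADP_IN", "ADP+Pi input", {"ADP": 1}, kind="input"),
    _rxn("ADP_OUT", "ADP+Pi output", {"ADP": -1}, kind="output"),
    _rxn("FE2_IN", "Fe2+ input", {"FE2": 1}, kind="input"),
    _rxn("FE3_OUT", "Fe3+ output", {"FE3": -1}, kind="output"),
]


def make_skeleton_model(apply_policy: bool = True) -> CellModel:
    """Build the curated skeleton network.

    With ``apply_policy=True`` (default) the standard bound policy is
    applied so the model is ready for analysis; with ``False`` the
    placeholder (0, 100) bounds are kept and only the speed tags carry the
    bound information.
    """
    model = CellModel(
        list(_METABOLITES), list(_REACTIONS), provenance="curated-skeleton"
    )
    return apply_bounds_policy(model) if apply_policy else model


def skeleton_tag_table() -> dict[str, list[str]]:
    """Reaction-id → group-label table of the skeleton."""
    return {r.id: sorted(r.groups) for r in _REACTIONS if r.groups}


def skeleton_groups() -> FluxGroups:
    return groups_from_model(make_skeleton_model(apply_policy=False))
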