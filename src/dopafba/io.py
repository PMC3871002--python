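"""Model and result I/O.

Models are exchanged in two formats:

* SBML — read Level 2 or 3, write Level 3 Version 1 with the ``fbc``
  package carrying flux bounds.  Package-specific fields that SBML core
  has no slot for (speed tag, reference flux, group labels, boundary kind,
  currency flag) travel in a small custom annotation so that write→read
  round trips are lossless.  MIRIAM-style cross-reference annotations of
  foreign files are preserved verbatim in :class:`ModelDocument`.
* a TSV reaction-table dialect — one ``@metabolite`` line per species and
  one row per reaction with a human-readable stoichiometry column such as
  ``-1 DA_c, +1 DA_v``.

There is no network access anywhere: deposited model files are supplied as
local paths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping
from xml.sax.saxutils import quoteattr

import libsbml

from .errors import FormatError, ModelIntegrityError, SBMLParseError
from .network import (
    COMPARTMENTS,
    CellModel,
    Metabolite,
    Reaction,
    normalize_group_label,
)

__all__ = [
    "ModelDocument",
    "read_sbml_model",
    "write_sbml_model",
    "read_reaction_table",
    "write_reaction_table",
    "write_flux_table",
    "write_json_summary",
]

log = logging.getLogger(__name__)

_NS = "https://dopafba.invalid/ns"  # custom annotation namespace (non-resolvable)
_DEFAULT_RANGE = (0.0, 100.0)


@dataclass
class ModelDocument:
    """A loaded model plus the exchange-level metadata of its file."""

    model: CellModel
    sbml_level_version: str = "L3V1"
    annotations: Mapping[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _compartment_kind(raw: str) -> str:
    low = raw.lower()
    if low in COMPARTMENTS:
        return low
    for key, kind in (
        ("cyto", "cytosol"),
        ("mito", "mitochondrion"),
        ("vesic", "vesicle"),
        ("extra", "extracellular"),
        ("ext", "extracellular"),
        ("lyso", "lysosome"),
    ):
        if key in low:
            return kind
    return "cytosol"


def _extra_attrs(node) -> dict[str, str]:
    """Read our custom annotation attributes off an SBML element."""
    ann = node.getAnnotation()
    if ann is None:
        return {}
    for i in range(ann.getNumChildren()):
        child = ann.getChild(i)
        if child.getURI() == _NS:
            attrs = child.getAttributes()
            return {
                attrs.getName(j): attrs.getValue(j)
                for j in range(attrs.getLength())
            }
    return {}


def _set_extra(node, attrs: dict[str, str]) -> None:
    if not attrs:
        return
    parts = " ".join(f"{k}={quoteattr(v)}" for k, v in attrs.items())
    xml = f'<dopafba:extra xmlns:dopafba="{_NS}" {parts}/>'
    node.appendAnnotation(xml)


def _cv_resources(node) -> list[str]:
    out: list[str] = []
    for i in range(node.getNumCVTerms()):
        term = node.getCVTerm(i)
        for j in range(term.getNumResources()):
            out.append(term.getResourceURI(j))
    return out


def _read_bounds(model, rxn) -> tuple[float, float] | None:
    fbc = rxn.getPlugin("fbc")
    if fbc is not None:
        lo_id, hi_id = fbc.getLowerFluxBound(), fbc.getUpperFluxBound()
        if lo_id and hi_id:
            lo_p, hi_p = model.getParameter(lo_id), model.getParameter(hi_id)
            if lo_p is not None and hi_p is not None:
                return lo_p.getValue(), hi_p.getValue()
    law = rxn.getKineticLaw()
    if law is not None:  # legacy COBRA-style L2 encoding
        lo = hi = None
        for i in range(law.getNumParameters()):
            p = law.getParameter(i)
            if p.getId() == "LOWER_BOUND":
                lo = p.getValue()
            elif p.getId() == "UPPER_BOUND":
                hi = p.getValue()
        if lo is not None and hi is not None:
            return lo, hi
    return None


def read_sbml_model(source) -> ModelDocument:
    """Read SBML (L2/L3) from a path, bytes or binary stream.

    Species flagged ``boundaryCondition`` are dropped from the steady-state
    constraint (they vanish from the metabolite list and from reaction
    stoichiometries).  Reactions without explicit flux-bound constructs get
    the default (0, 100) µM·h⁻¹ range, with a logged warning.  Negative
    lower bounds are clamped to 0: the network representation is strictly
    irreversible.
    """
    if hasattr(source, "read"):
        data = source.read()
    elif isinstance(source, (bytes, bytearray)):
        data = source
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8", errors="replace")
    doc = libsbml.readSBMLFromString(data)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) or doc.getModel() is None:
        msgs = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLParseError("; ".join(msgs[:3]) or "no model element found")
    sm = doc.getModel()
    level_version = f"L{doc.getLevel()}V{doc.getVersion()}"

    annotations: dict[str, list[str]] = {}
    boundary_species: set[str] = set()
    metabolites: list[Metabolite] = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary_species.add(sp.getId())
            continue
        extras = _extra_attrs(sp)
        comp_obj = sm.getCompartment(sp.getCompartment())
        comp_raw = extras.get(
            "compartment",
            (comp_obj.getName() or comp_obj.getId()) if comp_obj else "cytosol",
        )
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=_compartment_kind(comp_raw),
                is_currency=extras.get("is_currency") == "1",
            )
        )
        res = _cv_resources(sp)
        if res:
            annotations[sp.getId()] = res

    reactions: list[Reaction] = []
    defaulted = 0
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            sid = ref.getSpecies()
            if sid in boundary_species:
                continue
            stoich[sid] = stoich.get(sid, 0.0) - (ref.getStoichiometry() or 1.0)
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            sid = ref.getSpecies()
            if sid in boundary_species:
                continue
            stoich[sid] = stoich.get(sid, 0.0) + (ref.getStoichiometry() or 1.0)
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich and rx.getNumReactants() + rx.getNumProducts() == 0:
            raise ModelIntegrityError(
                f"reaction {rx.getId()} has no stoichiometry"
            )
        extras = _extra_attrs(rx)
        if "lb" in extras and "ub" in extras:
            lb, ub = float(extras["lb"]), float(extras["ub"])
        else:
            b = _read_bounds(sm, rx)
            if b is None:
                lb, ub = _DEFAULT_RANGE
                defaulted += 1
            else:
                lb, ub = b
        if lb < 0:
            log.warning("reaction %s: clamping negative lower bound to 0", rx.getId())
            lb = 0.0
        if "boundary_kind" in extras:
            kind = extras["boundary_kind"]
        else:
            coeffs = stoich.values()
            if stoich and all(c > 0 for c in coeffs):
                kind = "input"
            elif stoich and all(c < 0 for c in coeffs):
                kind = "output"
            else:
                kind = "internal"
        ref_flux = extras.get("best_reference_flux")
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                boundary_kind=kind,
                speed_tag=extras.get("speed_tag", "default"),
                best_reference_flux=float(ref_flux) if ref_flux else None,
                groups=frozenset(
                    normalize_group_label(g)
                    for g in extras.get("groups", "").split(";")
                    if g
                ),
            )
        )
        res = _cv_resources(rx)
        if res:
            annotations[rx.getId()] = res
    if defaulted:
        log.warning(
            "%d reaction(s) carried no flux-bound construct; "
            "defaulted to (0, 100) µM·h⁻¹",
            defaulted,
        )
    extras = _extra_attrs(sm)
    provenance = extras.get("provenance", "deposited")
    cell = CellModel(metabolites, reactions, provenance=provenance)
    return ModelDocument(cell, sbml_level_version=level_version, annotations=annotations)


def write_sbml_model(doc: ModelDocument | CellModel, sink) -> None:
    """Write SBML L3V1 (+fbc flux bounds).  Deterministic for a fixed model."""
    model = doc.model if isinstance(doc, ModelDocument) else doc
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    sdoc = libsbml.SBMLDocument(ns)
    sdoc.setPackageRequired("fbc", False)
    sm = sdoc.createModel()
    sm.setId("cell_model")
    _set_extra(sm, {"provenance": model.provenance})
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    used_comps = sorted({m.compartment for m in model.metabolites}) or ["cytosol"]
    for comp in used_comps:
        c = sm.createCompartment()
        c.setId(comp)
        c.setName(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        extras = {"compartment": met.compartment}
        if met.is_currency:
            extras["is_currency"] = "1"
        _set_extra(sp, extras)

    for rxn in model.reactions:
        p_lo = sm.createParameter()
        p_lo.setId(f"{rxn.id}_lb")
        p_lo.setValue(rxn.lower_bound)
        p_lo.setConstant(True)
        p_hi = sm.createParameter()
        p_hi.setId(f"{rxn.id}_ub")
        p_hi.setValue(rxn.upper_bound)
        p_hi.setConstant(True)

        rx = sm.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name)
        rx.setReversible(False)
        rx.setFast(False)
        for met_id in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[met_id]
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        plug = rx.getPlugin("fbc")
        plug.setLowerFluxBound(p_lo.getId())
        plug.setUpperFluxBound(p_hi.getId())
        extras = {
            "boundary_kind": rxn.boundary_kind,
            "speed_tag": rxn.speed_tag,
            # full-precision copies: the parameter values above go through
            # the writer's shorter decimal formatting
            "lb": repr(rxn.lower_bound),
            "ub": repr(rxn.upper_bound),
        }
        if rxn.best_reference_flux is not None:
            extras["best_reference_flux"] = repr(rxn.best_reference_flux)
        if rxn.groups:
            extras["groups"] = ";".join(sorted(rxn.groups))
        _set_extra(rx, extras)

    text = libsbml.writeSBMLToString(sdoc)
    _write_text(sink, text)


# ---------------------------------------------------------------------------
# TSV reaction tables
# ---------------------------------------------------------------------------

_TSV_HEADER = [
    "id",
    "name",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "boundary_kind",
    "speed_tag",
    "best_reference_flux",
    "groups",
]


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def _stoich_to_text(stoich: Mapping[str, float]) -> str:
    parts = []
    for met_id in sorted(stoich):
        c = stoich[met_id]
        sign = "+" if c > 0 else "-"
        parts.append(f"{sign}{_fmt_num(abs(c))} {met_id}")
    return ", ".join(parts)


def _parse_stoich(text: str, line_no: int) -> dict[str, float]:
    stoich: dict[str, float] = {}
    text = text.strip()
    if not text:
        return stoich
    for token in text.split(","):
        bits = token.strip().split()
        if len(bits) != 2:
            raise FormatError(f"unparseable stoichiometry token {token.strip()!r}", line_no)
        try:
            coeff = float(bits[0])
        except ValueError as exc:
            raise FormatError(
                f"unparseable stoichiometry coefficient {bits[0]!r}", line_no
            ) from exc
        stoich[bits[1]] = stoich.get(bits[1], 0.0) + coeff
    return stoich


def write_reaction_table(model: CellModel, sink) -> None:
    """Write the TSV dialect (lossless, including metabolite metadata)."""
    model.validate()
    lines = [f"#provenance\t{model.provenance}"]
    for m in model.metabolites:
        lines.append(
            "\t".join(
                ["@metabolite", m.id, m.name, m.compartment, "1" if m.is_currency else "0"]
            )
        )
    lines.append("\t".join(_TSV_HEADER))
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    _stoich_to_text(r.stoichiometry),
                    _fmt_num(r.lower_bound),
                    _fmt_num(r.upper_bound),
                    r.boundary_kind,
                    r.speed_tag,
                    "" if r.best_reference_flux is None else _fmt_num(r.best_reference_flux),
                    ";".join(sorted(r.groups)),
                ]
            )
        )
    _write_text(sink, "\n".join(lines) + "\n")


def read_reaction_table(source) -> CellModel:
    """Read the TSV dialect from a path, string content or text stream."""
    text = _read_text(source)
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    seen_met: set[str] = set()
    seen_rxn: set[str] = set()
    provenance = "curated-skeleton"
    header_seen = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#provenance"):
            parts = line.split("\t")
            if len(parts) == 2:
                provenance = parts[1]
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if cells[0] == "@metabolite":
            if len(cells) != 5:
                raise FormatError("@metabolite line needs 5 fields", line_no)
            _, mid, name, comp, cur = cells
            if mid in seen_met:
                raise FormatError(f"duplicate metabolite id {mid!r}", line_no)
            seen_met.add(mid)
            metabolites.append(
                Metabolite(id=mid, name=name, compartment=comp, is_currency=cur == "1")
            )
            continue
        if not header_seen:
            if cells != _TSV_HEADER:
                raise FormatError(
                    f"expected header {_TSV_HEADER!r}, got {cells!r}", line_no
                )
            header_seen = True
            continue
        if len(cells) != len(_TSV_HEADER):
            raise FormatError(
                f"expected {len(_TSV_HEADER)} fields, got {len(cells)}", line_no
            )
        rid, name, stoich_txt, lb, ub, kind, tag, ref, groups_txt = cells
        if rid in seen_rxn:
            raise FormatError(f"duplicate reaction id {rid!r}", line_no)
        seen_rxn.add(rid)
        try:
            lb_v, ub_v = float(lb), float(ub)
        except ValueError as exc:
            raise FormatError(f"unparseable bound {lb!r}/{ub!r}", line_no) from exc
        reactions.append(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=_parse_stoich(stoich_txt, line_no),
                lower_bound=lb_v,
                upper_bound=ub_v,
                boundary_kind=kind,
                speed_tag=tag,
                best_reference_flux=float(ref) if ref else None,
                groups=frozenset(g for g in groups_txt.split(";") if g),
            )
        )
    if not header_seen:
        raise FormatError("no reaction header row found")
    return CellModel(metabolites, reactions, provenance=provenance)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_flux_table(result, sink) -> None:
    """Write an objective-suite or scan result as TSV (2-decimal fluxes).

    Suites become a group × objective grid in the canonical header order
    (maxApo, minApo, maxDeg, minDeg); scans become a long table with one
    row per (input value, group).
    """
    frame = result.to_frame()
    text = frame.to_csv(sep="\t", float_format="%.2f", index=hasattr(result, "values"))
    _write_text(sink, text)


def write_json_summary(summary: Mapping, sink) -> None:
    """Write a JSON summary (windows, onsets, objective values) full precision."""
    _write_text(sink, json.dumps(summary, indent=2, ensure_ascii=False, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stream helpers
# ---------------------------------------------------------------------------

def _write_text(sink, text: str) -> None:
    if hasattr(sink, "write"):
        try:
            sink.write(text)
        except TypeError:
            sink.write(text.encode("utf-8"))
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def _read_text(source) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode("utf-8") if isinstance(data, bytes) else data
    text = str(source)
    if "\n" in text or "\t" in text:
        return text
    with open(text, "r", encoding="utf-8") as fh:
        return fh.read()
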