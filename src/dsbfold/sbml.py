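"""Model export: SBML Level 3 XML and a human-readable reaction list.

The serializer emits a self-contained SBML Level 3 Version 2 core document
with one compartment (the periplasm), the substrate and enzyme species,
global parameters for the rate constants, and the ten reaction groups with
mass-action kinetic laws in MathML.  Substrate-oxidation and isomerase
branches are written as separate reactions per outcome so their stoichiometry
and branching fractions are explicit.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

from .disulfides import Category
from .model import CATS, DsbFoldingModel

__all__ = ["to_sbml", "to_reaction_text"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math_product(parent: ET.Element, *factors: str) -> None:
    math = ET.SubElement(parent, f"{{{MATHML_NS}}}math")
    if len(factors) == 1:
        ET.SubElement(math, f"{{{MATHML_NS}}}ci").text = f" {factors[0]} "
        return
    apply_ = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(apply_, f"{{{MATHML_NS}}}times")
    for factor in factors:
        ET.SubElement(apply_, f"{{{MATHML_NS}}}ci").text = f" {factor} "


def _reaction(
    lor: ET.Element,
    rid: str,
    reactants: dict[str, float],
    products: dict[str, float],
    rate_factors: tuple[str, ...],
) -> None:
    rxn = ET.SubElement(lor, "reaction", id=rid, reversible="false")
    if reactants:
        lof = ET.SubElement(rxn, "listOfReactants")
        for species, stoich in reactants.items():
            ET.SubElement(
                lof, "speciesReference", species=species,
                stoichiometry=repr(float(stoich)), constant="true",
            )
    if products:
        lop = ET.SubElement(rxn, "listOfProducts")
        for species, stoich in products.items():
            ET.SubElement(
                lop, "speciesReference", species=species,
                stoichiometry=repr(float(stoich)), constant="true",
            )
    law = ET.SubElement(rxn, "kineticLaw")
    _math_product(law, *rate_factors)


def to_sbml(model: DsbFoldingModel, model_id: str = "dsb_oxidative_folding") -> str:
    """Serialize the network as an SBML Level 3 Version 2 document."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", level="3", version="2")
    mdl = ET.SubElement(sbml, "model", id=model_id)

    loc = ET.SubElement(mdl, "listOfCompartments")
    ET.SubElement(loc, "compartment", id="periplasm", spatialDimensions="3",
                  size="1", constant="true")

    species = {}
    state = model.initial
    for cat in CATS:
        species[f"UF_{cat.value}"] = state.UF[cat]
        species[f"MFP_{cat.value}"] = state.MFP[cat]
        species[f"FP_{cat.value}"] = state.FP[cat]
    for name in ("DsbAo", "DsbAr", "DsbBo", "DsbBr", "DsbCGr", "DsbCGo", "DsbDr", "DsbDo"):
        species[name] = getattr(state, name)

    los = ET.SubElement(mdl, "listOfSpecies")
    for sid, amount in species.items():
        ET.SubElement(
            los, "species", id=sid, compartment="periplasm",
            initialAmount=repr(float(amount)), hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
        )

    params = model.params
    values = dict(zip(params.rate_names(), params.rate_vector()))
    for cat in CATS:
        values[f"v_syn_{cat.value}"] = params.v_syn[cat]
        values[f"p_correct_{cat.value}"] = params.p_correct[cat]
    values["f_futile"] = params.f_futile
    values["f_success"] = params.f_success
    values["f_reduce"] = params.f_reduce

    lop = ET.SubElement(mdl, "listOfParameters")
    for pid, value in values.items():
        ET.SubElement(lop, "parameter", id=pid, value=repr(float(value)), constant="true")
    # branching products of rate constants and fractions, precomputed as parameters
    for cat in (Category.CAT2, Category.CAT3):
        for frac in ("f_success", "f_futile", "f_reduce"):
            pid = f"k678_{cat.value}_{frac}"
            ET.SubElement(
                lop, "parameter", id=pid,
                value=repr(float(values[f"k678_{cat.value}"] * values[frac])),
                constant="true",
            )
    for cat in CATS:
        p = params.p_correct[cat]
        k = values[f"k45_{cat.value}"]
        ET.SubElement(lop, "parameter", id=f"k4_{cat.value}",
                      value=repr(float(k * p)), constant="true")
        ET.SubElement(lop, "parameter", id=f"k5_{cat.value}",
                      value=repr(float(k * (1.0 - p))), constant="true")

    lor = ET.SubElement(mdl, "listOfReactions")
    for cat in CATS:
        c = cat.value
        _reaction(lor, f"R1_{c}", {}, {f"UF_{c}": 1}, (f"v_syn_{c}",))
    _reaction(lor, "R2", {"DsbBr": 1}, {"DsbBo": 1}, ("k2", "DsbBr"))
    _reaction(lor, "R3", {"DsbAr": 1, "DsbBo": 1}, {"DsbAo": 1, "DsbBr": 1},
              ("k3", "DsbAr", "DsbBo"))
    for cat in CATS:
        c = cat.value
        if params.p_correct[cat] > 0:
            _reaction(lor, f"R4_{c}", {f"UF_{c}": 1, "DsbAo": 1},
                      {f"FP_{c}": 1, "DsbAr": 1}, (f"k4_{c}", f"UF_{c}", "DsbAo"))
        if params.p_correct[cat] < 1:
            _reaction(lor, f"R5_{c}", {f"UF_{c}": 1, "DsbAo": 1},
                      {f"MFP_{c}": 1, "DsbAr": 1}, (f"k5_{c}", f"UF_{c}", "DsbAo"))
    for cat in (Category.CAT2, Category.CAT3):
        c = cat.value
        _reaction(lor, f"R6_{c}", {f"MFP_{c}": 1}, {f"FP_{c}": 1},
                  (f"k678_{c}_f_success", f"MFP_{c}", "DsbCGr"))
        _reaction(lor, f"R7_{c}", {f"MFP_{c}": 1}, {f"MFP_{c}": 1},
                  (f"k678_{c}_f_futile", f"MFP_{c}", "DsbCGr"))
        _reaction(lor, f"R8_{c}", {f"MFP_{c}": 1, "DsbCGr": 1},
                  {f"UF_{c}": 1, "DsbCGo": 1}, (f"k678_{c}_f_reduce", f"MFP_{c}", "DsbCGr"))
    _reaction(lor, "R9", {"DsbCGo": 1, "DsbDr": 1}, {"DsbCGr": 1, "DsbDo": 1},
              ("k9", "DsbCGo", "DsbDr"))
    _reaction(lor, "R10", {"DsbDo": 1}, {"DsbDr": 1}, ("k10", "DsbDo"))

    raw = ET.tostring(sbml, encoding="unicode")
    return minidom.parseString(raw).toprettyxml(indent="  ")


def to_reaction_text(model: DsbFoldingModel) -> str:
    """Human-readable reaction list with rate laws and parameter values."""
    p = model.params
    lines = ["# Oxidative folding reaction network (rates per minute)", ""]
    for cat in CATS:
        c = cat.value
        lines.append(f"R1_{c}:  -> UF_{c}            v = {p.v_syn[cat]:.6g}")
    lines.append(f"R2:   DsbBr -> DsbBo       v = k2*DsbBr, k2 = {p.k2:.6g}")
    lines.append(f"R3:   DsbAr + DsbBo -> DsbAo + DsbBr   v = k3*DsbAr*DsbBo, k3 = {p.k3:.6g}")
    for cat in CATS:
        c = cat.value
        pc = p.p_correct[cat]
        lines.append(
            f"R4/5_{c}: UF_{c} + DsbAo -> {pc:g} FP_{c} + {1-pc:g} MFP_{c} + DsbAr"
            f"   v = k45*UF*DsbAo, k45 = {p.k45[cat]:.6g}"
        )
    for cat in (Category.CAT2, Category.CAT3):
        c = cat.value
        lines.append(
            f"R6/7/8_{c}: MFP_{c} + DsbCGr -> {p.f_success:g} FP_{c} (R6) "
            f"+ {p.f_futile:g} MFP_{c} (R7, futile) "
            f"+ {p.f_reduce:g} (UF_{c} + DsbCGo) (R8)"
            f"   v = k678*MFP*DsbCGr, k678 = {p.k678[cat]:.6g}"
        )
    lines.append(f"R9:   DsbCGo + DsbDr -> DsbCGr + DsbDo   v = k9*DsbCGo*DsbDr, k9 = {p.k9:.6g}")
    lines.append(f"R10:  DsbDo -> DsbDr       v = k10*DsbDo, k10 = {p.k10:.6g}")
    lines.append("")
    lines.append("# Clamped boundary pools: quinone (folded into k2), thioredoxin (into k10)")
    return "\n".join(lines)
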