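"""SBML Level 3 Version 2 export / import for reaction networks.

Writes a self-contained subset of SBML: compartment, species (initial
concentrations, boundary condition flags), reactions with reactant /
product / modifier lists, mass-action or Michaelis-Menten kinetic laws as
MathML with local parameters (kf, kb, kcat, Km).  Cascade tags and
model-level parameter names ride along in a custom annotation namespace so
a round trip reproduces the network (and hence its simulation output)
exactly.

The reader accepts files produced by this writer (kinetic laws are
reconstructed from the local parameters and the reaction structure rather
than by evaluating arbitrary MathML); it is a deliberate subset, not a
general SBML consumer.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

from .network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    NetworkError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://mlcpath.invalid/annotations"

__all__ = ["to_sbml", "from_sbml", "write_sbml", "read_sbml"]


def _math(expr: ET.Element) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(expr)
    return math


def _ci(name: str) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _apply(op: str, *args: ET.Element) -> ET.Element:
    ap = ET.Element(f"{{{MATHML_NS}}}apply")
    ap.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        ap.append(a)
    return ap


def _cn(value: int) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}cn")
    el.set("type", "integer")
    el.text = f" {value} "
    return el


def _product_term(k: str, side: list[tuple[str, int]]) -> ET.Element:
    args = [_ci(k)]
    for sp, coef in side:
        args.append(_ci(sp) if coef == 1 else _apply("power", _ci(sp),
                                                     _cn(coef)))
    if len(args) == 1:
        return args[0]
    return _apply("times", *args)


def _kinetic_math(r: Reaction) -> ET.Element:
    rl = r.rate_law
    if rl.form == MICHAELIS_MENTEN:
        sub = r.reactants[0][0]
        num = _apply("times", _ci("kcat"), _ci(r.enzyme), _ci(sub))
        den = _apply("plus", _ci("Km"), _ci(sub))
        return _apply("divide", num, den)
    fwd = _product_term("kf", r.reactants)
    if rl.form == MASS_ACTION_IRREVERSIBLE:
        return fwd
    return _apply("minus", fwd, _product_term("kb", r.products))


def to_sbml(net: ReactionNetwork, model_id: str = "mlcpath_model") -> str:
    """Serialize a network to an SBML L3V2 document (string)."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("mlcpath", ANNOT_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml",
                      {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": model_id})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true",
                   "spatialDimensions": "3"})
    sps = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        ET.SubElement(sps, f"{{{SBML_NS}}}species", {
            "id": s.id,
            "name": s.display_name,
            "compartment": "cell",
            "initialConcentration": repr(float(s.initial_concentration)),
            "boundaryCondition": "true" if s.is_boundary else "false",
            "hasOnlySubstanceUnits": "false",
            "constant": "false",
        })
    rxns = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in net.reactions:
        rx = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction", {
            "id": r.id,
            "reversible": (
                "true" if r.rate_law.form == MASS_ACTION_REVERSIBLE
                else "false"
            ),
        })
        meta = {"tags": sorted(r.tags), "param_names": r.param_names,
                "form": r.rate_law.form}
        annot = ET.SubElement(rx, f"{{{SBML_NS}}}annotation")
        info = ET.SubElement(annot, f"{{{ANNOT_NS}}}reactionInfo")
        info.text = json.dumps(meta, sort_keys=True)
        if r.reactants:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp, coef in r.reactants:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(coef),
                               "constant": "true"})
        if r.products:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, coef in r.products:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(coef),
                               "constant": "true"})
        if r.enzyme:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            ET.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference",
                          {"species": r.enzyme})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math(_kinetic_math(r)))
        lp = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for name, value in r.rate_law.constants.items():
            ET.SubElement(lp, f"{{{SBML_NS}}}localParameter",
                          {"id": name, "value": repr(float(value))})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _side(rx: ET.Element, which: str) -> list[tuple[str, int]]:
    out = []
    lo = rx.find(f"{{{SBML_NS}}}listOf{which}")
    if lo is not None:
        for ref in lo.findall(f"{{{SBML_NS}}}speciesReference"):
            stoich = float(ref.get("stoichiometry", "1"))
            out.append((ref.get("species"), int(stoich)))
    return out


def from_sbml(text: str) -> ReactionNetwork:
    """Parse a document produced by :func:`to_sbml` back into a network."""
    root = ET.fromstring(text)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise NetworkError("no <model> element found")
    species = []
    for s in model.iter(f"{{{SBML_NS}}}species"):
        species.append(
            Species(
                id=s.get("id"),
                display_name=s.get("name", s.get("id")),
                initial_concentration=float(
                    s.get("initialConcentration", "0")
                ),
                is_boundary=s.get("boundaryCondition") == "true",
            )
        )
    reactions = []
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        meta = {"tags": [], "param_names": {}, "form": None}
        info = rx.find(
            f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}reactionInfo"
        )
        if info is not None and info.text:
            meta.update(json.loads(info.text))
        params = {}
        kl = rx.find(f"{{{SBML_NS}}}kineticLaw")
        if kl is not None:
            for lp in kl.iter(f"{{{SBML_NS}}}localParameter"):
                params[lp.get("id")] = float(lp.get("value"))
        form = meta["form"]
        if form is None:
            if "kcat" in params:
                form = MICHAELIS_MENTEN
            elif rx.get("reversible") == "true":
                form = MASS_ACTION_REVERSIBLE
            else:
                form = MASS_ACTION_IRREVERSIBLE
        rl = RateLaw(
            form=form,
            kf=params.get("kf", 0.0),
            kb=params.get("kb", 0.0),
            kcat=params.get("kcat", 0.0),
            Km=params.get("Km"),
        )
        enzyme = None
        mod = rx.find(
            f"{{{SBML_NS}}}listOfModifiers/"
            f"{{{SBML_NS}}}modifierSpeciesReference"
        )
        if mod is not None:
            enzyme = mod.get("species")
        reactions.append(
            Reaction(
                id=rx.get("id"),
                reactants=_side(rx, "Reactants"),
                products=_side(rx, "Products"),
                enzyme=enzyme,
                rate_law=rl,
                tags=frozenset(meta["tags"]),
                param_names=dict(meta["param_names"]),
            )
        )
    return ReactionNetwork(species, reactions)


def write_sbml(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_sbml(net))


def read_sbml(path) -> ReactionNetwork:
    with open(path) as fh:
        return from_sbml(fh.read())
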