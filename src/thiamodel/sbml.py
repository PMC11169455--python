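"""SBML Level 3 Version 2 export/import for pathway models.

A deliberately small SBML layer covering exactly the constructs this
package's models use: compartments, species with initial concentrations and
boundary conditions, reactions with stoichiometries, and kinetic laws written
as MathML with local parameters.  The rate-law type and its ordered substrate
list are additionally recorded in a package annotation so the import side can
reconstruct each :class:`~thiamodel.model.KineticLaw` without re-deriving it
from MathML; files are nevertheless valid SBML readable by COPASI-class
tools.  Round-trips preserve counts, stoichiometry, law types and parameter
values exactly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .model import KineticLaw, Metabolite, PathwayModel, Reaction

__all__ = ["export_sbml", "import_sbml", "SBMLError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:thiamodel:kinetic-law"


class SBMLError(ValueError):
    """Parse failure or an SBML construct this layer does not support."""


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# -- MathML builders --------------------------------------------------------

def _ci(parent: ET.Element, name: str) -> None:
    e = ET.SubElement(parent, _q("ci", MATHML_NS))
    e.text = f" {name} "


def _apply(parent: ET.Element, op: str) -> ET.Element:
    a = ET.SubElement(parent, _q("apply", MATHML_NS))
    ET.SubElement(a, _q(op, MATHML_NS))
    return a


def _law_mathml(math: ET.Element, law: KineticLaw) -> None:
    t = law.law_type
    subs = law.substrate_ids
    if t == "MM1":
        div = _apply(math, "divide")
        num = _apply(div, "times")
        _ci(num, "vmax")
        _ci(num, subs[0])
        den = _apply(div, "plus")
        _ci(den, "km")
        _ci(den, subs[0])
    elif t == "MM2":
        div = _apply(math, "divide")
        num = _apply(div, "times")
        for n in ("vmax", subs[0], subs[1]):
            _ci(num, n)
        den = _apply(div, "times")
        for km, s in (("km_a", subs[0]), ("km_b", subs[1])):
            p = _apply(den, "plus")
            _ci(p, km)
            _ci(p, s)
    elif t == "MM2_ping_pong":
        div = _apply(math, "divide")
        num = _apply(div, "times")
        for n in ("vmax", subs[0], subs[1]):
            _ci(num, n)
        den = _apply(div, "plus")
        for pair in (("km_b", subs[0]), ("km_a", subs[1]), (subs[0], subs[1])):
            term = _apply(den, "times")
            for n in pair:
                _ci(term, n)
    elif t == "mass_action":
        if subs:
            times = _apply(math, "times")
            _ci(times, "k")
            for s in subs:
                _ci(times, s)
        else:
            _ci(math, "k")
    elif t == "constant_flux":
        _ci(math, "k")
    else:  # pragma: no cover
        raise SBMLError(f"cannot serialize law_type {t!r}")


# -- export -----------------------------------------------------------------

def export_sbml(model: PathwayModel, path: str | Path) -> Path:
    """Write *model* as an SBML L3V2 file; returns the path."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("tkl", ANNOT_NS)

    sbml = ET.Element(_q("sbml"), {"level": "3", "version": "2"})
    mdl = ET.SubElement(sbml, _q("model"), {"id": model.metadata.get("id", "thiamodel")})

    compartments = sorted({m.compartment for m in model.metabolites})
    loc = ET.SubElement(mdl, _q("listOfCompartments"))
    for comp in compartments:
        ET.SubElement(
            loc, _q("compartment"), {"id": comp, "constant": "true", "size": "1"}
        )

    los = ET.SubElement(mdl, _q("listOfSpecies"))
    for m in model.metabolites:
        ET.SubElement(
            los,
            _q("species"),
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "initialConcentration": repr(m.initial_concentration),
                "boundaryCondition": "true" if m.boundary else "false",
                "constant": "true" if m.boundary else "false",
                "hasOnlySubstanceUnits": "false",
            },
        )

    lor = ET.SubElement(mdl, _q("listOfReactions"))
    for rxn in model.reactions:
        r = ET.SubElement(
            lor,
            _q("reaction"),
            {
                "id": rxn.id,
                "name": rxn.enzyme_label,
                "reversible": "true" if rxn.reversible else "false",
            },
        )
        annot = ET.SubElement(r, _q("annotation"))
        law_meta = {
            "enzyme": rxn.enzyme_label,
            "needs_fba": "1" if rxn.needs_fba else "0",
        }
        if rxn.law is not None:
            law_meta["type"] = rxn.law.law_type
            law_meta["substrates"] = " ".join(rxn.law.substrate_ids)
        ET.SubElement(annot, _q("law", ANNOT_NS), law_meta)

        reactants = {m: -c for m, c in rxn.stoichiometry.items() if c < 0}
        products = {m: c for m, c in rxn.stoichiometry.items() if c > 0}
        if reactants:
            lr = ET.SubElement(r, _q("listOfReactants"))
            for met_id, coeff in reactants.items():
                ET.SubElement(
                    lr,
                    _q("speciesReference"),
                    {"species": met_id, "stoichiometry": repr(coeff), "constant": "true"},
                )
        if products:
            lp = ET.SubElement(r, _q("listOfProducts"))
            for met_id, coeff in products.items():
                ET.SubElement(
                    lp,
                    _q("speciesReference"),
                    {"species": met_id, "stoichiometry": repr(coeff), "constant": "true"},
                )
        if rxn.law is not None:
            kl = ET.SubElement(r, _q("kineticLaw"))
            math = ET.SubElement(kl, _q("math", MATHML_NS))
            _law_mathml(math, rxn.law)
            lolp = ET.SubElement(kl, _q("listOfLocalParameters"))
            for name, value in rxn.law.parameter_items():
                ET.SubElement(
                    lolp, _q("localParameter"), {"id": name, "value": repr(value)}
                )

    path = Path(path)
    ET.indent(sbml)
    ET.ElementTree(sbml).write(path, xml_declaration=True, encoding="utf-8")
    return path


# -- import -----------------------------------------------------------------

def import_sbml(path: str | Path) -> PathwayModel:
    """Read an SBML L3 file written by :func:`export_sbml` (or equivalent).

    Kinetic laws are reconstructed from the package annotation plus the local
    parameters.  A reaction with a kinetic law but no recognizable law
    annotation is an unsupported rate-law form and raises :class:`SBMLError`.
    """
    path = Path(path)
    if not path.exists():
        raise SBMLError(f"SBML file not found: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SBMLError(f"{path}: XML parse failure: {exc}") from exc
    root = tree.getroot()
    mdl = root.find(_q("model"))
    if mdl is None:
        raise SBMLError(f"{path}: no <model> element")

    metabolites = []
    for sp in mdl.iter(_q("species")):
        metabolites.append(
            Metabolite(
                id=sp.get("id"),
                name=sp.get("name", ""),
                compartment=sp.get("compartment", "cytosol"),
                initial_concentration=float(sp.get("initialConcentration", "0")),
                boundary=sp.get("boundaryCondition", "false") == "true",
            )
        )

    reactions = []
    for r in mdl.iter(_q("reaction")):
        stoich: dict[str, float] = {}
        for lst, sign in ((_q("listOfReactants"), -1.0), (_q("listOfProducts"), 1.0)):
            holder = r.find(lst)
            if holder is None:
                continue
            for ref in holder.iter(_q("speciesReference")):
                met = ref.get("species")
                stoich[met] = stoich.get(met, 0.0) + sign * float(
                    ref.get("stoichiometry", "1")
                )

        law_el = None
        annot = r.find(_q("annotation"))
        if annot is not None:
            law_el = annot.find(_q("law", ANNOT_NS))
        needs_fba = law_el is not None and law_el.get("needs_fba") == "1"
        enzyme = (law_el.get("enzyme") if law_el is not None else None) or r.get(
            "name", r.get("id")
        )

        kl = r.find(_q("kineticLaw"))
        law = None
        if kl is not None:
            if law_el is None or law_el.get("type") is None:
                raise SBMLError(
                    f"{path}: reaction {r.get('id')}: unsupported rate-law form "
                    "(no kinetic-law annotation to reconstruct from)"
                )
            params: dict[str, float] = {}
            for lp in kl.iter(_q("localParameter")):
                params[lp.get("id")] = float(lp.get("value"))
            substrates = tuple((law_el.get("substrates") or "").split())
            law = KineticLaw(
                law_type=law_el.get("type"), substrate_ids=substrates, **params
            )
        elif not needs_fba:
            needs_fba = True  # no law, no annotation: treat as parameter gap

        reactions.append(
            Reaction(
                id=r.get("id"),
                enzyme_label=enzyme,
                stoichiometry=stoich,
                law=law,
                reversible=r.get("reversible", "false") == "true",
                needs_fba=needs_fba,
            )
        )

    return PathwayModel(metabolites, reactions, metadata={"source": str(path)})
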