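"""Minimal SBML Level 3 export: species, parameters and rate rules.

The network is exported as one rate rule per species whose MathML mirrors
the term grammar exactly; external inputs become non-constant parameters.
The writer emits plain SBML XML so no SBML library is required; output is
importable by standard tools (libSBML, COPASI) for interchange.
"""

from __future__ import annotations

from xml.etree import ElementTree as ET

from .model import ModelSpec, RateTerm

__all__ = ["export_sbml", "write_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _ci(parent: ET.Element, name: str) -> None:
    el = ET.SubElement(parent, f"{{{_MATHML_NS}}}ci")
    el.text = f" {name} "


def _cn(parent: ET.Element, value: float) -> None:
    el = ET.SubElement(parent, f"{{{_MATHML_NS}}}cn")
    el.text = f" {value} "


def _apply(parent: ET.Element, op: str) -> ET.Element:
    node = ET.SubElement(parent, f"{{{_MATHML_NS}}}apply")
    ET.SubElement(node, f"{{{_MATHML_NS}}}{op}")
    return node


def _one_plus_f_x(parent: ET.Element, f_name: str, species: str) -> None:
    plus = _apply(parent, "plus")
    _cn(plus, 1.0)
    times = _apply(plus, "times")
    _ci(times, f_name)
    _ci(times, species)


def _term_math(parent: ET.Element, term: RateTerm) -> None:
    if term.shape == "input_drive":
        times = _apply(parent, "times")
        _ci(times, term.rate_constant)
        _ci(times, term.driver)
        return
    if term.shape == "activation":
        times = _apply(parent, "times")
        _ci(times, term.rate_constant)
        for sp in term.factors:
            _ci(times, sp)
        for sp, f_name in term.accelerators:
            _one_plus_f_x(times, f_name, sp)
        return
    # decay: -(k * x * factors / prod(1 + F x))
    minus = _apply(parent, "minus")
    target: ET.Element = minus
    if term.decay_inhibitors:
        target = _apply(minus, "divide")
    times = _apply(target, "times")
    _ci(times, term.rate_constant)
    _ci(times, term.decay_of)
    for sp in term.factors:
        _ci(times, sp)
    if term.decay_inhibitors:
        if len(term.decay_inhibitors) == 1:
            sp, f_name = term.decay_inhibitors[0]
            _one_plus_f_x(target, f_name, sp)
        else:
            denom = _apply(target, "times")
            for sp, f_name in term.decay_inhibitors:
                _one_plus_f_x(denom, f_name, sp)


def export_sbml(model: ModelSpec, model_id: str = "er_stress_insulin") -> str:
    """Serialize the model to an SBML L3V2 document string."""
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("math", _MATHML_NS)
    sbml = ET.Element(
        f"{{{_SBML_NS}}}sbml", attrib={"level": "3", "version": "2"}
    )
    mdl = ET.SubElement(sbml, f"{{{_SBML_NS}}}model", attrib={"id": model_id})

    compartments = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(
        compartments,
        f"{{{_SBML_NS}}}compartment",
        attrib={"id": "cell", "constant": "true", "size": "1"},
    )

    species_list = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfSpecies")
    for sp in model.species:
        ET.SubElement(
            species_list,
            f"{{{_SBML_NS}}}species",
            attrib={
                "id": sp.name,
                "compartment": "cell",
                "initialAmount": str(sp.value),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    params = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfParameters")
    all_params = dict(model.parameters.rate_constants)
    all_params.update(model.parameters.binding_constants)
    for name, value in sorted(all_params.items()):
        ET.SubElement(
            params,
            f"{{{_SBML_NS}}}parameter",
            attrib={"id": name, "value": str(value), "constant": "true"},
        )
    for input_name in sorted(model.inputs):
        ET.SubElement(
            params,
            f"{{{_SBML_NS}}}parameter",
            attrib={"id": input_name, "value": "0", "constant": "false"},
        )

    rules = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfRules")
    for sp in model.species:
        rule = ET.SubElement(
            rules, f"{{{_SBML_NS}}}rateRule", attrib={"variable": sp.name}
        )
        math = ET.SubElement(rule, f"{{{_MATHML_NS}}}math")
        terms = model.terms[sp.name]
        if len(terms) == 1:
            _term_math(math, terms[0])
        else:
            total = _apply(math, "plus")
            for term in terms:
                _term_math(total, term)

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


def write_sbml(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(export_sbml(model))
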