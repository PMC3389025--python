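"""CellML document I/O and the uncertainty csymbol dialect.

Reads CellML 1.0/1.1 documents (single file, no ``<import>``), resolves
connections into canonical logical variables, extracts uncertainty
assertions written with the three ``http://www.cellml.org/uncertainty-1#``
csymbol operators, and classifies variables for ODE-IV simulation.
"""

from __future__ import annotations

import math as _math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Union

from . import mathml
from .errors import (AlgebraicLoopError, ModelError, UnderdeterminedModelError,
                     UnitsError)
from .mathml import (Apply, Constant, CsymbolApply, Environment, ExprNode,
                     Lambda, VariableRef, VectorLiteral, evaluate,
                     free_variables, parse_mathml, parse_xml)

CELLML_NAMESPACES = (mathml.CELLML_10_NS, mathml.CELLML_11_NS)
UNCERTAINTY_NS = "http://www.cellml.org/uncertainty-1#"

OP_WITH_DISTRIBUTION = UNCERTAINTY_NS + "uncertainParameterWithDistribution"
OP_FROM_DENSITY = UNCERTAINTY_NS + "distributionFromDensity"
OP_FROM_REALISATIONS = UNCERTAINTY_NS + "distributionFromRealisations"


# ---------------------------------------------------------------------------
# Document model
# ---------------------------------------------------------------------------

@dataclass
class VariableDecl:
    name: str
    units: str
    component: str
    initial_value: Optional[str] = None  # numeric literal or variable name

    @property
    def key(self) -> tuple:
        return (self.component, self.name)


@dataclass
class ComponentDef:
    name: str
    variables: dict = field(default_factory=dict)  # name -> VariableDecl


@dataclass
class DensitySpec:
    """A univariate p.d.f. given as a one-argument lambda."""

    pdf: Lambda

    def __post_init__(self):
        if not isinstance(self.pdf, Lambda):
            raise ModelError("distributionFromDensity takes a single argument "
                             "which must be a lambda expression")
        if len(self.pdf.bound_vars) != 1:
            raise ModelError(
                "density lambda must have exactly one bound variable, got "
                f"{len(self.pdf.bound_vars)}")


@dataclass
class RealisationsSpec:
    """An empirical distribution: scalars (k=1) or joint tuples (k>=2)."""

    realisations: tuple  # of float, or of tuple-of-float

    def __post_init__(self):
        if not self.realisations:
            raise ModelError("distributionFromRealisations vector is empty")
        first = self.realisations[0]
        if isinstance(first, tuple):
            k = len(first)
            for r in self.realisations:
                if not isinstance(r, tuple) or len(r) != k:
                    raise ModelError(
                        "realisation vector mixes scalars and tuples or has "
                        "inconsistent tuple lengths")
                if not all(_math.isfinite(v) for v in r):
                    raise ModelError("non-finite realisation value")
        else:
            for r in self.realisations:
                if isinstance(r, tuple):
                    raise ModelError(
                        "realisation vector mixes scalars and tuples")
                if not _math.isfinite(r):
                    raise ModelError("non-finite realisation value")

    @property
    def width(self) -> int:
        first = self.realisations[0]
        return len(first) if isinstance(first, tuple) else 1


@dataclass
class UncertaintyAssertion:
    targets: tuple  # of VariableRef, length >= 1
    spec: Union[DensitySpec, RealisationsSpec]
    component: Optional[str] = None  # component whose math declared it

    def __post_init__(self):
        if not self.targets:
            raise ModelError("uncertainty assertion with no target variable")
        if isinstance(self.spec, DensitySpec) and len(self.targets) != 1:
            raise ModelError(
                "distributionFromDensity cannot be attached to a vector of "
                "variables (multivariate densities are unsupported)")
        if isinstance(self.spec, RealisationsSpec):
            k = len(self.targets)
            if self.spec.width != k:
                raise ModelError(
                    f"realisation width {self.spec.width} does not match "
                    f"{k} target variable(s)")


@dataclass
class ModelDocument:
    name: str
    components: list = field(default_factory=list)    # of ComponentDef
    connections: list = field(default_factory=list)   # of ((c,v),(c,v))
    assignments: list = field(default_factory=list)   # of (lhs, rhs, component)
    uncertainty: list = field(default_factory=list)   # of UncertaintyAssertion
    units_definitions: list = field(default_factory=list)  # of units names
    _canonical: dict = field(default_factory=dict, repr=False)

    def canonical(self, key: tuple) -> tuple:
        return self._canonical.get(key, key)

    def variable(self, key: tuple) -> VariableDecl:
        comp, var = key
        for c in self.components:
            if c.name == comp and var in c.variables:
                return c.variables[var]
        raise ModelError(f"unknown variable {var!r} in component {comp!r}")

    def all_variable_keys(self) -> set:
        return {self.canonical(v.key)
                for c in self.components for v in c.variables.values()}


# ---------------------------------------------------------------------------
# Uncertainty extraction
# ---------------------------------------------------------------------------

def _const_value(expr: ExprNode, context: str) -> float:
    if free_variables(expr):
        raise ModelError(f"{context}: realisation elements must be constant "
                         "expressions with no free variables")
    return evaluate(expr, Environment())


def _parse_realisations(vec: ExprNode, context: str) -> RealisationsSpec:
    if not isinstance(vec, VectorLiteral):
        raise ModelError(
            f"{context}: distributionFromRealisations takes a single vector")
    elements = []
    for item in vec.elements:
        if isinstance(item, VectorLiteral):
            elements.append(tuple(_const_value(e, context)
                                  for e in item.elements))
        else:
            elements.append(_const_value(item, context))
    return RealisationsSpec(tuple(elements))


def _warn_probability_units(spec: DensitySpec):
    # the paper's units rule makes probabilities dimensionless; flag (but do
    # not reject) densities whose constants carry other units
    def constants(expr):
        if isinstance(expr, Constant):
            yield expr
        elif isinstance(expr, Apply):
            for o in expr.operands:
                yield from constants(o)
        elif isinstance(expr, Lambda):
            yield from constants(expr.body)
    offending = [c for c in constants(spec.pdf)
                 if c.units != "dimensionless"]
    if offending:
        warnings.warn(
            "density expression uses non-dimensionless constants "
            f"({sorted({c.units for c in offending})}); probabilities should "
            "be dimensionless", UserWarning, stacklevel=2)


def extract_uncertainty(math_exprs, component: Optional[str] = None) -> list:
    """Pull :class:`UncertaintyAssertion` records out of parsed math blocks.

    Recognizes top-level applies of ``uncertainParameterWithDistribution``;
    any other csymbol in the uncertainty namespace is an error.  Non-csymbol
    expressions are ignored (they are ordinary assignments).
    """
    assertions = []
    for expr in math_exprs:
        if not isinstance(expr, CsymbolApply):
            continue
        url = expr.definition_url
        if not url.startswith(UNCERTAINTY_NS):
            raise ModelError(f"unrecognised csymbol definitionURL {url!r}")
        if url != OP_WITH_DISTRIBUTION:
            suffix = url[len(UNCERTAINTY_NS):]
            raise ModelError(
                f"unknown uncertainty operator suffix {suffix!r} "
                "(top level must be uncertainParameterWithDistribution)")
        if len(expr.operands) != 2:
            raise ModelError(
                "uncertainParameterWithDistribution takes two arguments, got "
                f"{len(expr.operands)}")
        target_expr, dist_expr = expr.operands

        if isinstance(target_expr, VariableRef):
            targets = (target_expr,)
        elif (isinstance(target_expr, VectorLiteral)
              and target_expr.elements
              and all(isinstance(e, VariableRef)
                      for e in target_expr.elements)):
            targets = tuple(target_expr.elements)
        else:
            raise ModelError(
                "first argument of uncertainParameterWithDistribution must "
                "be a variable or a vector of variables")

        if not isinstance(dist_expr, CsymbolApply):
            raise ModelError(
                "second argument of uncertainParameterWithDistribution must "
                "be a distribution construct")
        durl = dist_expr.definition_url
        ctx = f"uncertainty for {', '.join(t.variable for t in targets)}"
        if durl == OP_FROM_DENSITY:
            if len(dist_expr.operands) != 1:
                raise ModelError(
                    "distributionFromDensity takes a single argument, got "
                    f"{len(dist_expr.operands)}")
            spec = DensitySpec(dist_expr.operands[0])
            _warn_probability_units(spec)
        elif durl == OP_FROM_REALISATIONS:
            if len(dist_expr.operands) != 1:
                raise ModelError(
                    "distributionFromRealisations takes a single argument, "
                    f"got {len(dist_expr.operands)}")
            spec = _parse_realisations(dist_expr.operands[0], ctx)
        elif durl.startswith(UNCERTAINTY_NS):
            raise ModelError(
                f"unknown uncertainty operator suffix "
                f"{durl[len(UNCERTAINTY_NS):]!r}")
        else:
            raise ModelError(f"unrecognised csymbol definitionURL {durl!r}")

        assertions.append(UncertaintyAssertion(targets, spec, component))
    return assertions


def assertion_to_expr(assertion: UncertaintyAssertion,
                      units: Optional[str] = None) -> CsymbolApply:
    """Serialize an assertion back into its csymbol apply form."""
    if len(assertion.targets) == 1:
        target_expr = assertion.targets[0]
    else:
        target_expr = VectorLiteral(assertion.targets)
    if isinstance(assertion.spec, DensitySpec):
        dist = CsymbolApply(OP_FROM_DENSITY, (assertion.spec.pdf,))
    else:
        u = units or "dimensionless"
        items = []
        for r in assertion.spec.realisations:
            if isinstance(r, tuple):
                items.append(VectorLiteral(
                    tuple(Constant(v, u) for v in r)))
            else:
                items.append(Constant(r, u))
        dist = CsymbolApply(OP_FROM_REALISATIONS, (VectorLiteral(tuple(items)),))
    return CsymbolApply(OP_WITH_DISTRIBUTION, (target_expr, dist))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _cellml_ns(root: ET.Element) -> str:
    tag = root.tag
    for ns in CELLML_NAMESPACES:
        if tag == f"{{{ns}}}model":
            return ns
    raise ModelError(f"not a CellML 1.0/1.1 model document (root {tag!r})")


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _rewrite_refs(expr: ExprNode, mapper) -> ExprNode:
    if isinstance(expr, VariableRef):
        comp, var = mapper(expr.key)
        return VariableRef(comp, var)
    if isinstance(expr, Apply):
        return Apply(expr.operator,
                     tuple(_rewrite_refs(o, mapper) for o in expr.operands))
    if isinstance(expr, mathml.Piecewise):
        cases = tuple((_rewrite_refs(c, mapper), _rewrite_refs(v, mapper))
                      for c, v in expr.cases)
        other = (_rewrite_refs(expr.otherwise, mapper)
                 if expr.otherwise is not None else None)
        return mathml.Piecewise(cases, other)
    if isinstance(expr, Lambda):
        bound = set(expr.bound_vars)

        def inner(key):
            return key if key[1] in bound else mapper(key)
        return Lambda(expr.bound_vars, _rewrite_refs(expr.body, inner))
    if isinstance(expr, VectorLiteral):
        return VectorLiteral(tuple(_rewrite_refs(e, mapper)
                                   for e in expr.elements))
    if isinstance(expr, CsymbolApply):
        return CsymbolApply(expr.definition_url,
                            tuple(_rewrite_refs(o, mapper)
                                  for o in expr.operands))
    return expr


def load_cellml(source) -> ModelDocument:
    """Load a CellML 1.0/1.1 document into a :class:`ModelDocument`.

    ``source`` is a path or an XML string.  Connections are resolved so that
    mapped variables collapse to one canonical logical variable; uncertainty
    csymbols are extracted from math blocks and kept apart from ordinary
    assignments.
    """
    root = parse_xml(source)
    ns = _cellml_ns(root)

    def c(tag):
        return f"{{{ns}}}{tag}"

    if root.find(c("import")) is not None:
        raise ModelError("CellML <import> elements are not supported "
                         "(single-document models only)")

    model = ModelDocument(name=root.get("name", "model"))
    for units_el in root.findall(c("units")):
        model.units_definitions.append(units_el.get("name"))

    raw_math = []  # (component name, list of ExprNode)
    for comp_el in root.findall(c("component")):
        cname = comp_el.get("name")
        if cname is None:
            raise ModelError("component without a name attribute")
        comp = ComponentDef(cname)
        for var_el in comp_el.findall(c("variable")):
            vname = var_el.get("name")
            vunits = var_el.get("units")
            if vname is None:
                raise ModelError(f"variable without name in component {cname!r}")
            if vunits is None:
                raise UnitsError(
                    f"variable {vname!r} in component {cname!r} has no units")
            if vname in comp.variables:
                raise ModelError(
                    f"variable {vname!r} declared twice in component {cname!r}")
            comp.variables[vname] = VariableDecl(
                vname, vunits, cname, var_el.get("initial_value"))
        exprs = []
        for math_el in comp_el.findall(f"{{{mathml.MATHML_NS}}}math"):
            for child in math_el:
                exprs.append(parse_mathml(child, cname))
        raw_math.append((cname, exprs))
        model.components.append(comp)

    declared = {v.key for comp in model.components
                for v in comp.variables.values()}

    uf = _UnionFind()
    for conn_el in root.findall(c("connection")):
        mc = conn_el.find(c("map_components"))
        if mc is None:
            raise ModelError("connection without map_components")
        c1, c2 = mc.get("component_1"), mc.get("component_2")
        for mv in conn_el.findall(c("map_variables")):
            v1, v2 = mv.get("variable_1"), mv.get("variable_2")
            k1, k2 = (c1, v1), (c2, v2)
            for k in (k1, k2):
                if k not in declared:
                    raise ModelError(
                        f"connection references undeclared variable "
                        f"{k[1]!r} in component {k[0]!r}")
            uf.union(k1, k2)
            model.connections.append((k1, k2))

    model._canonical = {k: uf.find(k) for k in declared}

    def mapper(key):
        if key not in declared:
            raise ModelError(
                f"reference to undeclared variable {key[1]!r} in component "
                f"{key[0]!r}")
        return model.canonical(key)

    assigned = {}
    for cname, exprs in raw_math:
        assertions = extract_uncertainty(exprs, cname)
        for a in assertions:
            spec = a.spec
            if isinstance(spec, DensitySpec):
                spec = DensitySpec(_rewrite_refs(spec.pdf, mapper))
            model.uncertainty.append(UncertaintyAssertion(
                tuple(VariableRef(*mapper(t.key)) for t in a.targets),
                spec, cname))
        for expr in exprs:
            if isinstance(expr, CsymbolApply):
                continue
            if not (isinstance(expr, Apply) and expr.operator == "eq"
                    and len(expr.operands) == 2):
                raise ModelError(
                    f"top-level math in component {cname!r} must be an "
                    "assignment (apply of <eq/>) or an uncertainty assertion")
            lhs, rhs = expr.operands
            lhs = _rewrite_refs(lhs, mapper)
            rhs = _rewrite_refs(rhs, mapper)
            if isinstance(lhs, VariableRef):
                key = lhs.key
            elif (isinstance(lhs, Apply) and lhs.operator == "diff"
                  and isinstance(lhs.operands[1], VariableRef)):
                key = ("d/dt",) + lhs.operands[1].key
            else:
                raise ModelError(
                    f"assignment left-hand side in component {cname!r} must "
                    "be a variable or a first derivative")
            if key in assigned:
                raise ModelError(
                    f"variable {key[-1]!r} is the target of two assignments")
            assigned[key] = True
            model.assignments.append((lhs, rhs, cname))

    targets_seen = set()
    for a in model.uncertainty:
        for t in a.targets:
            if t.key in targets_seen:
                raise ModelError(
                    f"variable {t.variable!r} targeted by two uncertainty "
                    "assertions")
            targets_seen.add(t.key)
            if t.key in assigned:
                raise ModelError(
                    f"variable {t.variable!r} has both an assignment and an "
                    "uncertainty assertion")
    return model


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_variables(model: ModelDocument) -> dict:
    """Partition variables into states/constants/uncertain/algebraic/bound.

    Raises :class:`UnderdeterminedModelError` for variables with no defining
    information and :class:`AlgebraicLoopError` on cyclic algebraic
    dependencies (implicit DAE systems are out of scope).
    """
    states, bound = set(), set()
    plain = {}  # canonical key -> rhs
    for lhs, rhs, _comp in model.assignments:
        if isinstance(lhs, Apply) and lhs.operator == "diff":
            bvar, state = lhs.operands
            states.add(model.canonical(state.key))
            bound.add(model.canonical(bvar.key))
        else:
            plain[model.canonical(lhs.key)] = rhs
    if len(bound) > 1:
        raise ModelError(
            f"derivatives taken with respect to {len(bound)} different bound "
            "variables; exactly one is supported")

    uncertain = set()
    for a in model.uncertainty:
        for t in a.targets:
            uncertain.add(model.canonical(t.key))

    constants, algebraic = set(), set()
    for key, rhs in plain.items():
        deps = {model.canonical(k) for k in free_variables(rhs)}
        if deps:
            algebraic.add(key)
        else:
            constants.add(key)

    all_keys = model.all_variable_keys()
    for key in all_keys:
        if key in states or key in bound or key in uncertain or key in plain:
            continue
        init = model.variable(key).initial_value
        if init is not None:
            constants.add(key)
        else:
            raise UnderdeterminedModelError(
                f"variable {key[1]!r} (component {key[0]!r}) has no "
                "assignment, initial value, or uncertainty declaration")

    # cycle check among algebraic assignments
    colour = {}

    def visit(key, stack):
        colour[key] = 1
        deps = {model.canonical(k) for k in free_variables(plain[key])}
        for d in deps:
            if d not in algebraic:
                continue
            if colour.get(d) == 1:
                cycle = " -> ".join(v for _, v in stack + [d])
                raise AlgebraicLoopError(
                    f"cyclic algebraic dependency: {cycle}")
            if colour.get(d) != 2:
                visit(d, stack + [d])
        colour[key] = 2

    for key in sorted(algebraic):
        if colour.get(key) != 2:
            visit(key, [key])

    return {"states": states, "constants": constants, "uncertain": uncertain,
            "algebraic": algebraic, "bound": bound}


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_cellml(model: ModelDocument, path) -> None:
    """Serialize a :class:`ModelDocument` to a CellML 1.1 file."""
    ns = mathml.CELLML_11_NS
    ET.register_namespace("cellml", ns)
    ET.register_namespace("m", mathml.MATHML_NS)
    root = ET.Element(f"{{{ns}}}model", {"name": model.name})

    for uname in model.units_definitions:
        units_el = ET.SubElement(root, f"{{{ns}}}units", {"name": uname})
        ET.SubElement(units_el, f"{{{ns}}}unit", {"units": "dimensionless"})

    for comp in model.components:
        comp_el = ET.SubElement(root, f"{{{ns}}}component",
                                {"name": comp.name})
        for var in comp.variables.values():
            attrs = {"name": var.name, "units": var.units}
            if var.initial_value is not None:
                attrs["initial_value"] = str(var.initial_value)
            ET.SubElement(comp_el, f"{{{ns}}}variable", attrs)
        exprs = [Apply("eq", (lhs, rhs))
                 for lhs, rhs, c in model.assignments if c == comp.name]
        for a in model.uncertainty:
            if (a.component or a.targets[0].component) == comp.name:
                units = None
                if isinstance(a.spec, RealisationsSpec) and len(a.targets) == 1:
                    units = model.variable(
                        model.canonical(a.targets[0].key)).units
                exprs.append(assertion_to_expr(a, units))
        if exprs:
            comp_el.append(mathml.wrap_math(exprs, units_ns=ns))

    for (c1, v1), (c2, v2) in model.connections:
        conn = ET.SubElement(root, f"{{{ns}}}connection")
        ET.SubElement(conn, f"{{{ns}}}map_components",
                      {"component_1": c1, "component_2": c2})
        ET.SubElement(conn, f"{{{ns}}}map_variables",
                      {"variable_1": v1, "variable_2": v2})

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="UTF-8", xml_declaration=True)
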