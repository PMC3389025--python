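"""Content MathML subset: parsing, serialization, and numerical evaluation.

The supported subset is what CellML models and the uncertainty operators
need: ``cn``/``ci`` leaves, ``apply`` with a fixed operator vocabulary,
``piecewise``, ``lambda``, ``vector``, and ``csymbol`` applications keyed
by their ``definitionURL``.  Expression trees are immutable dataclasses;
evaluation is a plain recursive interpreter, with :func:`compile_expr`
providing a closure-compiled fast path that must agree with it bit-for-bit.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .errors import EvaluationError, MathmlParseError, UnitsError

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
CELLML_10_NS = "http://www.cellml.org/cellml/1.0#"
CELLML_11_NS = "http://www.cellml.org/cellml/1.1#"

_LINE_KEY = "__sourceline__"


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    """A literal with a mandatory units annotation (possibly dimensionless)."""

    value: float
    units: str


@dataclass(frozen=True)
class VariableRef:
    component: Optional[str]
    variable: str

    @property
    def key(self) -> tuple:
        return (self.component, self.variable)


@dataclass(frozen=True)
class Apply:
    operator: str
    operands: tuple


@dataclass(frozen=True)
class Piecewise:
    cases: tuple  # of (condition ExprNode, value ExprNode)
    otherwise: Optional["ExprNode"] = None


@dataclass(frozen=True)
class Lambda:
    bound_vars: tuple  # of str
    body: "ExprNode"


@dataclass(frozen=True)
class VectorLiteral:
    elements: tuple


@dataclass(frozen=True)
class CsymbolApply:
    definition_url: str
    operands: tuple


ExprNode = Union[Constant, VariableRef, Apply, Piecewise, Lambda,
                 VectorLiteral, CsymbolApply]


# Operators recognised inside <apply>.  Values are (min_arity, max_arity).
SUPPORTED_OPERATORS = {
    "plus": (1, None), "minus": (1, 2), "times": (1, None), "divide": (2, 2),
    "power": (2, 2), "root": (1, 1), "exp": (1, 1), "ln": (1, 1),
    "log": (1, 1),
    "sin": (1, 1), "cos": (1, 1), "tan": (1, 1),
    "arcsin": (1, 1), "arccos": (1, 1), "arctan": (1, 1),
    "sinh": (1, 1), "cosh": (1, 1), "tanh": (1, 1),
    "eq": (2, None), "neq": (2, 2), "lt": (2, None), "leq": (2, None),
    "gt": (2, None), "geq": (2, None),
    "and": (1, None), "or": (1, None), "not": (1, 1), "xor": (1, None),
    "min": (1, None), "max": (1, None), "abs": (1, 1),
    "diff": (2, 2),
}

# <root> carries an optional <degree>; internally "root" operands are
# (degree, radicand) and "log" operands are (base, argument).

_NAMED_CONSTANTS = {
    "pi": math.pi,
    "exponentiale": math.e,
    "infinity": math.inf,
    "notanumber": math.nan,
    "true": 1.0,
    "false": 0.0,
}


class Environment:
    """Bindings for evaluation.

    Keys are either ``(component, variable)`` tuples for model variables or
    bare strings for lambda/bound variables.  Looking up an unbound name is
    always an error, never a default.
    """

    def __init__(self, bindings=None, derivatives=None):
        self.bindings = dict(bindings or {})
        self.derivatives = dict(derivatives or {})

    def bind(self, key, value) -> "Environment":
        child = Environment(self.bindings, self.derivatives)
        child.bindings[key] = float(value)
        return child

    def lookup(self, ref: VariableRef) -> float:
        b = self.bindings
        if ref.key in b:
            return b[ref.key]
        if ref.variable in b:
            return b[ref.variable]
        raise EvaluationError(
            f"unbound variable {ref.variable!r}"
            + (f" (component {ref.component!r})" if ref.component else ""))

    def lookup_derivative(self, state_key, bound_name) -> float:
        try:
            return self.derivatives[(state_key, bound_name)]
        except KeyError:
            raise EvaluationError(
                f"unbound derivative d{state_key}/d{bound_name}") from None


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _line(elem: ET.Element) -> str:
    line = elem.attrib.get(_LINE_KEY)
    return f" (line {line})" if line else ""


def _annotate_lines(root: ET.Element, text) -> None:
    """Best-effort: record each element's source line via an expat re-scan.

    Expat start events and ``root.iter()`` both run in document order, so a
    zip pairs them up without touching ET internals.
    """
    try:
        import xml.parsers.expat as expat
        lines = []
        p = expat.ParserCreate()
        p.StartElementHandler = \
            lambda *_: lines.append(p.CurrentLineNumber)
        p.Parse(text, True)
        for el, line in zip(root.iter(), lines):
            el.set(_LINE_KEY, str(line))
    except Exception:  # line numbers are advisory only
        pass


def parse_xml(source) -> ET.Element:
    """Parse an XML file or string, annotating elements with line numbers."""
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise MathmlParseError(f"malformed XML: {exc}") from exc
    _annotate_lines(root, text)
    return root


def _parse_cn(elem: ET.Element) -> Constant:
    units = (elem.get(f"{{{CELLML_10_NS}}}units")
             or elem.get(f"{{{CELLML_11_NS}}}units"))
    if units is None:
        raise UnitsError(
            f"<cn> without a cellml:units attribute{_line(elem)}: "
            f"{ET.tostring(elem, encoding='unicode')[:80]}")
    cn_type = elem.get("type", "real")
    text = (elem.text or "").strip()
    try:
        if cn_type == "e-notation":
            sep = list(elem)
            if len(sep) != 1 or _local(sep[0].tag) != "sep":
                raise MathmlParseError(
                    f"e-notation <cn> requires a single <sep>{_line(elem)}")
            mantissa = float(text)
            exponent = float((sep[0].tail or "").strip())
            value = mantissa * 10.0 ** exponent
        elif cn_type in ("real", "integer"):
            value = float(text)
        else:
            raise MathmlParseError(
                f"unsupported <cn> type {cn_type!r}{_line(elem)}")
        return Constant(value, units)
    except ValueError as exc:
        raise MathmlParseError(
            f"invalid numeric literal {text!r} in <cn>{_line(elem)}") from exc


def _parse_bvar(elem: ET.Element) -> str:
    children = [c for c in elem if _local(c.tag) != "degree"]
    if len(children) != 1 or _local(children[0].tag) != "ci":
        raise MathmlParseError(f"<bvar> must contain one <ci>{_line(elem)}")
    name = (children[0].text or "").strip()
    if not name:
        raise MathmlParseError(f"empty <ci> in <bvar>{_line(elem)}")
    return name


def _parse_apply(elem: ET.Element, component) -> ExprNode:
    children = list(elem)
    if not children:
        raise MathmlParseError(f"empty <apply>{_line(elem)}")
    op_elem, rest = children[0], children[1:]
    op = _local(op_elem.tag)

    if op == "csymbol":
        url = op_elem.get("definitionURL")
        if url is None:
            raise MathmlParseError(
                f"<csymbol> without definitionURL{_line(op_elem)}")
        return CsymbolApply(url, tuple(parse_mathml(c, component) for c in rest))

    if op == "diff":
        bvars = [c for c in rest if _local(c.tag) == "bvar"]
        args = [c for c in rest if _local(c.tag) != "bvar"]
        if len(bvars) != 1 or len(args) != 1:
            raise MathmlParseError(
                f"<diff> requires one <bvar> and one operand{_line(elem)}")
        bound = VariableRef(component, _parse_bvar(bvars[0]))
        return Apply("diff", (bound, parse_mathml(args[0], component)))

    if op == "root":
        degrees = [c for c in rest if _local(c.tag) == "degree"]
        args = [c for c in rest if _local(c.tag) != "degree"]
        if len(args) != 1 or len(degrees) > 1:
            raise MathmlParseError(f"malformed <root>{_line(elem)}")
        if degrees:
            deg_children = list(degrees[0])
            if len(deg_children) != 1:
                raise MathmlParseError(f"malformed <degree>{_line(elem)}")
            degree = parse_mathml(deg_children[0], component)
        else:
            degree = Constant(2.0, "dimensionless")
        return Apply("root", (degree, parse_mathml(args[0], component)))

    if op == "log":
        bases = [c for c in rest if _local(c.tag) == "logbase"]
        args = [c for c in rest if _local(c.tag) != "logbase"]
        if len(args) != 1 or len(bases) > 1:
            raise MathmlParseError(f"malformed <log>{_line(elem)}")
        if bases:
            base_children = list(bases[0])
            if len(base_children) != 1:
                raise MathmlParseError(f"malformed <logbase>{_line(elem)}")
            base = parse_mathml(base_children[0], component)
        else:
            base = Constant(10.0, "dimensionless")
        return Apply("log", (base, parse_mathml(args[0], component)))

    if op not in SUPPORTED_OPERATORS:
        raise MathmlParseError(
            f"unsupported operator <{op}>{_line(op_elem)}")
    lo, hi = SUPPORTED_OPERATORS[op]
    if len(rest) < lo or (hi is not None and len(rest) > hi):
        raise MathmlParseError(
            f"<{op}> applied to {len(rest)} operand(s){_line(elem)}")
    return Apply(op, tuple(parse_mathml(c, component) for c in rest))


def parse_mathml(elem: ET.Element, component: Optional[str] = None) -> ExprNode:
    """Parse a Content MathML subtree into an :class:`ExprNode`.

    ``component`` is the CellML component whose ``<math>`` block the
    fragment came from; ``<ci>`` references are resolved against it.
    """
    tag = _local(elem.tag)
    if tag == "math":
        children = list(elem)
        if len(children) != 1:
            raise MathmlParseError(
                f"<math> with {len(children)} children; expected exactly one"
                f"{_line(elem)}")
        return parse_mathml(children[0], component)
    if tag == "cn":
        return _parse_cn(elem)
    if tag == "ci":
        name = (elem.text or "").strip()
        if not name:
            raise MathmlParseError(f"empty <ci>{_line(elem)}")
        return VariableRef(component, name)
    if tag == "apply":
        return _parse_apply(elem, component)
    if tag == "piecewise":
        cases = []
        otherwise = None
        for child in elem:
            ctag = _local(child.tag)
            if ctag == "piece":
                parts = list(child)
                if len(parts) != 2:
                    raise MathmlParseError(
                        f"<piece> must have two children{_line(child)}")
                value = parse_mathml(parts[0], component)
                condition = parse_mathml(parts[1], component)
                cases.append((condition, value))
            elif ctag == "otherwise":
                parts = list(child)
                if len(parts) != 1 or otherwise is not None:
                    raise MathmlParseError(
                        f"malformed <otherwise>{_line(child)}")
                otherwise = parse_mathml(parts[0], component)
            else:
                raise MathmlParseError(
                    f"unexpected <{ctag}> in <piecewise>{_line(child)}")
        return Piecewise(tuple(cases), otherwise)
    if tag == "lambda":
        bvars = []
        body = None
        for child in elem:
            if _local(child.tag) == "bvar":
                bvars.append(_parse_bvar(child))
            else:
                if body is not None:
                    raise MathmlParseError(
                        f"<lambda> with multiple bodies{_line(elem)}")
                body = parse_mathml(child, component)
        if body is None or not bvars:
            raise MathmlParseError(
                f"<lambda> requires bound variables and a body{_line(elem)}")
        return Lambda(tuple(bvars), body)
    if tag == "vector":
        return VectorLiteral(tuple(parse_mathml(c, component) for c in elem))
    if tag == "csymbol":
        url = elem.get("definitionURL")
        if url is None:
            raise MathmlParseError(
                f"<csymbol> without definitionURL{_line(elem)}")
        return CsymbolApply(url, ())
    if tag in _NAMED_CONSTANTS:
        return Constant(_NAMED_CONSTANTS[tag], "dimensionless")
    raise MathmlParseError(f"unsupported MathML element <{tag}>{_line(elem)}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _chained(args, cmp) -> float:
    return 1.0 if all(cmp(a, b) for a, b in zip(args, args[1:])) else 0.0


def _apply_operator(op: str, args: list) -> float:
    try:
        if op == "plus":
            return math.fsum(args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "times":
            out = 1.0
            for a in args:
                out *= a
            return out
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "root":
            degree, radicand = args
            return radicand ** (1.0 / degree)
        if op == "exp":
            return math.exp(args[0])
        if op == "ln":
            return math.log(args[0])
        if op == "log":
            base, arg = args
            return math.log(arg, base)
        if op in ("sin", "cos", "tan", "arcsin", "arccos", "arctan",
                  "sinh", "cosh", "tanh"):
            fname = op.replace("arc", "a")
            return getattr(math, fname)(args[0])
        if op == "eq":
            return _chained(args, lambda a, b: a == b)
        if op == "neq":
            return 1.0 if args[0] != args[1] else 0.0
        if op == "lt":
            return _chained(args, lambda a, b: a < b)
        if op == "leq":
            return _chained(args, lambda a, b: a <= b)
        if op == "gt":
            return _chained(args, lambda a, b: a > b)
        if op == "geq":
            return _chained(args, lambda a, b: a >= b)
        if op == "and":
            return 1.0 if all(a != 0.0 for a in args) else 0.0
        if op == "or":
            return 1.0 if any(a != 0.0 for a in args) else 0.0
        if op == "not":
            return 1.0 if args[0] == 0.0 else 0.0
        if op == "xor":
            return 1.0 if sum(1 for a in args if a != 0.0) % 2 == 1 else 0.0
        if op == "min":
            return min(args)
        if op == "max":
            return max(args)
        if op == "abs":
            return abs(args[0])
    except (ValueError, ZeroDivisionError, OverflowError) as exc:
        raise EvaluationError(f"domain error in <{op}>: {exc}") from exc
    raise EvaluationError(f"operator <{op}> cannot be evaluated here")


def evaluate(expr: ExprNode, env: Environment) -> float:
    """Evaluate an expression to a real number.

    Relational and logical operators yield 1.0/0.0; piecewise conditions
    treat any nonzero value as true.  Lambdas and vectors are values, not
    scalars, and are rejected.
    """
    if isinstance(expr, Constant):
        return expr.value
    if isinstance(expr, VariableRef):
        return env.lookup(expr)
    if isinstance(expr, Apply):
        if expr.operator == "diff":
            bound, state = expr.operands
            return env.lookup_derivative(state.key, bound.variable)
        args = [evaluate(o, env) for o in expr.operands]
        return _apply_operator(expr.operator, args)
    if isinstance(expr, Piecewise):
        for condition, value in expr.cases:
            if evaluate(condition, env) != 0.0:
                return evaluate(value, env)
        if expr.otherwise is not None:
            return evaluate(expr.otherwise, env)
        raise EvaluationError("piecewise: no case matched and no otherwise")
    if isinstance(expr, (Lambda, VectorLiteral)):
        raise EvaluationError(
            f"{type(expr).__name__} is not a scalar expression")
    if isinstance(expr, CsymbolApply):
        raise EvaluationError(
            f"csymbol {expr.definition_url!r} cannot be evaluated numerically")
    raise TypeError(f"not an ExprNode: {expr!r}")


def apply_lambda(fn: Lambda, args, env: Optional[Environment] = None) -> float:
    """Apply a lambda to numeric arguments, with ``env`` visible to its body."""
    if len(args) != len(fn.bound_vars):
        raise EvaluationError(
            f"lambda of arity {len(fn.bound_vars)} applied to "
            f"{len(args)} argument(s)")
    inner = env or Environment()
    for name, value in zip(fn.bound_vars, args):
        inner = inner.bind(name, value)
    return evaluate(fn.body, inner)


def free_variables(expr: ExprNode, _bound=frozenset()) -> set:
    """Free ``(component, variable)`` pairs, excluding lambda-bound names."""
    if isinstance(expr, Constant):
        return set()
    if isinstance(expr, VariableRef):
        return set() if expr.variable in _bound else {expr.key}
    if isinstance(expr, Apply):
        if expr.operator == "diff":
            # the differentiation variable is bound by context, not free
            return free_variables(expr.operands[1], _bound)
        out = set()
        for o in expr.operands:
            out |= free_variables(o, _bound)
        return out
    if isinstance(expr, Piecewise):
        out = set()
        for condition, value in expr.cases:
            out |= free_variables(condition, _bound)
            out |= free_variables(value, _bound)
        if expr.otherwise is not None:
            out |= free_variables(expr.otherwise, _bound)
        return out
    if isinstance(expr, Lambda):
        return free_variables(expr.body, _bound | set(expr.bound_vars))
    if isinstance(expr, (VectorLiteral, CsymbolApply)):
        out = set()
        for o in (expr.elements if isinstance(expr, VectorLiteral)
                  else expr.operands):
            out |= free_variables(o, _bound)
        return out
    raise TypeError(f"not an ExprNode: {expr!r}")


# ---------------------------------------------------------------------------
# Closure compilation (fast path for quadrature / ODE right-hand sides)
# ---------------------------------------------------------------------------

def compile_expr(expr: ExprNode) -> Callable[[dict], float]:
    """Compile to a closure over a plain bindings dict.

    Must agree with :func:`evaluate` exactly (property-tested); used in hot
    loops where interpreter overhead matters.
    """
    if isinstance(expr, Constant):
        v = expr.value
        return lambda b: v
    if isinstance(expr, VariableRef):
        k1, k2 = expr.key, expr.variable

        def ref(b):
            if k1 in b:
                return b[k1]
            if k2 in b:
                return b[k2]
            raise EvaluationError(f"unbound variable {k2!r}")
        return ref
    if isinstance(expr, Apply):
        if expr.operator == "diff":
            raise EvaluationError("diff cannot appear in a compiled rhs")
        op = expr.operator
        fns = [compile_expr(o) for o in expr.operands]
        return lambda b: _apply_operator(op, [f(b) for f in fns])
    if isinstance(expr, Piecewise):
        case_fns = [(compile_expr(c), compile_expr(v)) for c, v in expr.cases]
        other_fn = (compile_expr(expr.otherwise)
                    if expr.otherwise is not None else None)

        def pw(b):
            for cond, val in case_fns:
                if cond(b) != 0.0:
                    return val(b)
            if other_fn is not None:
                return other_fn(b)
            raise EvaluationError("piecewise: no case matched and no otherwise")
        return pw
    raise EvaluationError(f"cannot compile {type(expr).__name__}")


def compile_lambda(fn: Lambda, base_bindings: Optional[dict] = None):
    """Compile a lambda into a fast ``f(*args) -> float`` callable."""
    body = compile_expr(fn.body)
    names = fn.bound_vars
    base = dict(base_bindings or {})

    def call(*args):
        if len(args) != len(names):
            raise EvaluationError(
                f"lambda of arity {len(names)} applied to {len(args)}")
        b = dict(base)
        for n, a in zip(names, args):
            b[n] = a
        return body(b)
    return call


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _format_number(value: float) -> str:
    if math.isfinite(value) and value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)


def to_element(expr: ExprNode, units_ns: str = CELLML_11_NS) -> ET.Element:
    """Serialize an :class:`ExprNode` back to a Content MathML element."""
    if isinstance(expr, Constant):
        if expr.value == math.pi and expr.units == "dimensionless":
            return ET.Element(_m("pi"))
        if expr.value == math.e and expr.units == "dimensionless":
            return ET.Element(_m("exponentiale"))
        el = ET.Element(_m("cn"), {f"{{{units_ns}}}units": expr.units})
        el.text = _format_number(expr.value)
        return el
    if isinstance(expr, VariableRef):
        el = ET.Element(_m("ci"))
        el.text = expr.variable
        return el
    if isinstance(expr, Apply):
        el = ET.Element(_m("apply"))
        if expr.operator == "diff":
            ET.SubElement(el, _m("diff"))
            bound, state = expr.operands
            bvar = ET.SubElement(el, _m("bvar"))
            ci = ET.SubElement(bvar, _m("ci"))
            ci.text = bound.variable
            el.append(to_element(state, units_ns))
            return el
        if expr.operator == "root":
            ET.SubElement(el, _m("root"))
            degree, radicand = expr.operands
            if degree != Constant(2.0, "dimensionless"):
                deg = ET.SubElement(el, _m("degree"))
                deg.append(to_element(degree, units_ns))
            el.append(to_element(radicand, units_ns))
            return el
        if expr.operator == "log":
            ET.SubElement(el, _m("log"))
            base, arg = expr.operands
            if base != Constant(10.0, "dimensionless"):
                lb = ET.SubElement(el, _m("logbase"))
                lb.append(to_element(base, units_ns))
            el.append(to_element(arg, units_ns))
            return el
        ET.SubElement(el, _m(expr.operator))
        for o in expr.operands:
            el.append(to_element(o, units_ns))
        return el
    if isinstance(expr, Piecewise):
        el = ET.Element(_m("piecewise"))
        for condition, value in expr.cases:
            piece = ET.SubElement(el, _m("piece"))
            piece.append(to_element(value, units_ns))
            piece.append(to_element(condition, units_ns))
        if expr.otherwise is not None:
            other = ET.SubElement(el, _m("otherwise"))
            other.append(to_element(expr.otherwise, units_ns))
        return el
    if isinstance(expr, Lambda):
        el = ET.Element(_m("lambda"))
        for name in expr.bound_vars:
            bvar = ET.SubElement(el, _m("bvar"))
            ci = ET.SubElement(bvar, _m("ci"))
            ci.text = name
        el.append(to_element(expr.body, units_ns))
        return el
    if isinstance(expr, VectorLiteral):
        el = ET.Element(_m("vector"))
        for item in expr.elements:
            el.append(to_element(item, units_ns))
        return el
    if isinstance(expr, CsymbolApply):
        el = ET.Element(_m("apply"))
        ET.SubElement(el, _m("csymbol"), {"definitionURL": expr.definition_url})
        for o in expr.operands:
            el.append(to_element(o, units_ns))
        return el
    raise TypeError(f"not an ExprNode: {expr!r}")


def wrap_math(exprs, units_ns: str = CELLML_11_NS) -> ET.Element:
    """Wrap expression trees in a single ``<math>`` element."""
    math_el = ET.Element(_m("math"))
    for expr in exprs:
        math_el.append(to_element(expr, units_ns))
    return math_el
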