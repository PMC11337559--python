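"""LL-XML pipeline documents: read, write, validate, render.

The lexicon-linked XML (LL-XML) format encodes an analysis pipeline as a
tree of ``Process`` elements, each carrying its OSIPI name (``value``
attribute) and lexicon code, with ``InputQuantity``, ``OutputQuantity``,
``Model`` and ``SetEqual`` children plus nested sub-processes.  A shipped
XSD (``data/llxml.xsd``) enforces the structural grammar; the semantic
rules that tie a document to the lexicon registry — name/code agreement,
section compatibility, units — live in :func:`validate_pipeline`.

Validation rule set
-------------------
R1  at least one top-level process
R2  only the allowed child element kinds, and a nested process must differ
    from its parent (different code)
R3  name (``value``) and ``code`` present on every process, quantity, model
R4  OSIPI name matches the registry entry for the code
R5  code resolves in the registry
R6  section compatibility: process codes in P/G/D, quantities in Q,
    models in M
R7  unit attribute present on every quantity and equal to the registry's
    OSIPI unit (SetEqual literals must match their left-hand quantity)
R8  optional ``type`` attribute is "free" or "fixed", on input quantities
    only
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

from lxml import etree

from .codes import LexiconCode, format_code, parse_code
from .errors import CodeParseError, LookupError_, PipelineParseError
from .registry import LexiconRegistry

NAMESPACE = "https://osipi.github.io/OSIPI_CAPLEX/llxml"
SCHEMA_FILENAME = "llxml.xsd"
_XSI = "http://www.w3.org/2001/XMLSchema-instance"

# single point of truth for element spellings, for easy re-mapping
TAGS = {
    "pipeline": "Pipeline",
    "process": "Process",
    "input": "InputQuantity",
    "output": "OutputQuantity",
    "model": "Model",
    "set_equal": "SetEqual",
    "quantity_ref": "Quantity",
    "literal": "Literal",
}
_Q = {key: f"{{{NAMESPACE}}}{tag}" for key, tag in TAGS.items()}


# ---------------------------------------------------------------------------
# document model

@dataclass(frozen=True)
class QuantityElement:
    """An InputQuantity or OutputQuantity element."""

    role: str  # input | output
    osipi_name: str
    code: LexiconCode | None
    unit: str | None
    instance: str | None = None
    fit_type: str | None = None      # free | fixed, inputs only
    numeric_value: float | None = None
    uncertainty: float | None = None


@dataclass(frozen=True)
class ModelElement:
    osipi_name: str
    code: LexiconCode | None
    instance: str | None = None


@dataclass(frozen=True)
class QuantityRef:
    code: LexiconCode
    osipi_name: str | None = None


@dataclass(frozen=True)
class Literal:
    value: float
    unit: str = ""


@dataclass(frozen=True)
class SetEqualStatement:
    left: QuantityRef
    right: QuantityRef | Literal


@dataclass(frozen=True)
class RawElement:
    """An element the format does not know; kept so the validator can
    report it (rule R2) instead of the reader crashing."""

    tag: str
    line: int | None = None


@dataclass(frozen=True)
class ProcessNode:
    osipi_name: str
    code: LexiconCode | None
    instance: str | None = None
    children: tuple = ()


@dataclass(frozen=True)
class PipelineDocument:
    """Ordered top-level processes plus namespace/schema metadata."""

    processes: tuple = ()
    namespace: str = NAMESPACE
    schema_location: str = SCHEMA_FILENAME


@dataclass
class ValidationReport:
    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, rule: str, location: str, message: str):
        self.violations.append((rule, location, message))

    def rules_fired(self) -> set[str]:
        return {rule for rule, _, _ in self.violations}

    def __str__(self) -> str:
        if self.valid:
            return "valid (0 violations)"
        lines = [f"invalid ({len(self.violations)} violation(s)):"]
        lines += [f"  {rule} at {loc}: {msg}" for rule, loc, msg in self.violations]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reading

def _schema() -> etree.XMLSchema:
    text = resources.files("caplex.data").joinpath(SCHEMA_FILENAME).read_bytes()
    return etree.XMLSchema(etree.parse(io.BytesIO(text)))


def _parse_optional_code(text: str | None, line: int | None) -> LexiconCode | None:
    if text is None or text == "":
        return None
    try:
        return parse_code(text)
    except CodeParseError as exc:
        raise PipelineParseError(f"bad lexicon code {text!r}: {exc}", line) from exc


def _float_attr(el, name: str) -> float | None:
    raw = el.get(name)
    return None if raw is None else float(raw)


def _read_quantity(el, role: str) -> QuantityElement:
    return QuantityElement(
        role=role,
        osipi_name=el.get("value", ""),
        code=_parse_optional_code(el.get("code"), el.sourceline),
        unit=el.get("unit"),
        instance=el.get("instance"),
        fit_type=el.get("type"),
        numeric_value=_float_attr(el, "numericValue"),
        uncertainty=_float_attr(el, "uncertainty"),
    )


def _read_quantity_ref(el) -> QuantityRef:
    code = _parse_optional_code(el.get("code"), el.sourceline)
    if code is None:
        raise PipelineParseError("SetEqual Quantity needs a code", el.sourceline)
    return QuantityRef(code=code, osipi_name=el.get("value"))


def _read_set_equal(el) -> SetEqualStatement:
    kids = [k for k in el if isinstance(k.tag, str)]
    if len(kids) != 2:
        raise PipelineParseError("SetEqual needs exactly two children", el.sourceline)
    left_el, right_el = kids
    if left_el.tag != _Q["quantity_ref"]:
        raise PipelineParseError("SetEqual left side must be a Quantity", el.sourceline)
    left = _read_quantity_ref(left_el)
    if right_el.tag == _Q["quantity_ref"]:
        right: QuantityRef | Literal = _read_quantity_ref(right_el)
    elif right_el.tag == _Q["literal"]:
        raw = right_el.get("numericValue")
        if raw is None:
            raise PipelineParseError("Literal needs numericValue", right_el.sourceline)
        right = Literal(value=float(raw), unit=right_el.get("unit", ""))
    else:
        raise PipelineParseError(
            f"SetEqual right side must be Quantity or Literal, got {right_el.tag}",
            right_el.sourceline,
        )
    return SetEqualStatement(left=left, right=right)


def _read_process(el, lenient: bool) -> ProcessNode:
    children = []
    for kid in el:
        if not isinstance(kid.tag, str):  # comments
            continue
        if kid.tag == _Q["process"]:
            children.append(_read_process(kid, lenient))
        elif kid.tag == _Q["input"]:
            children.append(_read_quantity(kid, "input"))
        elif kid.tag == _Q["output"]:
            children.append(_read_quantity(kid, "output"))
        elif kid.tag == _Q["model"]:
            children.append(
                ModelElement(
                    osipi_name=kid.get("value", ""),
                    code=_parse_optional_code(kid.get("code"), kid.sourceline),
                    instance=kid.get("instance"),
                )
            )
        elif kid.tag == _Q["set_equal"]:
            children.append(_read_set_equal(kid))
        elif lenient:
            children.append(RawElement(tag=kid.tag, line=kid.sourceline))
        else:
            raise PipelineParseError(f"unknown element {kid.tag}", kid.sourceline)
    return ProcessNode(
        osipi_name=el.get("value", ""),
        code=_parse_optional_code(el.get("code"), el.sourceline),
        instance=el.get("instance"),
        children=tuple(children),
    )


def read_pipeline(xml_text: str | bytes, lenient: bool = False) -> PipelineDocument:
    """Parse LL-XML into a :class:`PipelineDocument`.

    By default the document must satisfy the shipped XSD; parse failures
    raise :class:`~caplex.errors.PipelineParseError` with a line number.
    With ``lenient=True`` structural defects (missing attributes, unknown
    children, an empty pipeline) are carried into the document so that
    :func:`validate_pipeline` can report them as rule violations.
    """
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise PipelineParseError(f"XML syntax error: {exc}") from exc
    if root.tag != _Q["pipeline"]:
        raise PipelineParseError(f"root element must be Pipeline, got {root.tag}")
    if not lenient:
        schema = _schema()
        if not schema.validate(root):
            err = schema.error_log[0]
            raise PipelineParseError(f"schema violation: {err.message}", err.line)
    top: list = []
    for kid in root:
        if not isinstance(kid.tag, str):
            continue
        if kid.tag == _Q["process"]:
            top.append(_read_process(kid, lenient))
        elif lenient:
            top.append(RawElement(tag=kid.tag, line=kid.sourceline))
        else:  # pragma: no cover - schema already rejects this
            raise PipelineParseError(f"unexpected top-level element {kid.tag}", kid.sourceline)
    schema_loc = root.get(f"{{{_XSI}}}schemaLocation", SCHEMA_FILENAME)
    if schema_loc.startswith(f"{NAMESPACE} "):
        schema_loc = schema_loc[len(NAMESPACE) + 1 :]
    return PipelineDocument(processes=tuple(top), schema_location=schema_loc)


# ---------------------------------------------------------------------------
# writing

def _set_common(el, name: str, code: LexiconCode | None, instance: str | None):
    el.set("value", name)
    if code is not None:
        el.set("code", format_code(code))
    if instance:
        el.set("instance", instance)


def _write_quantity(parent, q: QuantityElement):
    tag = _Q["input"] if q.role == "input" else _Q["output"]
    el = etree.SubElement(parent, tag)
    el.set("value", q.osipi_name)
    if q.code is not None:
        el.set("code", format_code(q.code))
    if q.unit is not None:
        el.set("unit", q.unit)
    if q.instance:
        el.set("instance", q.instance)
    if q.fit_type is not None:
        el.set("type", q.fit_type)
    if q.numeric_value is not None:
        el.set("numericValue", repr(q.numeric_value))
    if q.uncertainty is not None:
        el.set("uncertainty", repr(q.uncertainty))


def _write_set_equal(parent, stmt: SetEqualStatement):
    el = etree.SubElement(parent, _Q["set_equal"])
    left = etree.SubElement(el, _Q["quantity_ref"])
    left.set("code", format_code(stmt.left.code))
    if stmt.left.osipi_name:
        left.set("value", stmt.left.osipi_name)
    if isinstance(stmt.right, Literal):
        right = etree.SubElement(el, _Q["literal"])
        right.set("numericValue", repr(stmt.right.value))
        if stmt.right.unit:
            right.set("unit", stmt.right.unit)
    else:
        right = etree.SubElement(el, _Q["quantity_ref"])
        right.set("code", format_code(stmt.right.code))
        if stmt.right.osipi_name:
            right.set("value", stmt.right.osipi_name)


def _write_process(parent, node: ProcessNode):
    el = etree.SubElement(parent, _Q["process"])
    _set_common(el, node.osipi_name, node.code, node.instance)
    for child in node.children:
        if isinstance(child, ProcessNode):
            _write_process(el, child)
        elif isinstance(child, QuantityElement):
            _write_quantity(el, child)
        elif isinstance(child, ModelElement):
            mel = etree.SubElement(el, _Q["model"])
            _set_common(mel, child.osipi_name, child.code, child.instance)
        elif isinstance(child, SetEqualStatement):
            _write_set_equal(el, child)
        else:
            raise TypeError(f"cannot serialize child {child!r}")


def write_pipeline(doc: PipelineDocument) -> str:
    """Serialize a document to LL-XML text (deterministic, UTF-8)."""
    nsmap = {"ex": NAMESPACE, "xsi": _XSI}
    root = etree.Element(_Q["pipeline"], nsmap=nsmap)
    if doc.schema_location:
        root.set(f"{{{_XSI}}}schemaLocation", f"{NAMESPACE} {doc.schema_location}")
    for node in doc.processes:
        if not isinstance(node, ProcessNode):
            raise TypeError(f"cannot serialize top-level {node!r}")
        _write_process(root, node)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# semantic validation against the registry

_ALLOWED_SECTIONS = {
    "process": ("P", "G", "D"),
    "quantity": ("Q",),
    "model": ("M",),
}


def _check_named(report, loc, kind: str, name: str, code, registry):
    """Shared R3-R6 checks for processes, quantities and models."""
    if not name or code is None:
        report.add("R3", loc, f"{kind} element needs both value (OSIPI name) and code")
        return None
    if code.section not in _ALLOWED_SECTIONS[kind]:
        report.add(
            "R6", loc,
            f"{kind} element carries a section-{code.section} code {format_code(code)}",
        )
    try:
        entry = registry.lookup(code)
    except LookupError_:
        report.add("R5", loc, f"code {format_code(code)} not found in registry")
        return None
    if entry.osipi_name != name:
        report.add(
            "R4", loc,
            f"OSIPI name {name!r} does not match registry name "
            f"{entry.osipi_name!r} for {format_code(code)}",
        )
    return entry


def _unit_of(registry, code: LexiconCode) -> str | None:
    try:
        return registry.lookup(code).osipi_unit
    except LookupError_:
        return None


def _validate_set_equal(report, loc, stmt: SetEqualStatement, registry):
    for side, ref in (("left", stmt.left), ("right", stmt.right)):
        if isinstance(ref, QuantityRef) and ref.code is not None:
            if ref.code not in registry:
                report.add("R5", f"{loc}/{side}", f"code {format_code(ref.code)} not in registry")
    left_unit = _unit_of(registry, stmt.left.code)
    if isinstance(stmt.right, Literal):
        if left_unit is not None and stmt.right.unit != left_unit:
            report.add(
                "R7", loc,
                f"literal unit {stmt.right.unit!r} differs from registry unit "
                f"{left_unit!r} of {format_code(stmt.left.code)}",
            )
    else:
        right_unit = _unit_of(registry, stmt.right.code)
        if None not in (left_unit, right_unit) and left_unit != right_unit:
            report.add("R7", loc, f"incompatible units {left_unit!r} vs {right_unit!r}")


def _validate_process(report, loc, node: ProcessNode, registry):
    _check_named(report, loc, "process", node.osipi_name, node.code, registry)
    counters: dict[str, int] = {}

    def child_loc(tagkey: str) -> str:
        counters[tagkey] = counters.get(tagkey, 0) + 1
        return f"{loc}/{TAGS[tagkey]}[{counters[tagkey]}]"

    for child in node.children:
        if isinstance(child, ProcessNode):
            cloc = child_loc("process")
            if (
                child.code is not None
                and node.code is not None
                and child.code == node.code
            ):
                report.add("R2", cloc, "a nested process must differ from its parent")
            _validate_process(report, cloc, child, registry)
        elif isinstance(child, QuantityElement):
            cloc = child_loc("input" if child.role == "input" else "output")
            entry = _check_named(report, cloc, "quantity", child.osipi_name, child.code, registry)
            if child.unit is None:
                report.add("R7", cloc, "quantity element needs a unit attribute")
            elif entry is not None and entry.osipi_unit is not None and child.unit != entry.osipi_unit:
                report.add(
                    "R7", cloc,
                    f"unit {child.unit!r} differs from OSIPI unit {entry.osipi_unit!r}",
                )
            if child.fit_type is not None:
                if child.fit_type not in ("free", "fixed"):
                    report.add("R8", cloc, f"type must be 'free' or 'fixed', got {child.fit_type!r}")
                elif child.role != "input":
                    report.add("R8", cloc, "type attribute is only meaningful on input quantities")
        elif isinstance(child, ModelElement):
            cloc = child_loc("model")
            _check_named(report, cloc, "model", child.osipi_name, child.code, registry)
        elif isinstance(child, SetEqualStatement):
            _validate_set_equal(report, child_loc("set_equal"), child, registry)
        elif isinstance(child, RawElement):
            report.add("R2", loc, f"element {child.tag} is not an allowed child of Process")
        else:  # pragma: no cover
            report.add("R2", loc, f"unexpected child {type(child).__name__}")


def validate_pipeline(doc: PipelineDocument, registry: LexiconRegistry) -> ValidationReport:
    """Apply the semantic rule set R1-R8 (see module docstring).

    Violations are returned as data in a :class:`ValidationReport`, never
    raised.
    """
    report = ValidationReport()
    procs = [p for p in doc.processes if isinstance(p, ProcessNode)]
    if not procs:
        report.add("R1", "/Pipeline", "pipeline must contain at least one process")
    for extra in doc.processes:
        if isinstance(extra, RawElement):
            report.add(
                "R2", "/Pipeline",
                f"top-level element {extra.tag} is not a Process",
            )
    for i, node in enumerate(procs, start=1):
        _validate_process(report, f"/Pipeline/Process[{i}]", node, registry)
    return report


# ---------------------------------------------------------------------------
# lexicon-linked free-text rendering

def _link(registry, name: str, code: LexiconCode, links: bool) -> str:
    if not links:
        return name
    return f"[{name}]({registry.hyperlink(code)})"


def _fmt_number(x: float) -> str:
    return f"{x:g}"


def _render_quantity(registry, q: QuantityElement, links: bool) -> str:
    entry = registry.lookup(q.code)
    text = _link(registry, entry.notation, q.code, links)
    unit = q.unit if q.unit else "unitless"
    if q.numeric_value is not None:
        text += f" = {_fmt_number(q.numeric_value)}"
        if q.uncertainty is not None:
            text += f" ± {_fmt_number(q.uncertainty)}"
        text += f" {unit}" if q.unit else " (unitless)"
    else:
        text += f" ({unit})"
    if q.fit_type is not None:
        text += f" [{q.fit_type}]"
    return text


def _render_set_equal(registry, stmt: SetEqualStatement, links: bool) -> str:
    left_entry = registry.lookup(stmt.left.code)
    left = _link(registry, left_entry.notation, stmt.left.code, links)
    if isinstance(stmt.right, Literal):
        unit = f" {stmt.right.unit}" if stmt.right.unit else " (unitless)"
        right = f"{_fmt_number(stmt.right.value)}{unit}"
    else:
        right_entry = registry.lookup(stmt.right.code)
        right = _link(registry, right_entry.notation, stmt.right.code, links)
    return f"setting {left} equal to {right}"


def _render_process(registry, node: ProcessNode, links: bool, depth: int = 0) -> list[str]:
    name = _link(registry, node.osipi_name, node.code, links)
    parts = [f"The {name} ({format_code(node.code)}) process was applied"]
    models = [c for c in node.children if isinstance(c, ModelElement)]
    inputs = [c for c in node.children if isinstance(c, QuantityElement) and c.role == "input"]
    outputs = [c for c in node.children if isinstance(c, QuantityElement) and c.role == "output"]
    equalities = [c for c in node.children if isinstance(c, SetEqualStatement)]
    subprocs = [c for c in node.children if isinstance(c, ProcessNode)]
    if models:
        parts.append(
            "using the " + " and the ".join(
                _link(registry, m.osipi_name, m.code, links) for m in models
            )
        )
    if inputs:
        parts.append("with inputs " + ", ".join(_render_quantity(registry, q, links) for q in inputs))
    if equalities:
        parts.append(", ".join(_render_set_equal(registry, s, links) for s in equalities))
    if outputs:
        parts.append("yielding " + ", ".join(_render_quantity(registry, q, links) for q in outputs))
    if node.instance:
        parts.append(f"(implemented as `{node.instance}`)")
    indent = "  " * depth
    lines = [f"{indent}- " + " ".join(parts) + "."]
    for sub in subprocs:
        lines.extend(_render_process(registry, sub, links, depth + 1))
    return lines


def render_free_text(
    doc: PipelineDocument, registry: LexiconRegistry, links: bool = True
) -> str:
    """Render a validated document as a lexicon-linked methods paragraph.

    Every process, model and quantity name is hyperlinked to its lexicon
    entry; quantities carry their OSIPI unit in parentheses and numeric
    values are rendered ``notation = value ± uncertainty unit``.  Invalid
    documents are refused.
    """
    report = validate_pipeline(doc, registry)
    if not report.valid:
        raise ValueError(f"refusing to render an invalid pipeline:\n{report}")
    lines = [
        f"All quantities, models and processes conform to OSIPI CAPLEX (v.{registry.version}).",
        "",
    ]
    for node in doc.processes:
        lines.extend(_render_process(registry, node, links))
    return "\n".join(lines) + "\n"
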