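"""Lexicon entries and the versioned registry.

Each entry records the fields the standard requires — code, OSIPI name,
notation, description — plus optional alternative names and reference, an
OSIPI unit for quantities, and complete ordered input/output lists for
processes.  The package ships a curated registry subset as JSON
(``data/registry.json``); the full lexicon lives on the public webpage, to
which rendered documents hyperlink.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .codes import LexiconCode, format_code, parse_code
from .errors import LookupError_

_SECTION_KIND = {"Q": "quantity", "M": "model", "P": "process", "G": "process", "D": "process"}


@dataclass(frozen=True)
class LexiconEntry:
    """One quantity, model or process record."""

    code: LexiconCode
    entry_kind: str  # quantity | model | process
    osipi_name: str
    notation: str
    description: str
    alternative_names: tuple[str, ...] = ()
    osipi_unit: str | None = None  # required for quantities; "" = unitless
    inputs: tuple[LexiconCode, ...] = ()   # processes only, ordered
    outputs: tuple[LexiconCode, ...] = ()  # processes only, ordered
    reference: str | None = None

    def bind_compartment(self, code: LexiconCode) -> "LexiconEntry":
        """Return a copy with ``code``'s compartment bound into the notation.

        E.g. the indicator-concentration template ``C`` resolved for
        ``Q.IC1.001.[a,p]`` renders its notation as ``C_a,p``.
        """
        if code.compartment is None:
            return self
        bound = f"{self.notation}_{code.compartment.serialize()}"
        return replace(self, code=code, notation=bound)


@dataclass
class Violation:
    """One validation finding: the rule that fired, where, and why."""

    rule: str
    field: str
    message: str


def validate_entry(entry: LexiconEntry) -> list[Violation]:
    """Check required-field and consistency invariants of one entry.

    Returns an empty list when the entry is well-formed; violations are
    data, never exceptions.
    """
    out: list[Violation] = []
    for name in ("osipi_name", "notation", "description"):
        if not getattr(entry, name):
            out.append(Violation("missing_required_field", name, f"{name} is required"))
    expected = _SECTION_KIND[entry.code.section]
    if entry.entry_kind != expected:
        out.append(
            Violation(
                "kind_section_mismatch",
                "entry_kind",
                f"section {entry.code.section} implies {expected}, got {entry.entry_kind}",
            )
        )
    if entry.entry_kind == "quantity" and entry.osipi_unit is None:
        out.append(Violation("missing_unit", "osipi_unit", "quantities require an OSIPI unit"))
    if entry.entry_kind == "process" and (not entry.inputs or not entry.outputs):
        out.append(
            Violation(
                "incomplete_io",
                "inputs/outputs",
                "processes require complete, ordered input and output lists",
            )
        )
    if entry.entry_kind != "process" and (entry.inputs or entry.outputs):
        out.append(Violation("io_on_non_process", "inputs/outputs", "only processes carry I/O lists"))
    return out


@dataclass
class LexiconRegistry:
    """Mapping from serialized code to entry, with version metadata.

    Lookup respects the compartment suffix: ``Q.X.Y`` rows are templates
    and ``Q.X.Y.[a]`` resolves to the template with the compartment bound.
    """

    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    version: str = "1.0.2"
    webpage_base: str = "https://osipi.github.io/OSIPI_CAPLEX"

    def lookup(self, code_text: str | LexiconCode) -> LexiconEntry:
        code = code_text if isinstance(code_text, LexiconCode) else parse_code(code_text)
        key = format_code(code)
        if key in self.entries:
            return self.entries[key]
        if code.compartment is not None:
            template_key = format_code(code.template)
            if template_key in self.entries:
                return self.entries[template_key].bind_compartment(code)
        raise LookupError_(key)

    def __contains__(self, code_text: str | LexiconCode) -> bool:
        try:
            self.lookup(code_text)
            return True
        except LookupError_:
            return False

    def hyperlink(self, code: LexiconCode | str) -> str:
        key = code if isinstance(code, str) else format_code(code)
        return f"{self.webpage_base}#{key}"

    def validate(self) -> list[tuple[str, Violation]]:
        """Validate every entry; returns (code, violation) pairs."""
        found = []
        for key, entry in self.entries.items():
            for v in validate_entry(entry):
                found.append((key, v))
        return found


def _entry_from_json(key: str, obj: dict) -> LexiconEntry:
    return LexiconEntry(
        code=parse_code(key),
        entry_kind=obj["kind"],
        osipi_name=obj["name"],
        notation=obj["notation"],
        description=obj["description"],
        alternative_names=tuple(obj.get("alternative_names", [])),
        osipi_unit=obj.get("unit"),
        inputs=tuple(parse_code(c) for c in obj.get("inputs", [])),
        outputs=tuple(parse_code(c) for c in obj.get("outputs", [])),
        reference=obj.get("reference"),
    )


def load_registry(path: str | Path | None = None) -> LexiconRegistry:
    """Load a registry from JSON; defaults to the curated subset shipped
    with the package."""
    if path is None:
        text = resources.files("caplex.data").joinpath("registry.json").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = json.loads(text)
    entries = {key: _entry_from_json(key, obj) for key, obj in raw["entries"].items()}
    return LexiconRegistry(
        entries=entries,
        version=raw.get("version", "1.0.2"),
        webpage_base=raw.get("webpage_base", "https://osipi.github.io/OSIPI_CAPLEX"),
    )
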