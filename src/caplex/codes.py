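"""CAPLEX identifier grammar: compartment subscripts and lexicon codes.

A lexicon code names one entry and is structured as
``Section.Group.Item.[CompartmentCode]``, e.g. ``Q.MS1.001.[a]`` — item 001
of group MS1 in section Q, measured in a feeding artery.  Sections are Q
(quantities), M (models) and P/G/D (perfusion / general-purpose / derived
processes).  Only quantities may carry a compartment suffix.

Compartment subscripts combine in three ways:

* nested  — smaller compartment inside a larger one, comma-separated with
  the larger first: ``a,p`` (plasma within a feeding artery);
* combined — concatenated without separator: ``be`` (whole blood plus
  extravascular extracellular space);
* exchange — two endpoints joined by an arrow giving the direction of
  transport: ``e→i``.

Parsing and serialization are exact inverses on every well-formed string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import CodeParseError

#: Single-letter compartment subscripts (tissue, capillary, artery, vein,
#: plasma, whole blood, intracellular, extravascular extracellular).
COMPARTMENT_SYMBOLS = frozenset("tcavpbie")

SECTIONS = ("Q", "M", "P", "G", "D")

ARROW = "→"  # →; "->" is accepted on input as an ASCII fallback

_GROUP_RE = re.compile(r"^[A-Za-z]{1,4}[0-9]{1,2}$")
_ITEM_RE = re.compile(r"^[0-9]{3}$")


@dataclass(frozen=True)
class CompartmentToken:
    """One compartment subscript letter."""

    symbol: str

    def __post_init__(self):
        if self.symbol not in COMPARTMENT_SYMBOLS:
            raise CodeParseError(
                "compartment", self.symbol, f"unknown compartment letter {self.symbol!r}"
            )

    def __str__(self) -> str:
        return self.symbol


@dataclass(frozen=True)
class CompartmentSpec:
    """A compartment expression: single, nested, combined or exchange.

    ``tokens`` holds :class:`CompartmentToken` for the first three kinds and
    exactly two :class:`CompartmentSpec` endpoints for ``exchange``.
    """

    kind: str  # single | nested | combined | exchange
    tokens: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind not in ("single", "nested", "combined", "exchange"):
            raise CodeParseError("compartment", str(self.tokens), f"unknown kind {self.kind!r}")
        n = len(self.tokens)
        if self.kind == "single" and n != 1:
            raise CodeParseError("compartment", str(self.tokens), "single needs exactly 1 token")
        if self.kind in ("nested", "combined") and n < 2:
            raise CodeParseError("compartment", str(self.tokens), f"{self.kind} needs >=2 tokens")
        if self.kind == "exchange":
            if n != 2:
                raise CodeParseError(
                    "compartment", str(self.tokens), "exchange needs exactly 2 endpoints"
                )
            for t in self.tokens:
                if not isinstance(t, CompartmentSpec) or t.kind == "exchange":
                    raise CodeParseError(
                        "compartment", str(self.tokens), "exchange endpoints must be non-exchange specs"
                    )

    def serialize(self) -> str:
        if self.kind == "single":
            return str(self.tokens[0])
        if self.kind == "nested":
            return ",".join(str(t) for t in self.tokens)
        if self.kind == "combined":
            return "".join(str(t) for t in self.tokens)
        return ARROW.join(t.serialize() for t in self.tokens)

    def __str__(self) -> str:
        return self.serialize()


def parse_compartment_spec(text: str) -> CompartmentSpec:
    """Parse a compartment expression such as ``a,p``, ``be`` or ``e→i``.

    The kind is inferred from the separators: an arrow makes an exchange,
    a comma a nested spec, several bare letters a combined compartment and
    one letter a single compartment.  ``->`` is accepted as an ASCII
    fallback for the arrow.
    """
    if not text:
        raise CodeParseError("compartment", text, "empty compartment spec")
    normalized = text.replace("->", ARROW)
    if ARROW in normalized:
        sides = normalized.split(ARROW)
        if len(sides) != 2:
            raise CodeParseError("compartment", text, "exchange needs exactly 2 endpoints")
        endpoints = []
        for side in sides:
            if not side:
                raise CodeParseError("compartment", text, "empty side of exchange arrow")
            endpoints.append(parse_compartment_spec(side))
        return CompartmentSpec("exchange", tuple(endpoints))
    if "," in normalized:
        parts = normalized.split(",")
        if any(len(p) != 1 for p in parts):
            raise CodeParseError("compartment", text, "nested subscripts are single letters")
        return CompartmentSpec("nested", tuple(CompartmentToken(p) for p in parts))
    if len(normalized) > 1:
        return CompartmentSpec("combined", tuple(CompartmentToken(c) for c in normalized))
    return CompartmentSpec("single", (CompartmentToken(normalized),))


@dataclass(frozen=True)
class LexiconCode:
    """A parsed ``Section.Group.Item.[Compartment]`` identifier."""

    section: str
    group: str
    item: str
    compartment: CompartmentSpec | None = None

    def __post_init__(self):
        if self.section not in SECTIONS:
            raise CodeParseError("section", self.section, f"unknown section {self.section!r}")
        if not _GROUP_RE.match(self.group):
            raise CodeParseError("group", self.group, "group must be 1-4 letters + 1-2 digits")
        if not _ITEM_RE.match(self.item):
            raise CodeParseError("item", self.item, "item must be a 3-digit number")
        if self.compartment is not None and self.section != "Q":
            raise CodeParseError(
                "compartment", str(self.compartment),
                f"compartment suffix only allowed on section Q, not {self.section}",
            )

    @property
    def template(self) -> "LexiconCode":
        """The code with any compartment suffix removed."""
        if self.compartment is None:
            return self
        return LexiconCode(self.section, self.group, self.item)

    def with_compartment(self, spec: CompartmentSpec | str | None) -> "LexiconCode":
        if isinstance(spec, str):
            spec = parse_compartment_spec(spec)
        return LexiconCode(self.section, self.group, self.item, spec)

    def serialize(self) -> str:
        base = f"{self.section}.{self.group}.{self.item}"
        if self.compartment is not None:
            base += f".[{self.compartment.serialize()}]"
        return base

    def __str__(self) -> str:
        return self.serialize()


def parse_code(text: str) -> LexiconCode:
    """Parse a serialized lexicon code, e.g. ``Q.IC1.001.[a,p]``.

    Codes are case-sensitive exactly as printed.  Raises
    :class:`~caplex.errors.CodeParseError` naming the offending component.
    """
    if not text:
        raise CodeParseError("section", text, "empty code")
    parts = text.split(".")
    if len(parts) < 3:
        raise CodeParseError("item", text, "a code needs at least Section.Group.Item")
    section, group = parts[0], parts[1]
    comp_text = None
    if len(parts) == 3:
        item = parts[2]
    else:
        # everything past Group joins back together: the compartment itself
        # may contain dots? No — but nested specs contain commas only; the
        # bracketed suffix never contains ".", so >4 parts is malformed.
        item = parts[2]
        suffix = ".".join(parts[3:])
        if not (suffix.startswith("[") and suffix.endswith("]")):
            raise CodeParseError("compartment", text, "compartment suffix must be bracketed")
        comp_text = suffix[1:-1]
    if section not in SECTIONS:
        raise CodeParseError("section", text, f"unknown section {section!r}")
    if not _GROUP_RE.match(group):
        raise CodeParseError("group", text, f"bad group token {group!r}")
    if not _ITEM_RE.match(item):
        raise CodeParseError("item", text, f"bad item token {item!r}")
    compartment = parse_compartment_spec(comp_text) if comp_text is not None else None
    return LexiconCode(section, group, item, compartment)


def format_code(code: LexiconCode) -> str:
    """Serialize a code; inverse of :func:`parse_code`."""
    return code.serialize()
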