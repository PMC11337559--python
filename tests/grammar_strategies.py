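"""Hypothesis strategies and a plain seeded fuzzer for the code grammar."""

import string

import numpy as np
from hypothesis import strategies as st

from caplex.codes import (
    COMPARTMENT_SYMBOLS,
    CompartmentSpec,
    CompartmentToken,
    LexiconCode,
    SECTIONS,
)

_letters = sorted(COMPARTMENT_SYMBOLS)

tokens = st.sampled_from(_letters).map(CompartmentToken)

singles = tokens.map(lambda t: CompartmentSpec("single", (t,)))
nested = st.lists(tokens, min_size=2, max_size=4).map(
    lambda ts: CompartmentSpec("nested", tuple(ts))
)
combined = st.lists(tokens, min_size=2, max_size=4).map(
    lambda ts: CompartmentSpec("combined", tuple(ts))
)
_endpoints = st.one_of(singles, nested, combined)
exchanges = st.tuples(_endpoints, _endpoints).map(
    lambda pair: CompartmentSpec("exchange", pair)
)
compartment_specs = st.one_of(singles, nested, combined, exchanges)

groups = st.builds(
    lambda ls, ds: ls + ds,
    st.text(alphabet=string.ascii_letters, min_size=1, max_size=4),
    st.text(alphabet=string.digits, min_size=1, max_size=2),
)
items = st.integers(min_value=0, max_value=999).map(lambda i: f"{i:03d}")


@st.composite
def lexicon_codes(draw):
    section = draw(st.sampled_from(SECTIONS))
    comp = draw(compartment_specs) if section == "Q" and draw(st.booleans()) else None
    return LexiconCode(section, draw(groups), draw(items), comp)


def random_code(rng: np.random.Generator) -> LexiconCode:
    """Seeded fuzz generator mirroring the hypothesis strategy."""
    section = SECTIONS[rng.integers(len(SECTIONS))]
    letters = string.ascii_letters
    group = "".join(
        rng.choice(list(letters), size=rng.integers(1, 5))
    ) + "".join(rng.choice(list(string.digits), size=rng.integers(1, 3)))
    item = f"{rng.integers(0, 1000):03d}"
    comp = None
    if section == "Q" and rng.random() < 0.5:
        comp = random_compartment(rng)
    return LexiconCode(section, group, item, comp)


def random_compartment(rng: np.random.Generator, allow_exchange: bool = True) -> CompartmentSpec:
    kinds = ["single", "nested", "combined"] + (["exchange"] if allow_exchange else [])
    kind = kinds[rng.integers(len(kinds))]
    if kind == "single":
        return CompartmentSpec("single", (CompartmentToken(_letters[rng.integers(8)]),))
    if kind in ("nested", "combined"):
        n = rng.integers(2, 5)
        toks = tuple(CompartmentToken(_letters[rng.integers(8)]) for _ in range(n))
        return CompartmentSpec(kind, toks)
    ends = tuple(random_compartment(rng, allow_exchange=False) for _ in range(2))
    return CompartmentSpec("exchange", ends)
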