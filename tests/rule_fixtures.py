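"""Conformance fixtures live with the package; re-exported for the tests."""

from caplex.examples import INVALID, VALID  # noqa: F401
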