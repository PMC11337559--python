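"""Exception hierarchy shared across the package."""


class CaplexError(Exception):
    """Base class for all package-specific errors."""


class CodeParseError(CaplexError, ValueError):
    """A lexicon identifier could not be parsed.

    Parameters
    ----------
    component
        Which grammatical component was at fault (``section``, ``group``,
        ``item``, ``compartment``).
    text
        The offending input text.
    """

    def __init__(self, component: str, text: str, message: str):
        self.component = component
        self.text = text
        super().__init__(f"{component}: {message} (in {text!r})")


class LookupError_(CaplexError, KeyError):
    """A code is absent from the registry; carries the unresolved code."""

    def __init__(self, code_text: str):
        self.code_text = code_text
        super().__init__(f"code not in registry: {code_text}")


class PipelineParseError(CaplexError, ValueError):
    """An LL-XML document could not be read; carries a location when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


class ExecutionError(CaplexError, RuntimeError):
    """Pipeline execution failed (unbound input, unimplemented process...)."""

    def __init__(self, message: str, code: str | None = None):
        self.code = code
        super().__init__(message)


class DomainError(CaplexError, ValueError):
    """A numeric argument lies outside the model's domain."""


class FitError(CaplexError, RuntimeError):
    """A model fit could not be performed on the given data."""
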