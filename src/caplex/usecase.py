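"""Builders for the worked ROI-analysis pipeline document.

The standard document encodes the classic ROI-level DCE analysis: estimate
the baseline signal of the tissue and arterial curves, convert both to the
change in longitudinal relaxation rate with the linear signal model, and
fit a kinetic model to the tissue response driven by the arterial input.
A fixed arterial hematocrit is declared explicitly with SetEqual.  The
document is built against the shipped registry so that every name/code
pair validates, and a serialized copy ships as
``data/usecase_pipeline.xml``.
"""

from __future__ import annotations

from importlib import resources

from .pipeline import (
    Literal,
    ModelElement,
    PipelineDocument,
    ProcessNode,
    QuantityElement,
    QuantityRef,
    SetEqualStatement,
    read_pipeline,
)
from .registry import LexiconRegistry, load_registry


def _q(registry: LexiconRegistry, role: str, code: str, **kw) -> QuantityElement:
    entry = registry.lookup(code)
    return QuantityElement(
        role=role,
        osipi_name=entry.osipi_name,
        code=entry.code if entry.code.serialize() == code else entry.code,
        unit=entry.osipi_unit,
        **kw,
    )


def _model(registry: LexiconRegistry, code: str) -> ModelElement:
    entry = registry.lookup(code)
    return ModelElement(osipi_name=entry.osipi_name, code=entry.code)


def _proc(registry: LexiconRegistry, code: str, children, instance: str | None = None) -> ProcessNode:
    entry = registry.lookup(code)
    return ProcessNode(
        osipi_name=entry.osipi_name, code=entry.code, instance=instance,
        children=tuple(children),
    )


def build_roi_pipeline(
    n_baseline: int,
    registry: LexiconRegistry | None = None,
    model_code: str = "M.IC1.011",
    R10: float = 1.0,
    hct: float = 0.45,
    initial: dict[str, float] | None = None,
) -> PipelineDocument:
    """Build the ROI kinetic-analysis document.

    ``n_baseline`` (the number of initial dynamics averaged for the
    baseline signal) has no default on purpose: the convention in the
    literature varies and must be stated.  ``initial`` maps kinetic
    parameter names to their starting values; free parameters are encoded
    as typed InputQuantity elements so that rendered reports state the
    optimizer configuration.
    """
    reg = registry or load_registry()
    init = {"Ktrans": 0.1, "ve": 20.0} if initial is None else dict(initial)
    param_codes = {"Ktrans": "Q.PH1.008", "ve": "Q.PH1.001.[e]", "Fp": "Q.PH1.002",
                   "vp": "Q.PH1.001.[p]", "PS": "Q.PH1.004"}

    def baseline(comp: str) -> ProcessNode:
        return _proc(reg, "P.BE1.001", [
            _q(reg, "input", f"Q.MS1.001.[{comp}]"),
            _q(reg, "input", "Q.BL1.001", numeric_value=float(n_baseline)),
            _q(reg, "output", f"Q.MS1.002.[{comp}]"),
        ])

    def to_delta_r1(comp: str) -> ProcessNode:
        return _proc(reg, "P.SC1.001", [
            _q(reg, "input", f"Q.MS1.001.[{comp}]"),
            _q(reg, "input", f"Q.MS1.002.[{comp}]"),
            _q(reg, "input", "Q.EL1.002", numeric_value=R10),
            _model(reg, "M.EL1.001"),
            _q(reg, "output", f"Q.EL1.003.[{comp}]"),
        ])

    fit_children = [
        _model(reg, model_code),
        _q(reg, "input", "Q.EL1.003.[t]"),
        _q(reg, "input", "Q.EL1.003.[a,b]"),
    ]
    fit_children += [
        _q(reg, "input", param_codes[name], numeric_value=value, fit_type="free")
        for name, value in init.items()
    ]
    fit_children += [
        _q(reg, "output", param_codes[name]) for name in init
    ]
    fit_children.append(_q(reg, "output", "Q.OP1.003"))
    fit = _proc(reg, "P.PE1.001", fit_children, instance="scipy.optimize.least_squares")

    hct_code = reg.lookup("Q.PH1.007.[a]").code
    analysis = _proc(reg, "D.PE1.001", [
        SetEqualStatement(left=QuantityRef(code=hct_code), right=Literal(value=hct, unit="")),
        baseline("t"),
        baseline("a,b"),
        to_delta_r1("t"),
        to_delta_r1("a,b"),
        fit,
    ])
    return PipelineDocument(processes=(analysis,))


def usecase_document() -> PipelineDocument:
    """The shipped worked-example document (read from package data)."""
    text = resources.files("caplex.data").joinpath("usecase_pipeline.xml").read_text("utf-8")
    return read_pipeline(text)
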