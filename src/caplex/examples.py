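"""Example LL-XML documents: valid ones plus one per validation rule.

This doubles as the format's conformance suite: each invalid example is
crafted to trigger exactly one semantic rule, keeping the rest of the
document clean, so classification is unambiguous.
"""

from importlib import resources

_NS = 'xmlns:ex="https://osipi.github.io/OSIPI_CAPLEX/llxml"'


def _pipeline(body: str) -> str:
    return f'<?xml version="1.0" encoding="UTF-8"?>\n<ex:Pipeline {_NS}>{body}</ex:Pipeline>'


_HOST_OPEN = '<ex:Process value="Baseline signal estimation by averaging" code="P.BE1.001">'

VALID = {
    "minimal": _pipeline(
        '<ex:Process value="Baseline signal estimation by averaging" code="P.BE1.001"/>'
    ),
    "usecase": resources.files("caplex.data").joinpath("usecase_pipeline.xml").read_text("utf-8"),
    "two_processes": _pipeline(
        '<ex:Process value="Threshold segmentation" code="G.SE1.001">'
        '<ex:InputQuantity value="Baseline signal" code="Q.MS1.002" unit="a.u."/>'
        '<ex:OutputQuantity value="Region-of-interest mask" code="Q.SE1.001" unit=""/>'
        "</ex:Process>"
        '<ex:Process value="Plasma flow from blood flow and hematocrit" code="P.PX1.002">'
        '<ex:InputQuantity value="Blood flow" code="Q.PH1.003" unit="mL/min/100 mL"/>'
        '<ex:InputQuantity value="Hematocrit" code="Q.PH1.007.[a]" unit="" numericValue="0.45"/>'
        '<ex:Model value="Hematocrit flow identity" code="M.PI1.002"/>'
        '<ex:OutputQuantity value="Blood plasma flow" code="Q.PH1.002" unit="mL/min/100 mL"/>'
        "</ex:Process>"
    ),
    "nested_with_setequal": _pipeline(
        '<ex:Process value="ROI perfusion analysis" code="D.PE1.001">'
        "<ex:SetEqual>"
        '<ex:Quantity code="Q.PH1.007.[a]"/>'
        '<ex:Literal numericValue="0.45"/>'
        "</ex:SetEqual>"
        f"{_HOST_OPEN}</ex:Process>"
        "</ex:Process>"
    ),
}

# rule id -> fixture triggering it and only it
INVALID = {
    "R1": _pipeline(""),
    "R2": _pipeline(f"{_HOST_OPEN}<ex:Banana/></ex:Process>"),
    "R3": _pipeline('<ex:Process value="Baseline signal estimation by averaging"/>'),
    "R4": _pipeline(
        f"{_HOST_OPEN}"
        '<ex:InputQuantity value="Blood plasma flow" code="Q.PH1.008" unit="1/min"/>'
        "</ex:Process>"
    ),
    "R5": _pipeline(
        f"{_HOST_OPEN}"
        '<ex:InputQuantity value="Mystery quantity" code="Q.ZZ9.999" unit=""/>'
        "</ex:Process>"
    ),
    "R6": _pipeline('<ex:Process value="Tofts model" code="M.IC1.011"/>'),
    "R7": _pipeline(
        f"{_HOST_OPEN}"
        '<ex:InputQuantity value="Blood plasma flow" code="Q.PH1.002" unit="mL/min"/>'
        "</ex:Process>"
    ),
    "R8": _pipeline(
        f"{_HOST_OPEN}"
        '<ex:InputQuantity value="Number of baseline time points" code="Q.BL1.001"'
        ' unit="" type="maybe"/>'
        "</ex:Process>"
    ),
}
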