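<?xml version='1.0' encoding='UTF-8'?>
<ex:Pipeline xmlns:ex="https://osipi.github.io/OSIPI_CAPLEX/llxml" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xsi:schemaLocation="https://osipi.github.io/OSIPI_CAPLEX/llxml llxml.xsd">
  <ex:Process value="ROI perfusion analysis" code="D.PE1.001">
    <ex:SetEqual>
      <ex:Quantity code="Q.PH1.007.[a]"/>
      <ex:Literal numericValue="0.45"/>
    </ex:SetEqual>
    <ex:Process value="Baseline signal estimation by averaging" code="P.BE1.001">
      <ex:InputQuantity value="Signal" code="Q.MS1.001.[t]" unit="a.u."/>
      <ex:InputQuantity value="Number of baseline time points" code="Q.BL1.001" unit="" numericValue="15.0"/>
      <ex:OutputQuantity value="Baseline signal" code="Q.MS1.002.[t]" unit="a.u."/>
    </ex:Process>
    <ex:Process value="Baseline signal estimation by averaging" code="P.BE1.001">
      <ex:InputQuantity value="Signal" code="Q.MS1.001.[a,b]" unit="a.u."/>
      <ex:InputQuantity value="Number of baseline time points" code="Q.BL1.001" unit="" numericValue="15.0"/>
      <ex:OutputQuantity value="Baseline signal" code="Q.MS1.002.[a,b]" unit="a.u."/>
    </ex:Process>
    <ex:Process value="Signal to relaxation rate conversion (linear)" code="P.SC1.001">
      <ex:InputQuantity value="Signal" code="Q.MS1.001.[t]" unit="a.u."/>
      <ex:InputQuantity value="Baseline signal" code="Q.MS1.002.[t]" unit="a.u."/>
      <ex:InputQuantity value="Native longitudinal relaxation rate" code="Q.EL1.002" unit="1/s" numericValue="1.0"/>
      <ex:Model value="Linear signal-relaxation model" code="M.EL1.001"/>
      <ex:OutputQuantity value="Change in longitudinal relaxation rate" code="Q.EL1.003.[t]" unit="1/s"/>
    </ex:Process>
    <ex:Process value="Signal to relaxation rate conversion (linear)" code="P.SC1.001">
      <ex:InputQuantity value="Signal" code="Q.MS1.001.[a,b]" unit="a.u."/>
      <ex:InputQuantity value="Baseline signal" code="Q.MS1.002.[a,b]" unit="a.u."/>
      <ex:InputQuantity value="Native longitudinal relaxation rate" code="Q.EL1.002" unit="1/s" numericValue="1.0"/>
      <ex:Model value="Linear signal-relaxation model" code="M.EL1.001"/>
      <ex:OutputQuantity value="Change in longitudinal relaxation rate" code="Q.EL1.003.[a,b]" unit="1/s"/>
    </ex:Process>
    <ex:Process value="Kinetic model fitting by nonlinear least squares" code="P.PE1.001" instance="scipy.optimize.least_squares">
      <ex:Model value="Tofts model" code="M.IC1.011"/>
      <ex:InputQuantity value="Change in longitudinal relaxation rate" code="Q.EL1.003.[t]" unit="1/s"/>
      <ex:InputQuantity value="Change in longitudinal relaxation rate" code="Q.EL1.003.[a,b]" unit="1/s"/>
      <ex:InputQuantity value="Volume transfer constant" code="Q.PH1.008" unit="1/min" type="free" numericValue="0.1"/>
      <ex:InputQuantity value="Volume fraction" code="Q.PH1.001.[e]" unit="mL/100 mL" type="free" numericValue="20.0"/>
      <ex:OutputQuantity value="Volume transfer constant" code="Q.PH1.008" unit="1/min"/>
      <ex:OutputQuantity value="Volume fraction" code="Q.PH1.001.[e]" unit="mL/100 mL"/>
      <ex:OutputQuantity value="Residual sum of squares" code="Q.OP1.003" unit=""/>
    </ex:Process>
  </ex:Process>
</ex:Pipeline>
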