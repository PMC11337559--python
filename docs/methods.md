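# Methods

This note documents the scientific and numerical choices behind the
package: what is modelled, which conventions were fixed where the standard
leaves room, and what the synthetic data does and does not emulate.

## Identifier grammar

Lexicon codes have the shape `Section.Group.Item.[CompartmentCode]` with
sections Q/M/P/G/D.  The standard does not state a formal grammar for the
group token; we accept 1–4 letters followed by 1–2 digits (all published
examples, e.g. `MS1`, `PH1`, `IC1`, fit this).  Items are exactly three
digits, zero-padded.  Codes are case-sensitive as printed.  Compartment
subscripts are the eight letters t, c, a, v, p, b, i, e; "no index given"
is represented as the absence of a compartment, not a ninth token.  The
exchange arrow is serialized as the Unicode `→`; `->` is accepted on input
as an encoding-robust fallback and canonicalized on output.  Parsing and
serialization are exact inverses over the full grammar (property-tested).

Compartment-bearing quantity codes (`Q.IC1.001.[a,p]`) are resolved as a
template row plus a bound suffix: the registry stores `Q.IC1.001` once and
lookup binds the compartment into the notation (`C` → `C_a,p`).  Whether
the upstream lexicon stores bound rows separately is an open question of
the standard; template-plus-suffix avoids duplicating entries.

## Registry

The shipped registry (`data/registry.json`, 47 entries, version tag
1.0.2) is a curated subset sufficient to encode and execute the worked
ROI analysis; it is not a mirror of the complete public lexicon.  Entries
record the required fields (code, OSIPI name, notation, description), a
unit for every quantity (`""` meaning unitless), and complete ordered
input/output lists for processes.  Where this package needed codes the
published tables do not print (e.g. the baseline-signal quantity or the
deconvolution process), codes were assigned in the published style within
plausibly named groups; they are package-local identifiers, and swapping
them for official ones is a one-line registry edit.

## LL-XML format

The pipeline format is XML in the namespace
`https://osipi.github.io/OSIPI_CAPLEX/llxml` with elements `Pipeline`,
`Process`, `InputQuantity`, `OutputQuantity`, `Model` and `SetEqual`.
Element spellings are isolated in a single naming table
(`pipeline.TAGS`) so they can be re-mapped if an official schema fixes
different ones.  A shipped XSD enforces the structural grammar: at least
one process per pipeline; processes carry required `value` (OSIPI name)
and `code` attributes plus an optional `instance`; quantity elements
additionally carry a required `unit`, an optional `type` (`free`/`fixed`,
inputs only), and optional `numericValue`/`uncertainty` attributes.  The
numeric attributes are this package's extension: the format needs a place
for literal values (e.g. Hct = 0.45) both to render results in the
`notation = value ± uncertainty unit` style and to execute pipelines.
`SetEqual` holds two children — a quantity reference and either a second
reference or a `Literal` — making modelling assumptions explicit.

Semantic validation is separate from schema validation and reports
violations as data, one rule per finding: R1 (≥1 process), R2 (allowed
child kinds; a nested process must differ from its parent — read as
*different code than the parent*, not global uniqueness), R3 (name and
code present), R4 (name matches the registry entry for the code), R5
(code resolves), R6 (section compatibility), R7 (unit present and equal
to the registry unit — mismatches are violations, never auto-converted:
this is a reporting standard, not a calculator), R8 (`type` is
free/fixed, on inputs only).  The reader has two modes: the strict mode
applies the XSD and raises structured parse errors with line numbers;
the lenient mode carries structural defects into the document model so
that the validator can report them as R-violations (this is what the
`validate` CLI uses, so a malformed document yields a report rather than
a crash).  `Model` elements are permitted only as children of `Process`.

Rendering produces Markdown: one bullet per process (nested processes
indented), every name hyperlinked to `webpage_base#code`, every quantity
followed by its unit in parentheses (`unitless` when empty), numeric
values as `notation = value ± uncertainty unit`, and the conformance
statement with the registry version as the opening line.  Invalid
documents are refused.

## Kinetic models and units

All interface parameters use the lexicon's endorsed units — Ktrans in
min⁻¹, flows in mL/min/100 mL, volume fractions in mL/100 mL, times in
seconds — and all internal computation uses per-second rates and
dimensionless fractions, converted exactly once at the model boundary.
Consequently an impulse-response curve is returned in s⁻¹ on the seconds
grid; its value at t = 0 equals the rate/flow parameter after the ÷60 (or
÷6000) conversion and its trapezoidal area equals the volume parameter
÷100.  The v_e appearing inside the Tofts exponent is treated as a
fraction (registry unit mL/100 mL divided by 100).

Each forward model exists in two independent implementations — discrete
convolution of the analytic impulse response, and direct integration of
the mass-balance ODEs (`scipy.integrate.solve_ivp`, RK45, max step = one
sample interval, rtol 1e-8) — which serve as mutual oracles in the tests
(agreement < 0.5% relative L2 on the standard synthetic AIF).  The
two-compartment exchange impulse response is computed by
eigendecomposition of the 2×2 state matrix; the uptake model is its
no-backflux limit and the PS = 0 vascular monoexponential is shared by
both, which the tests exploit as nested-model checks.

Discrete convolution uses trapezoidal quadrature on a uniform grid
(half-weights on the end samples); non-uniform grids are resampled by
linear interpolation first.  The saturation-recovery R1 fit assumes ideal
saturation, S(TD) = M0(1 − e^(−TD·R1)), with delays given in ms.

## Deconvolution

`gcv_deconvolve` builds the lower-triangular convolution matrix with the
same trapezoid weighting (so the forward operator and the reported
trapezoidal area of the recovered response are mutually consistent — with
rectangle weights a dispersion-free response would lose half its first
sample and PA would be biased low by up to 50%).  Tikhonov regularization
on the identity operator is solved through the SVD; the regularization
weight λ is chosen at the minimum of the GCV score
n·‖y − ŷ_λ‖² / (n − Σf_i(λ))² over 50 log-spaced values in
[1e−6, 1e2].  PA is the trapezoidal area of the recovered impulse
response.  On noiseless scale-only data GCV drives λ to the bottom of the
grid and PA is recovered to < 0.1%; with an exponential dispersion kernel
and 1% noise the recovery error is a few percent.

## Fitting and model selection

Kinetic fits use bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`, xtol = ftol = gtol =
1e−12, max 2000 evaluations) with non-negativity bounds and volume
fractions capped at 100 mL/100 mL.  Default initial values follow the
worked analysis: F_p = 2 mL/min/100 mL, PS = 0.2 mL/min/100 mL, v_p = 10
mL/100 mL, v_e = 20 mL/100 mL (Tofts: Ktrans = 0.1 min⁻¹, v_e = 20
mL/100 mL).  Every `FitResult` records the free/fixed split, the initial
values, the RSS and the optimizer diagnostics, so rendered reports can
state the optimization configuration.  Non-identifiable input (zero AIF)
returns `success=False` with diagnostics rather than raising.

Model selection uses the least-squares AIC, n·ln(RSS/n) + 2k, with k the
number of free parameters and no small-sample correction (the most common
convention for least-squares fits; with n ≈ 200 points the correction
term is negligible).  A perfect fit is floored at RSS/n = 1e−12 to keep
the logarithm finite; exact ties go to the candidate with fewer free
parameters.

## Pipeline execution

`execute_pipeline` walks the document top to bottom and depth-first:
SetEqual statements bind values into the environment before a node's
children run; child processes run in document order; a process whose code
has a registered implementation consumes its InputQuantity elements in
order (literal `numericValue`s directly, otherwise by environment lookup
keyed on the serialized code) and publishes its OutputQuantity codes.  A
process without an implementation is accepted if nested children did the
work (derived/composite processes) and otherwise raises a structured
"unimplemented process" error naming the code.  For the model-fitting
process the convention is: first curve input = tissue response, second =
arterial input; parameter-coded inputs with a `type` attribute carry
initial (free) or fixed values; the Model child names the model.
Compartment suffixes keep concurrent streams apart (`Q.EL1.003.[t]` vs
`Q.EL1.003.[a,b]`).

The number of baseline dynamics is deliberately a required argument
throughout (`baseline_mean`, `build_roi_pipeline`): published practice
varies between 15 and 20, so the choice must be stated rather than
defaulted.

## Synthetic data

The AIF is a deterministic population-shaped curve: a gamma-variate first
pass (arrival 30 s, shape 3, time scale 8 s, peak 6 mM) plus an
exponentially recovering washout tail at 40% of the peak with a 300 s
decay — typical of a standard-dose bolus at a few-second dynamic
sampling.  Tissue curves are forward-model outputs plus seeded additive
Gaussian noise.

The default phantom is 16×16×2 voxels with 211 time points at 2 s
(420 s), desk-scale by construction: a background margin, two Tofts
tissue regions (Ktrans = 0.25 min⁻¹, v_e = 20 mL/100 mL — tumor-like;
Ktrans = 0.05 min⁻¹, v_e = 15 mL/100 mL — white-matter-like) and an
arterial stripe carrying the AIF.  The signal model is linear in R1:
S = S_BL(1 + ΔR1/R10) with ΔR1 = r1·C, S_BL = 100 a.u., R10 = 1 s⁻¹,
relaxivity r1 = 4.5 s⁻¹mM⁻¹.  Noise is additive Gaussian on the signal
and the seed affects only the noise, never the ground truth.

Limitations: the generator emulates none of the MR physics that
complicates real data — no Rician noise floor, no saturation of the
arterial signal, no B1/coil inhomogeneity, no motion, no water-exchange
effects, and the same linear signal model is used for generation and
analysis.  Passing recovery tests therefore demonstrates correctness of
the computational chain (encoding → validation → execution → fitting),
not robustness to acquisition physics.

## Problem sizes

Simulation-based checks use the standard 211-point grid with 100 seeded
repeats for parameter recovery and model selection, 200 repeats for the
saturation-recovery noise study, and 10,000 fuzz-generated identifiers
for the grammar round-trip — sizes chosen so the full suite and the
acceptance script each complete in seconds while keeping Monte-Carlo
rates stable to a few percent.
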