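# Methods

## Model structure

The cohort is a hypothetical LGS patient with drug-resistant seizures
(failed ≥2 anti-seizure medications) who is a candidate for palliative
surgery via either corpus callosotomy (CC) or vagus nerve stimulation
(VNS). The horizon is one year, the perspective healthcare-payer, costs
undiscounted 2015-era USD; baseline (non-procedural) healthcare
utilization is assumed equal across arms and omitted.

Each arm is a two-level tree: a complication chance node crossed with a
seizure-outcome chance node, treated as **independent**. The published
description does not pin down whether complications were nested under
seizure outcomes or vice versa, and gives no conditional probabilities;
under independence the expectation is order-invariant, so nesting is
cosmetic, and independence reproduces the reported expected costs to the
dollar. Each node carries a designated residual branch absorbing
`1 − Σ(explicit)`, clamped at a −1e−12 tolerance (anything more negative
is a construction error). Zero-probability complication branches are
pruned, so an arm without complications degenerates to the bare
three-outcome node.

Complication cost increments accrue regardless of seizure outcome;
complications interact with *effectiveness* only through the
effectiveness policy (below). This is the only split that reconciles the
reported cost column (which reflects every complication probability) with
the reported effectiveness column (which does not).

## Effectiveness policies

The stated outcome rule — "positive = >50% seizure reduction and no
complication" — contradicts the reported effectiveness values: CC's 0.63
is exactly `p_free + p_red = 0.16 + 0.47` with no complication discount,
while VNS's 0.48 equals `(0.052 + 0.441) · (1 − p_infection)`. Both
readings are therefore implemented explicitly and never blended:

- `strict`: every complication disqualifies ({infection, other_vns} /
  {deficit, reop}) — the literal rule;
- `reference` (default): {infection} / {} — the reconstruction that
  reproduces all four reported effectiveness values (0.48, 0.63, 0.53,
  0.80) at printed precision;
- `none`: no complication disqualifies.

Effectiveness is provably monotone strict ≤ reference ≤ none, which the
suite property-tests. Under `strict`, CC's base effectiveness is
`0.63 × 0.928 = 0.58464`, visibly inconsistent with the reported 0.63;
the reconciliation report quantifies this.

## Parameters

All inputs are `base/low/high` triples; probabilities are stored as
proportions, costs in USD. The bundled files carry the published
estimates: seizure outcomes per arm for all seizure types and for the
atonic subtype (the atonic scenario overlays only those four rows),
complication rates, and index-procedure costs (VNS $30 091, range
$20 000–40 000; CC $92 800, range $72 900–178 800). Infection and
reoperation are priced at the index procedure, per the source's stated
assumption.

Two complication costs ("other VNS complications", "permanent neurologic
deficit") have no published estimate. Each arm's expected cost is linear
in its own complication costs with a single unknown, so the reported
totals ($30 844, $98 991) identify them exactly:
`c_other = (30 844 − 30 091·1.024)/0.014 ≈ $2 201` and
`c_deficit = (98 991 − 92 800·1.066)/0.006 ≈ $11 033`, with ±$35.7 and
±$83.3 bands from the half-dollar rounding of the targets. The shipped
defaults are the round-dollar solution inside those bands, $2 200 and
$11 000; the calibration module re-derives all of this at run time, and a
planted-cost recovery property confirms the solve is exact on unrounded
totals.

The tabulated VNS seizure-freedom rate is 5.2%, but the reported
base-case ICER ($451 952) is consistent only with 5.0% (5.2% gives
$457 877, +1.3%). The default keeps the tabulated 5.2%; the 5.0% reading
is available as `--p-free-vns-override 0.050`, and the reconciliation
report scores every headline number under both readings and all three
policies.

## Comparison and sensitivity analyses

Strategies are ordered by expected cost; incremental columns are computed
against the previous non-dominated row; simple dominance is flagged even
though with two strategies extended dominance cannot arise. The ICER is
computed from unrounded expectations; rounding (whole dollars, 2-decimal
effectiveness, whole-percent incremental effectiveness) happens only in
the reporting layer.

One-way analyses record the CC-vs-VNS ICER with one parameter at each end
of its range. If an excursion removes CC's effectiveness gain the ICER is
undefined; the tornado then records the finite stand-in `λ − ΔNMB`
(which exceeds λ exactly when CC is not worth buying) and flags the
entry, keeping the diagram sortable. The **default tornado spans the ten
parameters with published base estimates**. The four complication costs
are tabulated without an estimate and their "ranges" are arbitrary wide
scans ($0–100 000 / $0–500 000), not uncertainty intervals around a base,
so a tornado bar centered on them is not meaningful; they remain fully
supported by `one_way` and are written by the pipeline as a separate
flagged wide-scan table. This choice also makes the ranking match the
qualitative finding that complication *rates* matter least: over the
ten estimate-bearing parameters the four complication rates have exactly
the four smallest spreads (207–21 200 USD, versus ≥134 000 for every
other parameter), whereas the wide-scan cost bars would interleave with
them (e.g. the $0–500 000 deficit-cost scan spreads ≈$20 000, the
reoperation-rate bar ≈$21 000).

The two-way analysis rasterizes the favored strategy (by NMB at λ) on a
0.005-step grid over both ranges and solves the frontier analytically:
ΔNMB is affine in each input, so the root along the y-axis is obtained
exactly from the two endpoint evaluations. The grid step therefore
affects only the raster; the suite checks that each column's raster flip
brackets the analytic threshold within one step. The published corner
reproduces: CC becomes favorable at a CC reduction rate ≥54.7% (≈55%)
when VNS reduction sits at its 32.3% floor, and at a VNS rate ≤33.7%
(≈34%) when CC sits at its 56% ceiling. Axis ranges are the published
parameter ranges, which reproduce that corner.

The device-replacement break-even uses an explicit cost-parity
definition: the smallest multiple of the replacement interval at which
cumulative pulse-generator costs meet the initial incremental cost
(`$40 000` every 5 years vs ΔC = $68 147 gives 10 years). The source
narrative sketches "approximately 20 years" for atonic seizures; no
definition we could state reproduces 20 from the printed inputs, so the
operation is documented and tested on its own terms and the 20-year
figure is not asserted.

## Synthetic data

The generator produces (a) random decision trees (depth ≤3, branching
≤4, Dirichlet branch probabilities, terminal costs uniform on
[0, 100 000], labels drawn from the model's outcome/complication
alphabet) whose ground truth is computed at generation time by the
enumeration oracle, with zero-probability branches and zero costs
injected at fixed rates so degenerate cases are exercised by
construction; and (b) parameter sets drawn uniformly within the published
ranges, rejection-sampled (cap 10 000) until the joint per-arm
constraints hold. All randomness flows through one explicitly seeded
generator; identical seeds reproduce identical objects bit-for-bit.

What this does *not* emulate: patient-level seizure trajectories,
correlation between parameters, time-varying effectiveness or recurrence,
QALY weights. Passing tests demonstrate internal correctness of the
arithmetic and reconstruction — not external validity of the published
inputs.

## Numerical choices

- Probability conservation at nodes: 1e−12 absolute; rollback vs
  enumeration agreement: 1e−10 relative.
- Tornado ties in spread break alphabetically; CE rows tie-break by name
  at equal cost.
- ICER at ΔE = 0 raises a distinct error; callers fall back to dominance
  by cost.
- Calibration residuals are recomputed through the actual tree evaluation
  (not the closed form) to guard against drift between the two.
- Problem sizes in the shipped diagnostics — 1 000 oracle trees, 500
  parameter draws, 25 recovery seeds — were chosen as comfortable
  saturation points for a desk-scale model whose every quantity is exact
  to machine precision; the whole pipeline runs in about a second.

## Known limitations

One-year horizon only (no discounting, by construction); two strategies
(extended dominance unreachable); no probabilistic sensitivity analysis
or acceptability curves; no QALY cost-utility layer; callosotomy
technique variants (anterior two-thirds vs complete, radiosurgical/laser)
are out of scope. Whether the original model truly used nonzero costs for
the two unreported complications cannot be confirmed; the calibration
makes that assumption explicit and falsifiable against the reported
totals.
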