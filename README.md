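# lgscea

Decision-analytic cost-effectiveness comparison of the two palliative
surgical options for drug-resistant seizures in Lennox-Gastaut syndrome
(LGS): **corpus callosotomy (CC)** versus **vagus nerve stimulation
(VNS)**, over a one-year horizon from a US healthcare perspective.

The package is for health-economics and epilepsy-surgery researchers who
want to reproduce, stress, or extend the published one-year comparison:
every input is an editable CSV row, every analysis is a library function,
and a CLI re-runs the whole study in about a second.

## The model

Each strategy arm is a small decision tree: an arm-specific complication
chance node (VNS: infection, other device complications; CC: permanent
neurologic deficit, reoperation; plus a residual "none" branch) crossed
independently with a seizure-outcome chance node (seizure freedom, >50%
seizure reduction, no improvement — *discrete* outcomes, the freedom rate
having been subtracted from the inclusive responder rate). Rolling the
tree back gives, per arm,

- expected one-year cost `C = c_index + Σ_k p_k · c_k` over complications `k`, and
- effectiveness `E = P(positive outcome)`, where a positive outcome is
  seizure freedom or >50% reduction without a disqualifying complication.

Strategies are compared by the incremental cost-effectiveness ratio
`ICER = ΔC / ΔE` (USD per positive seizure outcome gained) and by net
monetary benefit `NMB = λ·E − C` at willingness-to-pay `λ` (default
$200 000). Deterministic sensitivity analyses vary each parameter across
its published range (one-way/tornado) or two parameters jointly
(two-way), where the VNS-vs-CC frontier is solved in closed form because
`C` and `E` are affine in every single input. A calibration module
recovers the two complication costs that have no published estimate by
inverting the per-arm linear cost equations against the reported expected
strategy costs. Which complications disqualify a positive outcome is an
explicit `EffectivenessPolicy` (`strict`, `reference`, `none`); the
`reference` preset (VNS infection only) is the reconstruction that
reproduces the reported effectiveness values and is the default — see
`docs/methods.md`.

## Worked example

```python
from lgscea import (EffectivenessPolicy, build_ce_table, load_parameters)
from lgscea.sensitivity import evaluate_arms

pi, ci = load_parameters()                      # bundled base case
policy = EffectivenessPolicy.preset("reference")
table = build_ce_table(sorted(evaluate_arms(pi, ci, policy).items()))
print(table.to_dataframe().to_string(index=False))
```

prints

```
strategy    cost  incr_cost  effectiveness  incr_effectiveness     icer dominance  incr_effectiveness_pct
     VNS 30844.0        NaN           0.48                 NaN      NaN                               NaN
      CC 98991.0    68147.0           0.63                0.15 457877.0                              15.0
```

i.e. VNS costs $30 844 per patient with a 0.48 chance of a positive
seizure outcome; CC costs $68 147 more and raises that chance by 15
percentage points, at $457 877 per positive outcome gained (the
tabulated 5.2% VNS seizure-freedom rate; the 5.0% reading reproduces the
reported $451 952 — pass `--p-free-vns-override 0.050`). At a $200 000
willingness to pay, VNS is preferred in the base case, in the
atonic-seizure scenario (ICER ≈ $250 555), and at nearly every point of
the two-way sensitivity grid: CC becomes favorable only when its >50%
seizure-reduction rate exceeds ~55% while the VNS rate falls below ~34%.

The same analysis from the shell:

```
lgscea run --scenario atonic --out results/
lgscea owsa --out results/           # tornado CSV
lgscea twsa --grid-step 0.005 --out results/
lgscea calibrate --out results/     # solve the two unreported costs
lgscea synth --seed 1               # synthetic problems + recovery report
```

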