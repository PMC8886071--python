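"""Clinical and cost inputs for the callosotomy-vs-VNS decision model.

The model compares two palliative surgical strategies for drug-resistant
Lennox-Gastaut seizures — corpus callosotomy (CC) and vagus nerve
stimulation (VNS) — over a one-year horizon from a healthcare perspective.
Every input is a :class:`ParamRange` (base estimate plus a low/high
sensitivity range): eight probabilities (seizure freedom, >50% seizure
reduction, and procedure-specific complication rates per arm) and six
costs (index procedures and complication cost increments, USD).

Seizure freedom and >50% reduction are *discrete* outcomes: the freedom
rate is subtracted from the inclusive reduction rate so that the two
probabilities may be added (see :func:`subtract_freedom_from_reduction`).

Parameter files are plain CSV (``name,kind,arm,base,low,high``, ``#``
comments allowed) so the study can be re-run with edited values; the
bundled files carry the default base case and the atonic-seizure scenario.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import pandas as pd

__all__ = [
    "ParamRange",
    "ProbabilityInputs",
    "CostInputs",
    "ScenarioLabel",
    "SCENARIOS",
    "PROBABILITY_NAMES",
    "COST_NAMES",
    "SEIZURE_PROBABILITY_NAMES",
    "COMPLICATION_PROBABILITY_NAMES",
    "UNREPORTED_COST_NAMES",
    "ParameterError",
    "ValidationError",
    "subtract_freedom_from_reduction",
    "validate",
    "load_parameters",
    "write_parameters",
    "get_param",
    "set_param",
    "default_parameter_dir",
]

ScenarioLabel = Literal["base", "atonic"]
SCENARIOS: tuple[ScenarioLabel, ...] = ("base", "atonic")

SEIZURE_PROBABILITY_NAMES = ("p_red_vns", "p_free_vns", "p_red_cc", "p_free_cc")
COMPLICATION_PROBABILITY_NAMES = ("p_infection", "p_other_vns", "p_deficit", "p_reop")
PROBABILITY_NAMES = SEIZURE_PROBABILITY_NAMES + COMPLICATION_PROBABILITY_NAMES
COST_NAMES = (
    "c_vns_index",
    "c_cc_index",
    "c_infection",
    "c_other_vns",
    "c_deficit",
    "c_reop",
)
#: Complication costs with no published estimate (tabulated as "N/A"); their
#: bundled bases come from calibration and their ranges are wide scans.
UNREPORTED_COST_NAMES = ("c_infection", "c_other_vns", "c_deficit", "c_reop")

_ARM_OF = {name: ("vns" if name.endswith("vns") or "infection" in name else "cc")
           for name in PROBABILITY_NAMES + COST_NAMES}
_ARM_OF.update(p_red_vns="vns", p_free_vns="vns", p_red_cc="cc", p_free_cc="cc")


class ParameterError(ValueError):
    """A parameter file could not be loaded (missing/unknown rows)."""


class ValidationError(ValueError):
    """One or more parameter invariants are violated.

    ``violations`` lists every failure, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class ParamRange:
    """A model input: base-case value plus low/high sensitivity bounds."""

    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                [f"range disordered: low={self.low} base={self.base} high={self.high}"]
            )

    def with_base(self, value: float) -> "ParamRange":
        return ParamRange(value, min(self.low, value), max(self.high, value))

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class ProbabilityInputs:
    """Per-arm seizure-outcome and complication probabilities.

    ``p_red_*`` is the discrete ">50% reduction but not seizure-free"
    probability; ``p_free_*`` is seizure freedom. Complications:
    ``p_infection``/``p_other_vns`` (VNS) and ``p_deficit``/``p_reop`` (CC).
    """

    p_red_vns: ParamRange
    p_free_vns: ParamRange
    p_red_cc: ParamRange
    p_free_cc: ParamRange
    p_infection: ParamRange
    p_other_vns: ParamRange
    p_deficit: ParamRange
    p_reop: ParamRange


@dataclass(frozen=True)
class CostInputs:
    """Index-procedure costs and complication cost increments (USD)."""

    c_vns_index: ParamRange
    c_cc_index: ParamRange
    c_infection: ParamRange
    c_other_vns: ParamRange
    c_deficit: ParamRange
    c_reop: ParamRange


def subtract_freedom_from_reduction(
    reduction_inclusive: float, freedom: float
) -> float:
    """Convert an inclusive >50%-reduction rate into a discrete one.

    Published responder rates usually count seizure-free patients inside the
    ">50% reduction" fraction; the model needs the two as mutually exclusive
    outcomes, so the freedom rate is subtracted out.
    """
    if not (0.0 <= freedom <= reduction_inclusive <= 1.0):
        raise ValueError(
            f"inconsistent rates: freedom={freedom} must lie in "
            f"[0, reduction_inclusive={reduction_inclusive}] within [0, 1]"
        )
    return reduction_inclusive - freedom


def _iter_params(
    pi: ProbabilityInputs, ci: CostInputs
) -> Iterator[tuple[str, str, ParamRange]]:
    for f in fields(pi):
        yield f.name, "probability", getattr(pi, f.name)
    for f in fields(ci):
        yield f.name, "cost", getattr(ci, f.name)


def validate(pi: ProbabilityInputs, ci: CostInputs) -> list[str]:
    """Check every invariant; return the (possibly empty) list of violations."""
    out: list[str] = []
    for name, kind, pr in _iter_params(pi, ci):
        if not (pr.low <= pr.base <= pr.high):
            out.append(f"{name}: range disordered (low {pr.low}, base {pr.base}, high {pr.high})")
        if kind == "probability":
            if pr.low < 0 or pr.high > 1:
                out.append(f"{name}: probability outside [0, 1] (low {pr.low}, high {pr.high})")
        else:
            if pr.low < 0:
                out.append(f"{name}: negative cost (low {pr.low})")
    for arm in ("vns", "cc"):
        free = getattr(pi, f"p_free_{arm}").base
        red = getattr(pi, f"p_red_{arm}").base
        if free + red > 1.0:
            out.append(f"{arm}: p_free + p_red > 1 ({free} + {red})")
    if pi.p_infection.base + pi.p_other_vns.base >= 1.0:
        out.append("vns: complication probabilities sum to >= 1")
    if pi.p_deficit.base + pi.p_reop.base >= 1.0:
        out.append("cc: complication probabilities sum to >= 1")
    return out


def default_parameter_dir() -> Path:
    """Directory holding the bundled parameter files."""
    return Path(resources.files("lgscea").joinpath("data"))  # type: ignore[arg-type]


def _read_table(path: Path) -> dict[str, tuple[str, ParamRange]]:
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"name", "kind", "base", "low", "high"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, tuple[str, ParamRange]] = {}
    for row in df.itertuples(index=False):
        try:
            pr = ParamRange(float(row.base), float(row.low), float(row.high))
        except ValidationError as exc:
            raise ValidationError([f"{row.name}: {v}" for v in exc.violations]) from exc
        out[str(row.name)] = (str(row.kind), pr)
    return out


def load_parameters(
    path: str | Path | None = None, scenario: ScenarioLabel = "base"
) -> tuple[ProbabilityInputs, CostInputs]:
    """Load and validate a parameter set.

    ``path`` is a directory containing ``probabilities_base.csv``,
    ``probabilities_atonic.csv`` and ``costs.csv`` (default: the bundled
    files). The atonic scenario overlays only the four seizure-outcome
    probabilities on the base set.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    root = Path(path) if path is not None else default_parameter_dir()
    rows = _read_table(root / "probabilities_base.csv")
    if scenario == "atonic":
        overlay = _read_table(root / "probabilities_atonic.csv")
        unknown = set(overlay) - set(SEIZURE_PROBABILITY_NAMES)
        if unknown:
            raise ParameterError(
                f"atonic overlay may only change seizure-outcome probabilities, got {sorted(unknown)}"
            )
        rows.update(overlay)
    rows.update(_read_table(root / "costs.csv"))

    def pick(name: str, kind: str) -> ParamRange:
        if name not in rows:
            raise ParameterError(f"missing parameter {name!r} in {root}")
        got_kind, pr = rows[name]
        if got_kind != kind:
            raise ParameterError(f"parameter {name!r} has kind {got_kind!r}, expected {kind!r}")
        return pr

    pi = ProbabilityInputs(**{n: pick(n, "probability") for n in PROBABILITY_NAMES})
    ci = CostInputs(**{n: pick(n, "cost") for n in COST_NAMES})
    violations = validate(pi, ci)
    if violations:
        raise ValidationError(violations)
    return pi, ci


def write_parameters(
    pi: ProbabilityInputs, ci: CostInputs, directory: str | Path
) -> None:
    """Write a parameter set back to the three-file CSV layout.

    Uses ``repr`` float formatting so a reload reproduces every field
    bit-identically. The atonic overlay file is written with the current
    seizure probabilities (useful when round-tripping a scenario set).
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)

    def dump(names: tuple[str, ...], obj, kind: str, fname: str) -> None:
        rec = [
            {
                "name": n,
                "kind": kind,
                "arm": _ARM_OF[n],
                "base": repr(getattr(obj, n).base),
                "low": repr(getattr(obj, n).low),
                "high": repr(getattr(obj, n).high),
            }
            for n in names
        ]
        pd.DataFrame(rec).to_csv(root / fname, index=False)

    dump(PROBABILITY_NAMES, pi, "probability", "probabilities_base.csv")
    dump(SEIZURE_PROBABILITY_NAMES, pi, "probability", "probabilities_atonic.csv")
    dump(COST_NAMES, ci, "cost", "costs.csv")


def get_param(pi: ProbabilityInputs, ci: CostInputs, name: str) -> ParamRange:
    if name in PROBABILITY_NAMES:
        return getattr(pi, name)
    if name in COST_NAMES:
        return getattr(ci, name)
    raise KeyError(f"unknown parameter {name!r}")


def set_param(
    pi: ProbabilityInputs, ci: CostInputs, name: str, value: float | ParamRange
) -> tuple[ProbabilityInputs, CostInputs]:
    """Return a copy of the inputs with one parameter replaced.

    A bare float replaces the base value (widening the range if needed);
    a :class:`ParamRange` replaces the whole entry.
    """
    current = get_param(pi, ci, name)
    pr = current.with_base(value) if isinstance(value, (int, float)) else value
    if name in PROBABILITY_NAMES:
        return dataclasses.replace(pi, **{name: pr}), ci
    return pi, dataclasses.replace(ci, **{name: pr})
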