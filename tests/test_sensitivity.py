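"""One-way (tornado) and two-way deterministic sensitivity analyses."""

import dataclasses

import numpy as np
import pytest

from lgscea import (
    ALL_PARAMETERS,
    CEAConfig,
    ESTIMATED_PARAMETERS,
    ParamRange,
    one_way,
    run_scenario,
    set_param,
    threshold_value,
    tornado,
    two_way,
)
from lgscea.parameters import COMPLICATION_PROBABILITY_NAMES
from lgscea.sensitivity import evaluate_arms


def _closed_form_icer(pi, ci, p_red_vns=None, p_red_cc=None):
    """Independent closed-form pipeline (no tree code) for cross-checks."""
    rv = p_red_vns if p_red_vns is not None else pi.p_red_vns.base
    rc = p_red_cc if p_red_cc is not None else pi.p_red_cc.base
    cost_vns = (
        ci.c_vns_index.base
        + pi.p_infection.base * ci.c_infection.base
        + pi.p_other_vns.base * ci.c_other_vns.base
    )
    cost_cc = (
        ci.c_cc_index.base
        + pi.p_deficit.base * ci.c_deficit.base
        + pi.p_reop.base * ci.c_reop.base
    )
    eff_vns = (rv + pi.p_free_vns.base) * (1 - pi.p_infection.base)
    eff_cc = rc + pi.p_free_cc.base
    return (cost_cc - cost_vns) / (eff_cc - eff_vns)


def test_one_way_p_red_vns_endpoints_match_closed_form(base_inputs, reference_policy):
    pi, ci = base_inputs
    entry = one_way("p_red_vns", pi, ci, reference_policy)
    assert entry.metric_at_low == pytest.approx(
        _closed_form_icer(pi, ci, p_red_vns=0.323), rel=1e-12
    )
    assert entry.metric_at_high == pytest.approx(
        _closed_form_icer(pi, ci, p_red_vns=0.560), rel=1e-12
    )
    assert entry.flag == ""


def test_one_way_infection_smaller_than_any_seizure_probability(base_inputs, reference_policy):
    pi, ci = base_inputs
    infection = one_way("p_infection", pi, ci, reference_policy).spread
    for name in ("p_red_vns", "p_free_vns", "p_red_cc", "p_free_cc"):
        assert infection < one_way(name, pi, ci, reference_policy).spread


def test_one_way_degenerate_range_has_zero_spread(base_inputs, reference_policy):
    pi, ci = base_inputs
    pi2 = dataclasses.replace(pi, p_red_vns=ParamRange(0.441, 0.441, 0.441))
    assert one_way("p_red_vns", pi2, ci, reference_policy).spread == 0.0


def test_one_way_unknown_parameter(base_inputs, reference_policy):
    with pytest.raises(KeyError):
        one_way("p_bogus", *base_inputs, reference_policy)


def test_tornado_ranking(base_inputs, reference_policy):
    entries = tornado(*base_inputs, reference_policy)
    assert [e.parameter for e in entries[:1]] == ["p_red_vns"]
    assert set(e.parameter for e in entries[-4:]) == set(COMPLICATION_PROBABILITY_NAMES)
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)


def test_tornado_endpoints_equal_direct_one_way(base_inputs, reference_policy):
    """No caching drift: tornado rows equal fresh one_way evaluations."""
    entries = {e.parameter: e for e in tornado(*base_inputs, reference_policy)}
    for name in ("p_red_cc", "c_cc_index", "p_reop"):
        assert entries[name] == one_way(name, *base_inputs, reference_policy)


def test_tornado_collapsed_ranges_sort_alphabetically(base_inputs, reference_policy):
    from lgscea.parameters import get_param

    pi, ci = base_inputs
    for name in ESTIMATED_PARAMETERS:
        pr = get_param(pi, ci, name)
        pi, ci = set_param(pi, ci, name, ParamRange(pr.base, pr.base, pr.base))
    entries = tornado(pi, ci, reference_policy)
    assert all(e.spread == 0.0 for e in entries)
    assert [e.parameter for e in entries] == sorted(ESTIMATED_PARAMETERS)


def test_tornado_all_parameters_flags_wide_scans(base_inputs, reference_policy):
    entries = tornado(*base_inputs, reference_policy, parameters=ALL_PARAMETERS)
    assert len(entries) == 14
    flags = {e.parameter: e.flag for e in entries}
    for name in ("c_infection", "c_other_vns", "c_deficit", "c_reop"):
        assert flags[name] == "unreported_base"


def test_icer_monotone_in_reduction_rates(base_inputs, reference_policy):
    """ICER falls as CC responds better, rises as VNS responds better."""
    pi, ci = base_inputs

    def icer_at(name, v):
        pi2, ci2 = set_param(pi, ci, name, v)
        res = evaluate_arms(pi2, ci2, reference_policy)
        return (res["cc"].expected_cost - res["vns"].expected_cost) / (
            res["cc"].expected_effectiveness - res["vns"].expected_effectiveness
        )

    cc_vals = [icer_at("p_red_cc", v) for v in np.linspace(0.38, 0.56, 7)]
    assert all(a >= b for a, b in zip(cc_vals, cc_vals[1:]))
    vns_vals = [icer_at("p_red_vns", v) for v in np.linspace(0.323, 0.56, 7)]
    assert all(a <= b for a, b in zip(vns_vals, vns_vals[1:]))


@pytest.fixture(scope="module")
def grid(base_inputs, reference_policy):
    return two_way("p_red_cc", "p_red_vns", *base_inputs, reference_policy,
                   CEAConfig(wtp=200_000.0), step=0.005)


def test_two_way_cc_corner(grid):
    """CC is favored only at high CC response and low VNS response."""
    cc_points = [
        (x, y)
        for i, y in enumerate(grid.y_values)
        for j, x in enumerate(grid.x_values)
        if grid.favored[i][j] == "cc"
    ]
    assert cc_points, "CC must be favored somewhere in the ranges"
    assert all(x > 0.545 for x, _y in cc_points)
    assert all(y < 0.34 for _x, y in cc_points)
    # VNS favored at every grid point with p_red_cc <= 0.54
    for i in range(len(grid.y_values)):
        for j, x in enumerate(grid.x_values):
            if x <= 0.54:
                assert grid.favored[i][j] == "vns"


def test_two_way_single_switch_per_column(grid):
    """The model is affine in each probability: at most one flip per column."""
    for j in range(len(grid.x_values)):
        column = [grid.favored[i][j] for i in range(len(grid.y_values))]
        flips = sum(a != b for a, b in zip(column, column[1:]))
        assert flips <= 1


def test_contour_brackets_grid_switch(grid):
    """The analytic frontier sits within one step of each raster flip."""
    contour = dict(grid.contour)
    for j, x in enumerate(grid.x_values):
        column = [grid.favored[i][j] for i in range(len(grid.y_values))]
        switches = [i for i, (a, b) in enumerate(zip(column, column[1:])) if a != b]
        if x not in contour:
            assert not switches
            continue
        y_star = contour[x]
        assert switches, f"analytic threshold at x={x} but uniform column"
        i = switches[0]
        assert grid.y_values[i] - 1e-12 <= y_star <= grid.y_values[i + 1] + 1e-12


def test_two_way_zero_wtp_prefers_cheaper_everywhere(base_inputs, reference_policy):
    g = two_way("p_red_cc", "p_red_vns", *base_inputs, reference_policy,
                CEAConfig(wtp=0.0), step=0.02)
    assert all(cell == "vns" for row in g.favored for cell in row)
    assert g.contour == ()


def test_two_way_rejects_bad_arguments(base_inputs, reference_policy):
    with pytest.raises(ValueError):
        two_way("p_red_cc", "p_red_cc", *base_inputs, reference_policy)
    with pytest.raises(ValueError):
        two_way("p_red_cc", "p_red_vns", *base_inputs, reference_policy, step=0.0)


def test_threshold_value_is_exact_root(base_inputs, reference_policy):
    pi, ci = base_inputs
    pi2, ci2 = set_param(pi, ci, "p_red_vns", 0.323)
    t = threshold_value("p_red_cc", pi2, ci2, reference_policy, 200_000.0)
    # verify by direct NMB difference at the root (affine => exact)
    pi3, ci3 = set_param(pi2, ci2, "p_red_cc", t)
    res = evaluate_arms(pi3, ci3, reference_policy)
    d_nmb = (200_000.0 * res["cc"].expected_effectiveness - res["cc"].expected_cost) - (
        200_000.0 * res["vns"].expected_effectiveness - res["vns"].expected_cost
    )
    assert d_nmb == pytest.approx(0.0, abs=1e-6)


def test_run_scenario_consistency(base_inputs, reference_policy):
    from lgscea import build_ce_table

    base_table = run_scenario("base", reference_policy)
    direct = build_ce_table(sorted(evaluate_arms(*base_inputs, reference_policy).items()))
    assert base_table.rows == direct.rows
    atonic = run_scenario("atonic", reference_policy).to_dataframe()
    assert atonic.loc[1, "effectiveness"] == pytest.approx(0.80)
    assert atonic.loc[0, "effectiveness"] == pytest.approx(0.53)
    assert atonic.loc[1, "incr_effectiveness_pct"] == 27
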