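import numpy as np
import pytest

from ceatree import ModelError, one_way, solve_threshold, tornado, two_way
from ceatree.sensitivity import base_roles, evaluate_output

WTP = 12876.0


@pytest.fixture(scope="module")
def roles(acl_model):
    model, params = acl_model
    return base_roles(model, params)


class TestOneWay:
    def test_base_roles_assign_conservative_as_reference(self, roles):
        assert roles == ("Conservative treatment", "Early ACLR")

    def test_single_point_grid_equals_base_case(self, acl_model):
        model, params = acl_model
        base = params["u_stable_aclr"].base
        ((v, out),) = one_way(model, params, "u_stable_aclr", [base], output="icer")
        ref, comp = base_roles(model, params)
        assert out == evaluate_output(model, params, "icer", ref, comp)

    def test_icer_decreases_as_post_surgery_utility_rises(self, acl_model):
        model, params = acl_model
        grid = np.linspace(0.82, 0.95, 8)
        outs = [o for _, o in one_way(model, params, "u_stable_aclr", grid, "icer")]
        assert all(a > b for a, b in zip(outs, outs[1:]))

    def test_irrelevant_parameter_gives_constant_output(self, acl_model):
        model, params = acl_model
        outs = [o for _, o in one_way(model, params, "u_baseline", [0.55, 0.61, 0.67], "icer")]
        assert outs[0] == outs[1] == outs[2]

    def test_unknown_parameter_and_kind_bounds_rejected(self, acl_model):
        model, params = acl_model
        with pytest.raises(ModelError, match="unknown parameter"):
            one_way(model, params, "nope", [0.5])
        with pytest.raises(ModelError, match="outside probability bounds"):
            one_way(model, params, "p_delayed_aclr", [1.4])


class TestTwoWay:
    def test_one_by_one_grid_is_base_case(self, acl_model):
        model, params = acl_model
        ref, comp = base_roles(model, params)
        base = evaluate_output(model, params, "nmb_diff", ref, comp)
        m = two_way(model, params, "u_stable_aclr", "c_aclr_direct",
                    [params["u_stable_aclr"].base], [params["c_aclr_direct"].base],
                    output="nmb_diff")
        assert m.shape == (1, 1) and m[0, 0] == base

    def test_row_at_base_matches_one_way_slice(self, acl_model):
        model, params = acl_model
        grid_a = [0.84, 0.86, 0.88]
        m = two_way(model, params, "u_stable_aclr", "p_delayed_aclr",
                    grid_a, [params["p_delayed_aclr"].base], output="nmb_diff")
        ow = one_way(model, params, "u_stable_aclr", grid_a, output="nmb_diff")
        assert m[:, 0] == pytest.approx([o for _, o in ow], rel=1e-12)

    def test_monotone_in_each_argument(self, acl_model):
        model, params = acl_model
        # higher post-ACLR utility and lower ACLR cost both favour early surgery
        m = two_way(model, params, "u_stable_aclr", "c_aclr_direct",
                    np.linspace(0.84, 0.88, 4), np.linspace(2400.0, 3400.0, 4),
                    output="nmb_diff")
        assert (np.diff(m, axis=0) > 0).all()
        assert (np.diff(m, axis=1) < 0).all()


class TestTornado:
    def test_entries_match_one_way_endpoints_exactly(self, acl_model):
        model, params = acl_model
        entries = tornado(model, params, output="nmb_diff")
        ref, comp = base_roles(model, params)
        for e in entries[:5]:
            pts = one_way(model, params, e.parameter, [e.low, e.high], "nmb_diff", ref, comp)
            assert (e.output_low, e.output_high) == (pts[0][1], pts[1][1])

    def test_sorted_descending_with_zero_width_last(self, acl_model):
        from ceatree.sensitivity import default_range

        model, params = acl_model
        ranges = {name: default_range(params, name) for name in params}
        ranges["n_rehab_weeks"] = (36.0, 36.0)  # pinned: zero-width range
        entries = tornado(model, params, ranges=ranges, output="nmb_diff")
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)
        fixed = next(e for e in entries if e.parameter == "n_rehab_weeks")
        assert fixed.spread == 0.0
        assert entries[-1].spread == 0.0

    def test_cost_and_crossover_parameters_outrank_utilities(self, acl_model):
        """The strategy choice is driven by treatment costs and the delayed-ACLR
        crossover rate, not by post-treatment quality of life."""
        model, params = acl_model
        entries = tornado(model, params, output="nmb_diff")
        top3 = {e.parameter for e in entries[:3]}
        assert top3 == {"p_delayed_aclr", "c_aclr_direct", "c_base_conserv"}
        rank = {e.parameter: i for i, e in enumerate(entries)}
        assert rank["u_stable_aclr"] > 2 and rank["u_stable_conserv"] > 2

    def test_range_not_bracketing_base_rejected(self, acl_model):
        model, params = acl_model
        with pytest.raises(ModelError, match="does not bracket"):
            tornado(model, params, ranges={"u_stable_aclr": (0.87, 0.90)})


class TestThreshold:
    def test_post_surgery_utility_threshold(self, acl_model):
        """Early ACLR becomes cost-effective at the WTP once its utility exceeds
        u_conserv + deltaCost/WTP ~ 0.8858, i.e. 0.89 at two decimals."""
        model, params = acl_model
        res = solve_threshold(model, params, "u_stable_aclr", WTP, (0.82, 0.95), "icer")
        assert res.converged
        assert res.threshold == pytest.approx(0.81 + 976 / WTP, abs=5e-5)
        assert round(res.threshold, 2) == 0.89
        assert res.direction == "above"

    def test_linear_model_closed_form(self, acl_model):
        # NMB difference is affine in the ACLR direct cost: solve for nmb_diff = 0
        model, params = acl_model
        ref, comp = base_roles(model, params)
        f0 = evaluate_output(model, params.with_base({"c_aclr_direct": 0.0}),
                             "nmb_diff", ref, comp)
        f1 = evaluate_output(model, params.with_base({"c_aclr_direct": 1000.0}),
                             "nmb_diff", ref, comp)
        slope = (f1 - f0) / 1000.0
        expected = -f0 / slope
        res = solve_threshold(model, params, "c_aclr_direct", 0.0, (0.0, 4000.0), "nmb_diff")
        assert res.converged
        assert res.threshold == pytest.approx(expected, rel=1e-6)

    def test_no_sign_change_reports_diagnostics(self, acl_model):
        model, params = acl_model
        res = solve_threshold(model, params, "u_stable_aclr", WTP, (0.93, 0.95), "icer")
        assert not res.converged and res.threshold is None
        assert res.value_lo > 0 and res.value_hi > 0

    def test_agrees_with_grid_scan_oracle(self, acl_model):
        model, params = acl_model
        ref, comp = base_roles(model, params)
        grid = np.linspace(0.82, 0.95, 10_001)
        outs = np.array([
            evaluate_output(model, params.with_base({"u_stable_aclr": v}), "icer", ref, comp)
            for v in grid
        ])
        crossing = grid[np.argmax(outs < WTP)]
        res = solve_threshold(model, params, "u_stable_aclr", WTP, (0.82, 0.95), "icer")
        assert abs(res.threshold - crossing) <= (grid[1] - grid[0])
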