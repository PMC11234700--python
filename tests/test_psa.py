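import numpy as np
import pandas as pd
import pytest

from ceatree import (
    AnalysisSettings,
    Branch,
    DecisionModel,
    DecisionTree,
    DistributionSpec,
    ModelError,
    Parameter,
    ParameterSet,
    TreeNode,
    build_sampler,
    ce_plane,
    ceac,
    run_psa,
)
from ceatree.psa import PSASampleSet, beta_from_moments, gamma_from_moments
from scipy import stats


def _param(name, kind, base, family, se):
    return Parameter(name=name, kind=kind, base=base,
                     dist=DistributionSpec(family=family, mean=base, se=se))


class TestMomentFits:
    def test_beta_moment_recovery(self):
        a, b = beta_from_moments(0.41, 0.05)
        rng = np.random.default_rng(0)
        draws = rng.beta(a, b, size=100_000)
        assert draws.mean() == pytest.approx(0.41, abs=3 * 0.05 / np.sqrt(100_000) * 10)
        assert draws.std() == pytest.approx(0.05, rel=0.05)

    def test_gamma_moment_recovery(self):
        shape, scale = gamma_from_moments(2853.0, 570.0)
        rng = np.random.default_rng(0)
        draws = rng.gamma(shape, scale, size=100_000)
        assert draws.mean() == pytest.approx(2853.0, rel=0.01)
        assert draws.var() == pytest.approx(570.0**2, rel=0.05)

    def test_infeasible_beta_names_parameter(self):
        params = ParameterSet([_param("p_bad", "probability", 0.5, "beta", 0.6)])
        with pytest.raises(ModelError, match="p_bad"):
            build_sampler(params)

    def test_zero_se_is_degenerate(self):
        params = ParameterSet([_param("c", "cost", 100.0, "gamma", 0.0)])
        sampler = build_sampler(params)
        rng = np.random.default_rng(1)
        assert {sampler.sample(rng)["c"] for _ in range(10)} == {100.0}

    def test_sorted_name_order_independent_of_declaration(self):
        a = _param("alpha", "cost", 10.0, "gamma", 2.0)
        b = _param("beta_p", "probability", 0.4, "beta", 0.04)
        s1 = build_sampler(ParameterSet([a, b]))
        s2 = build_sampler(ParameterSet([b, a]))
        v1 = s1.sample(np.random.default_rng(7))
        v2 = s2.sample(np.random.default_rng(7))
        assert v1 == v2


def _coin_model(se=0.0):
    # two structurally identical strategies: outcomes tie bit-for-bit
    params = ParameterSet(
        [
            Parameter(name="p_hit", kind="probability", base=0.41,
                      dist=DistributionSpec(family="beta", mean=0.41, se=se)
                      if se else DistributionSpec(family="fixed")),
            Parameter(name="c_hit", kind="cost", base=100.0),
        ]
    )

    def arm(label):
        return TreeNode(label=label, kind="chance", branches=[
            Branch(prob="p_hit", node=TreeNode(label=f"{label}_h", kind="terminal",
                                               cost="c_hit", effect=0.8)),
            Branch(prob="complement", node=TreeNode(label=f"{label}_m", kind="terminal",
                                                    cost=0.0, effect=0.6)),
        ])

    tree = DecisionTree(label="coin", strategies=[arm("S1"), arm("S2")])
    model = DecisionModel(tree, AnalysisSettings())
    return model, params


class TestRunPSA:
    def test_all_fixed_reproduces_base_case(self):
        model, params = _coin_model(se=0.0)
        samples = run_psa(model, build_sampler(params), draws=5, seed=1)
        s1 = samples.data[samples.data.strategy == "S1"]
        assert s1.cost.to_numpy() == pytest.approx(41.0)
        assert s1.effect.to_numpy() == pytest.approx(0.682)

    def test_same_seed_bit_identical(self, acl_model):
        model, params = acl_model
        sampler = build_sampler(params)
        a = run_psa(model, sampler, draws=50, seed=42)
        b = run_psa(model, sampler, draws=50, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_cloud_mean_near_base_case(self, acl_model):
        model, params = acl_model
        samples = run_psa(model, build_sampler(params), draws=4000, seed=9)
        means = samples.data.groupby("strategy")[["cost", "effect"]].mean()
        assert means.loc["Early ACLR", "cost"] == pytest.approx(4266, rel=0.02)
        assert means.loc["Early ACLR", "effect"] == pytest.approx(0.86, rel=0.02)
        assert means.loc["Conservative treatment", "cost"] == pytest.approx(3290, rel=0.02)
        assert means.loc["Conservative treatment", "effect"] == pytest.approx(0.81, rel=0.02)

    def test_invalid_vectors_rejected_and_counted(self):
        # two wide beta probabilities on one chance node: their sum often
        # exceeds 1, leaving a negative complement that must be resampled
        params = ParameterSet(
            [
                _param("p_a", "probability", 0.6, "beta", 0.25),
                _param("p_b", "probability", 0.6, "beta", 0.25),
            ]
        )
        tree = DecisionTree(
            label="t",
            strategies=[
                TreeNode(label="S", kind="chance", branches=[
                    Branch(prob="p_a", node=TreeNode(label="a", kind="terminal",
                                                     cost=1.0, effect=0.1)),
                    Branch(prob="p_b", node=TreeNode(label="b", kind="terminal",
                                                     cost=2.0, effect=0.2)),
                    Branch(prob="complement", node=TreeNode(label="c", kind="terminal",
                                                            cost=3.0, effect=0.3)),
                ]),
            ],
        )
        model = DecisionModel(tree, AnalysisSettings())
        samples = run_psa(model, build_sampler(params), draws=200, seed=3)
        assert samples.rejections > 0
        assert samples.data.draw.nunique() == 200


class TestCEAC:
    def test_probabilities_sum_to_one_and_lie_in_unit_interval(self, acl_model):
        model, params = acl_model
        samples = run_psa(model, build_sampler(params), draws=500, seed=5)
        curve = ceac(samples, np.linspace(0, 40000, 21))
        total = curve.probabilities.sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)
        assert ((curve.probabilities >= 0) & (curve.probabilities <= 1)).all().all()

    def test_zero_wtp_rewards_cheaper_strategy(self, acl_model):
        model, params = acl_model
        samples = run_psa(model, build_sampler(params), draws=1000, seed=6)
        curve = ceac(samples, [0.0])
        costs = samples.pivot("cost")
        frac_cheaper = (costs["Conservative treatment"] < costs["Early ACLR"]).mean()
        assert curve.probability("Conservative treatment", 0.0) == pytest.approx(frac_cheaper)

    def test_large_wtp_rewards_more_effective_strategy(self, acl_model):
        model, params = acl_model
        samples = run_psa(model, build_sampler(params), draws=1000, seed=6)
        curve = ceac(samples, [1e9])
        effects = samples.pivot("effect")
        frac_better = (effects["Early ACLR"] > effects["Conservative treatment"]).mean()
        assert curve.probability("Early ACLR", 1e9) == pytest.approx(frac_better)

    def test_ties_split_equally(self):
        model, params = _coin_model(se=0.0)  # S1 and S2 have identical outcomes
        samples = run_psa(model, build_sampler(params), draws=10, seed=2)
        curve = ceac(samples, [0.0, 5000.0])
        assert np.allclose(curve.probabilities.to_numpy(), 0.5)

    def test_monotone_for_uniform_effect_gain(self):
        rows = []
        rng = np.random.default_rng(0)
        for d in range(400):
            e0 = rng.uniform(0.4, 0.6)
            rows.append((d, "ref", rng.uniform(900, 1100), e0))
            rows.append((d, "comp", rng.uniform(1000, 1400), e0 + rng.uniform(0.01, 0.1)))
        samples = PSASampleSet(400, 0, pd.DataFrame(
            rows, columns=["draw", "strategy", "cost", "effect"]))
        curve = ceac(samples, np.linspace(0, 50000, 26))
        p = curve.probabilities["comp"].to_numpy()
        assert (np.diff(p) >= -1e-12).all()


class TestCEPlane:
    def test_known_covariance_axis_ratio_and_orientation(self):
        rng = np.random.default_rng(12)
        xy = rng.multivariate_normal([0, 0], [[4.0, 0.0], [0.0, 1.0]], size=20_000)
        rows = [(d, "ref", 0.0, 0.0) for d in range(len(xy))]
        rows += [(d, "comp", float(c), float(e)) for d, (e, c) in enumerate(xy)]
        samples = PSASampleSet(len(xy), 0, pd.DataFrame(
            rows, columns=["draw", "strategy", "cost", "effect"]))
        _, ell = ce_plane(samples, "ref", "comp", level=0.95)
        assert ell.semi_axes[0] / ell.semi_axes[1] == pytest.approx(2.0, rel=0.05)
        # major axis along the effect axis (variance 4 on delta_effect)
        assert abs(np.sin(ell.orientation)) < 0.1

    def test_isotropic_semi_axes_match_chi2_quantile(self):
        rng = np.random.default_rng(3)
        xy = rng.multivariate_normal([0, 0], np.eye(2), size=20_000)
        rows = [(d, "ref", 0.0, 0.0) for d in range(len(xy))]
        rows += [(d, "comp", float(c), float(e)) for d, (e, c) in enumerate(xy)]
        samples = PSASampleSet(len(xy), 0, pd.DataFrame(
            rows, columns=["draw", "strategy", "cost", "effect"]))
        _, ell = ce_plane(samples, "ref", "comp", level=0.95)
        root = np.sqrt(stats.chi2.ppf(0.95, 2))  # ~ sqrt(5.991)
        assert ell.semi_axes[0] == pytest.approx(root, rel=0.03)
        assert ell.semi_axes[1] == pytest.approx(root, rel=0.03)

    def test_zero_variance_cloud_degenerates_with_warning(self):
        rows = []
        for d in range(10):
            rows.append((d, "ref", 100.0, 0.5))
            rows.append((d, "comp", 150.0, 0.6))
        samples = PSASampleSet(10, 0, pd.DataFrame(
            rows, columns=["draw", "strategy", "cost", "effect"]))
        with pytest.warns(UserWarning, match="degenerates"):
            cloud, ell = ce_plane(samples, "ref", "comp")
        assert ell.degenerate
        assert ell.contains(cloud[["delta_effect", "delta_cost"]].to_numpy()).all()

    def test_fewer_than_three_draws_yield_no_ellipse(self):
        rows = [(0, "ref", 1.0, 0.1), (0, "comp", 2.0, 0.2),
                (1, "ref", 1.5, 0.15), (1, "comp", 2.5, 0.25)]
        samples = PSASampleSet(2, 0, pd.DataFrame(
            rows, columns=["draw", "strategy", "cost", "effect"]))
        cloud, ell = ce_plane(samples, "ref", "comp")
        assert ell is None and len(cloud) == 2

    def test_level_must_be_fraction(self):
        model, params = _coin_model()
        samples = run_psa(model, build_sampler(params), draws=5, seed=1)
        with pytest.raises(ValueError):
            ce_plane(samples, "S1", "S2", level=1.0)
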