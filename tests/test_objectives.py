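import dataclasses

import numpy as np
import pytest

from immunoninf.objectives import (
    EndpointKind,
    ObjectiveNode,
    default_objective_tree,
    evaluate_objectives,
    planned_evaluable,
    simulate_power,
)
from immunoninf.proportion_stats import score_diff_ci
from immunoninf.synth import default_config, generate_trial
from test_synth import small_config


def override_antigen(cfg, name, **kw):
    return dataclasses.replace(
        cfg,
        antigens={**cfg.antigens, name: dataclasses.replace(cfg.antigens[name], **kw)},
    )


@pytest.fixture(scope="module")
def default_trial():
    return generate_trial(default_config(seed=12))


class TestTreeDefinition:
    def test_primaries_precede_secondaries(self):
        tree = default_objective_tree()
        last_primary = max(n.order_index for n in tree if n.tier == "primary")
        first_secondary = min(n.order_index for n in tree if n.tier == "secondary")
        assert last_primary < first_secondary

    def test_margin_sign_validation(self):
        with pytest.raises(ValueError):
            ObjectiveNode("bad", 1, EndpointKind.SRR_DIFF, ("measles",), margin=5.0)
        with pytest.raises(ValueError):
            ObjectiveNode("bad", 1, EndpointKind.GMC_RATIO, ("measles",), margin=1.5)


class TestEvaluation:
    def test_calibrated_trial_meets_every_node(self, default_trial):
        res = evaluate_objectives(default_trial)
        assert res.overall_success
        assert all(o.evaluated and o.met for o in res.nodes)

    def test_forced_primary_failure_closes_the_gate(self):
        # MMR-RIT mumps seroresponse forced ~10 points under the reference:
        # with a -5 point margin the sub-cohort-1 and -2 SRR primaries fail
        cfg = override_antigen(default_config(seed=13), "mumps", response_rate_override=(0.88, 1.0))
        res = evaluate_objectives(generate_trial(cfg))
        by_id = {o.node.id: o for o in res.nodes}
        assert by_id["P1-srr-coad"].met is False
        for o in res.nodes:
            if o.node.tier == "secondary":
                assert not o.evaluated
                assert o.met is None
        assert not res.overall_success

    def test_empty_secondary_tier_reduces_to_primary_conjunction(self, default_trial):
        tree = [n for n in default_objective_tree() if n.tier == "primary"]
        res = evaluate_objectives(default_trial, tree=tree)
        assert res.overall_success == all(o.met for o in res.nodes)

    def test_unknown_antigen_is_an_error(self, default_trial):
        tree = [
            ObjectiveNode("bad", 1, EndpointKind.SRR_DIFF, ("smallpox",), margin=-5.0)
        ]
        with pytest.raises(ValueError, match="smallpox"):
            evaluate_objectives(default_trial, tree=tree)

    def test_sequential_gate_blocks_later_secondaries(self):
        # fail the first secondary (varicella SRR) only; sequential mode must
        # leave the remaining secondaries unevaluated, primary mode must not
        cfg = override_antigen(default_config(seed=14), "VZV", response_rate_override=(0.80, 1.0))
        trial = generate_trial(cfg)
        res_p = evaluate_objectives(trial, gate_mode="primary")
        res_s = evaluate_objectives(trial, gate_mode="sequential")
        p = {o.node.id: o for o in res_p.nodes}
        s = {o.node.id: o for o in res_s.nodes}
        assert p["S1-vzv-srr"].met is False
        assert p["S2-dtap-brr"].evaluated
        assert not s["S2-dtap-brr"].evaluated


class TestPowerSimulation:
    def test_same_seed_reproduces_success_rate(self):
        cfg = small_config(n1=150)
        tree = [n for n in default_objective_tree() if n.id == "P1-srr-coad"]
        a = simulate_power(cfg, tree=tree, n_replicates=5, seed=3, keep_replicates=False)
        b = simulate_power(cfg, tree=tree, n_replicates=5, seed=3, keep_replicates=False)
        assert a.success_rate == b.success_rate

    def test_near_certain_regime(self):
        # both arms respond with probability ~1 at planned evaluable sizes
        cfg = small_config(n1=0, n2=876)
        tree = [n for n in default_objective_tree() if n.id == "P3-srr-alone"]
        res = simulate_power(cfg, tree=tree, n_replicates=50, seed=21, keep_replicates=False)
        assert res.success_rate >= 0.95

    def test_alternative_outside_margin_rarely_succeeds(self):
        # a true -10 point deficit against a -5 point margin
        cfg = override_antigen(
            small_config(n1=0, n2=2000), "measles", response_rate_override=(0.88, 0.98)
        )
        tree = [
            ObjectiveNode("m", 2, EndpointKind.SRR_DIFF, ("measles",), margin=-5.0)
        ]
        res = simulate_power(cfg, tree=tree, n_replicates=50, seed=22, keep_replicates=False)
        assert res.success_rate <= 0.05

    def test_gate_soundness_across_replicates(self):
        cfg = override_antigen(
            small_config(n1=250), "mumps", response_rate_override=(0.85, 1.0)
        )
        tree = [n for n in default_objective_tree() if n.sub_cohort == 1]
        res = simulate_power(cfg, tree=tree, n_replicates=10, seed=23)
        for rep in res.replicates:
            primaries_met = all(
                o.met for o in rep.nodes if o.node.tier == "primary"
            )
            for o in rep.nodes:
                if o.node.tier == "secondary" and o.evaluated:
                    assert primaries_met

    def test_rate_margin_type_one_error_controlled(self):
        # with the true difference exactly on the -5 margin, the one-sided
        # declaration rate at a 97.5% two-sided CI is nominally 1.25%
        rng = np.random.default_rng(31)
        n1, n2 = 700, 250
        p2 = 0.98
        p1 = p2 - 0.05
        rejections = sum(
            score_diff_ci(int(x1), n1, int(x2), n2, level=0.975).lower_pct >= -5.0
            for x1, x2 in zip(rng.binomial(n1, p1, 2000), rng.binomial(n2, p2, 2000))
        )
        assert rejections / 2000 <= 0.029

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_power(small_config(), n_replicates=0, seed=1)


def test_planned_sample_size_arithmetic():
    assert planned_evaluable(822) == 657
    assert planned_evaluable(274) == 219
    assert planned_evaluable(822) + planned_evaluable(274) == 876
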