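"""Vmax-scaling perturbations: identity, compositionality, knockouts, scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thiamodel import synth
from thiamodel.perturb import (
    PerturbationScenario,
    apply_perturbation,
    enumerate_standard_scenarios,
    run_scan,
)
from thiamodel.simulate import SimulationConfig, simulate


class TestApplyPerturbation:
    def test_identity_fold_leaves_model_equal(self, thiamin_toy):
        out = apply_perturbation(
            thiamin_toy, PerturbationScenario("id", {"TH1": 1.0})
        )
        assert out.reactions == thiamin_toy.reactions

    def test_identity_scenario_reproduces_baseline_trajectory_bitwise(self, thiamin_toy):
        cfg = SimulationConfig(t_end=200.0, n_output_points=50)
        base = simulate(thiamin_toy, cfg)
        same = simulate(
            apply_perturbation(thiamin_toy, PerturbationScenario("id", {"TH1": 1.0})),
            cfg,
        )
        np.testing.assert_array_equal(base.concentrations, same.concentrations)

    def test_scaling_touches_only_named_enzyme(self, thiamin_toy):
        out = apply_perturbation(thiamin_toy, PerturbationScenario("x", {"THI1": 100.0}))
        assert out.reaction("THI1").law.vmax == 100.0 * thiamin_toy.reaction("THI1").law.vmax
        assert out.reaction("THI1").law.km == thiamin_toy.reaction("THI1").law.km
        for rid in ("THIC", "TH1_kinase", "TH1_synthase", "TMP_drain"):
            assert out.reaction(rid) == thiamin_toy.reaction(rid)

    def test_input_model_is_not_mutated(self, thiamin_toy):
        before = thiamin_toy.reaction("THI1").law.vmax
        apply_perturbation(thiamin_toy, PerturbationScenario("x", {"THI1": 100.0}))
        assert thiamin_toy.reaction("THI1").law.vmax == before

    def test_shared_enzyme_label_scales_all_its_reactions(self, thiamin_toy):
        out = apply_perturbation(thiamin_toy, PerturbationScenario("x", {"TH1": 10.0}))
        assert out.reaction("TH1_kinase").law.vmax == pytest.approx(5.0)
        assert out.reaction("TH1_synthase").law.vmax == pytest.approx(5.0)

    def test_mass_action_enzymes_scale_their_k(self):
        model = synth.make_rice_network()
        out = apply_perturbation(model, PerturbationScenario("x", {"TDP_carrier": 3.0}))
        assert out.reaction("t_tdp_cm").law.k == pytest.approx(
            3.0 * model.reaction("t_tdp_cm").law.k
        )

    def test_unknown_enzyme_lists_valid_labels(self, thiamin_toy):
        with pytest.raises(KeyError, match="TH1"):
            apply_perturbation(thiamin_toy, PerturbationScenario("x", {"NOPE": 2.0}))

    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError):
            PerturbationScenario("bad", {"TH1": -1.0})

    def test_knockout_of_sole_producer_freezes_target_at_initial(self, thiamin_toy):
        model = thiamin_toy.copy()
        model.metabolite("TMP").initial_concentration = 0.0
        out = apply_perturbation(model, PerturbationScenario("ko", {"TH1": 0.0}))
        res = simulate(out, SimulationConfig(t_end=500.0, n_output_points=50))
        np.testing.assert_array_equal(res.series("TMP"), 0.0)

    @given(a=st.floats(0.1, 50), b=st.floats(0.1, 50))
    @settings(derandomize=True, max_examples=50)
    def test_scaling_is_compositional(self, thiamin_toy, a, b):
        one = apply_perturbation(
            apply_perturbation(thiamin_toy, PerturbationScenario("a", {"TH1": a})),
            PerturbationScenario("b", {"TH1": b}),
        )
        both = apply_perturbation(thiamin_toy, PerturbationScenario("ab", {"TH1": a * b}))
        for r1, r2 in zip(one.reactions, both.reactions):
            if r1.law.vmax is not None:
                assert r1.law.vmax == pytest.approx(r2.law.vmax, rel=1e-12)


class TestEnumerateScenarios:
    def test_default_set_is_singles_plus_combination(self, thiamin_toy):
        scen = enumerate_standard_scenarios(thiamin_toy, ["THIC", "THI1", "TH1"], 100.0)
        assert len(scen) == 4
        assert [sorted(s.fold_changes) for s in scen] == [
            ["THIC"], ["THI1"], ["TH1"], ["TH1", "THI1", "THIC"],
        ]
        assert all(f == 100.0 for s in scen for f in s.fold_changes.values())

    def test_single_enzyme_gives_one_scenario(self, thiamin_toy):
        assert len(enumerate_standard_scenarios(thiamin_toy, ["TH1"], 10.0)) == 1

    def test_powerset_of_three_gives_seven(self, thiamin_toy):
        scen = enumerate_standard_scenarios(
            thiamin_toy, ["THIC", "THI1", "TH1"], 100.0, powerset=True
        )
        assert len(scen) == 7

    def test_large_powerset_refused_with_guidance(self, rice_network):
        labels = rice_network.enzyme_labels[:13]
        with pytest.raises(ValueError, match="at most 12"):
            enumerate_standard_scenarios(rice_network, labels, 2.0, powerset=True)


class TestRunScan:
    def test_monotone_flux_increase_on_linear_chain(self):
        # constant influx below both Vmax values: scaling E2 never lowers
        # the steady-state flux into the terminal product
        model = synth.make_mm_chain(2, seed=11)
        cfg = SimulationConfig(t_end=2000.0, n_output_points=100)
        finals = []
        for fold in (1.0, 2.0, 5.0, 20.0):
            pert = apply_perturbation(model, PerturbationScenario("f", {"E2": fold}))
            finals.append(simulate(pert, cfg).final_value("P"))
        assert all(b >= a - 1e-9 for a, b in zip(finals, finals[1:]))

    def test_scan_report_shape_and_baseline(self, thiamin_toy):
        scen = enumerate_standard_scenarios(
            thiamin_toy, ["THIC", "THI1", "TH1"], 100.0, target_metabolite="TMP"
        )
        cfg = SimulationConfig(t_end=2000.0, n_output_points=200)
        report = run_scan(thiamin_toy, scen, cfg, target_metabolite="TMP")
        assert list(report.rows["scenario"])[0] == "baseline"
        assert len(report.rows) == 5
        assert report.rows["ok"].all()
        ranked = report.ranking("final")
        assert sorted(ranked["scenario"]) == sorted(report.rows["scenario"])
        assert ranked["final"].is_monotonic_decreasing

    def test_failed_scenario_is_flagged_not_fatal(self, rice_network):
        # unresolved needs_fba reactions make every simulation fail
        report = run_scan(
            rice_network,
            [PerturbationScenario("x", {"TH1": 2.0}, target_metabolite="TMP_c")],
            SimulationConfig(t_end=10.0),
            target_metabolite="TMP_c",
        )
        assert not report.rows["ok"].any()
        assert report.rows["error"].str.len().gt(0).all()
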