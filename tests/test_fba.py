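"""Flux-balance analysis: LP correctness against vertex enumeration and
cobrapy, steady-state residuals, and kinetic gap-filling."""

import numpy as np
import pytest

from thiamodel import synth
from thiamodel.fba import build_stoich, gapfill_parameters, solve_fba
from thiamodel.model import KineticLaw, Metabolite, PathwayModel, Reaction
from thiamodel.rates import evaluate_rates
from thiamodel.simulate import SimulationConfig, simulate

from oracles import lp_vertex_max


def _linear_chain():
    """A -> B -> C with an influx and a terminal export."""
    mets = [
        Metabolite("A", initial_concentration=1.0),
        Metabolite("B", initial_concentration=1.0),
        Metabolite("C", initial_concentration=1.0),
    ]
    law = lambda: KineticLaw("constant_flux", k=0.1)
    rxns = [
        Reaction("up", "U", {"A": 1.0}, law()),
        Reaction("r1", "E1", {"A": -1.0, "B": 1.0}, law()),
        Reaction("r2", "E2", {"B": -1.0, "C": 1.0}, law()),
        Reaction("out", "X", {"C": -1.0}, law()),
    ]
    return PathwayModel(mets, rxns)


class TestBuildStoich:
    def test_chain_matrix_entries(self):
        st = build_stoich(_linear_chain(), objective={"out": 1.0})
        assert st.stoich_matrix.shape == (3, 4)
        np.testing.assert_array_equal(
            st.stoich_matrix,
            [[1, -1, 0, 0], [0, 1, -1, 0], [0, 0, 1, -1]],
        )

    def test_full_model_has_34_columns(self, rice_network):
        st = build_stoich(rice_network, objective="TMP_c")
        assert st.stoich_matrix.shape[1] == 34

    def test_boundary_metabolites_excluded_from_constraints(self, rice_network):
        st = build_stoich(rice_network, objective="TMP_c")
        assert set(st.internal_metabolite_ids).isdisjoint(rice_network.boundary_ids)
        assert len(st.internal_metabolite_ids) == 29 - 6

    def test_all_clamped_model_yields_vacuous_constraints(self):
        m = _linear_chain()
        for met in m.metabolites:
            met.boundary = True
        st = build_stoich(m, objective={"out": 1.0})
        assert st.stoich_matrix.shape[0] == 0
        sol = solve_fba(st)
        assert sol.ok  # vacuously feasible

    def test_unknown_objective_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            build_stoich(_linear_chain(), objective={"nope": 1.0})


class TestSolveFba:
    def test_chain_saturates_influx_bound(self):
        st = build_stoich(
            _linear_chain(),
            bounds={"up": (0.0, 1.0)},
            objective={"out": 1.0},
            default_bounds=(0.0, 10.0),
        )
        sol = solve_fba(st)
        assert sol.ok
        assert all(sol.fluxes[r] == pytest.approx(1.0, abs=1e-9) for r in sol.fluxes)

    def test_contradictory_bounds_report_infeasible(self):
        st = build_stoich(
            _linear_chain(),
            bounds={"up": (2.0, 3.0), "out": (0.0, 1.0)},
            objective={"out": 1.0},
        )
        assert solve_fba(st).status == "infeasible"

    def test_steady_state_residual_below_1e9(self, rice_network):
        bounds = {r.id: (0.0, 0.05) for r in rice_network.reactions if r.needs_fba}
        st = build_stoich(rice_network, bounds=bounds, objective="TMP_c")
        sol = solve_fba(st)
        assert sol.ok
        v = np.array([sol.fluxes[r] for r in st.reaction_ids])
        assert np.abs(st.stoich_matrix @ v).max() < 1e-9

    def _branched_toy(self):
        """Influx splits into two branches with different caps re-merging."""
        mets = [Metabolite(x, initial_concentration=1.0) for x in ("A", "B", "C")]
        law = lambda: KineticLaw("constant_flux", k=0.1)
        rxns = [
            Reaction("up", "U", {"A": 1.0}, law()),
            Reaction("b1", "E1", {"A": -1.0, "B": 1.0}, law()),
            Reaction("b2", "E2", {"A": -1.0, "C": 1.0}, law()),
            Reaction("out1", "X1", {"B": -1.0}, law()),
            Reaction("out2", "X2", {"C": -1.0}, law()),
        ]
        return PathwayModel(mets, rxns)

    def test_branched_optimum_matches_vertex_enumeration(self):
        model = self._branched_toy()
        bounds = {"up": (0.0, 2.0), "b1": (0.0, 0.7), "b2": (0.0, 0.9)}
        st = build_stoich(model, bounds=bounds, objective={"out1": 1.0, "out2": 0.5},
                          default_bounds=(0.0, 5.0))
        sol = solve_fba(st)
        oracle_val, _ = lp_vertex_max(st.stoich_matrix, st.lower, st.upper, st.objective)
        assert sol.ok
        assert sol.objective_value == pytest.approx(oracle_val, abs=1e-9)

    def test_chain_optimum_matches_cobrapy(self):
        """Independent cross-check of the LP layer against cobrapy."""
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("chain")
        mets = {x: cobra.Metabolite(x, compartment="c") for x in ("A", "B", "C")}
        defs = [("up", {}, {"A": 1}), ("r1", {"A": -1}, {"B": 1}),
                ("r2", {"B": -1}, {"C": 1}), ("out", {"C": -1}, {})]
        for rid, sub, prod in defs:
            rxn = cobra.Reaction(rid, lower_bound=0.0, upper_bound=10.0)
            rxn.add_metabolites({mets[m]: c for m, c in {**sub, **prod}.items()})
            model.add_reactions([rxn])
        model.reactions.up.upper_bound = 1.0
        model.objective = "out"
        cobra_opt = model.optimize().objective_value

        st = build_stoich(
            _linear_chain(), bounds={"up": (0.0, 1.0)}, objective={"out": 1.0},
            default_bounds=(0.0, 10.0),
        )
        assert solve_fba(st).objective_value == pytest.approx(cobra_opt, abs=1e-9)


class TestGapfill:
    def _gap_model(self, s0=4.0):
        mets = [
            Metabolite("S", initial_concentration=s0),
            Metabolite("Q", initial_concentration=0.0),
        ]
        rxns = [
            Reaction("feed", "F", {"S": 1.0}, KineticLaw("constant_flux", k=2.0)),
            Reaction("gap", "G", {"S": -1.0, "Q": 1.0}, None, needs_fba=True),
            Reaction("out", "X", {"Q": -1.0}, KineticLaw("constant_flux", k=2.0)),
        ]
        return PathwayModel(mets, rxns)

    def test_mm1_backsolve_reproduces_predicted_flux(self):
        model = self._gap_model(s0=4.0)
        st = build_stoich(model, bounds={"gap": (0.0, 5.0)}, objective={"gap": 1.0},
                          default_bounds=(2.0, 2.0))
        sol = solve_fba(st)
        assert sol.fluxes["gap"] == pytest.approx(2.0)
        filled = gapfill_parameters(model, sol, km_default=4.0)
        law = filled.reaction("gap").law
        assert law.law_type == "MM1" and law.vmax == pytest.approx(4.0)
        # forward check: rate at initial concentrations equals the flux
        v = evaluate_rates(filled, filled.initial_state())
        assert v[1] == pytest.approx(2.0, rel=1e-9)

    def test_zero_flux_becomes_zero_constant_flux(self):
        model = self._gap_model()
        st = build_stoich(model, objective={"gap": 1.0}, default_bounds=(0.0, 0.0))
        filled = gapfill_parameters(model, solve_fba(st))
        law = filled.reaction("gap").law
        assert law.law_type == "constant_flux" and law.k == 0.0

    def test_constant_flux_mode_pins_rate(self):
        model = self._gap_model()
        st = build_stoich(model, bounds={"gap": (0.0, 5.0)}, objective={"gap": 1.0},
                          default_bounds=(2.0, 2.0))
        filled = gapfill_parameters(model, solve_fba(st), mode="constant_flux")
        assert filled.reaction("gap").law.law_type == "constant_flux"
        assert filled.reaction("gap").law.k == pytest.approx(2.0)

    def test_zero_substrate_with_nonzero_flux_is_unsatisfiable(self):
        model = self._gap_model(s0=0.0)
        st = build_stoich(model, bounds={"gap": (0.0, 5.0)}, objective={"gap": 1.0},
                          default_bounds=(2.0, 2.0))
        with pytest.raises(ValueError, match="starts at zero"):
            gapfill_parameters(model, solve_fba(st))

    def test_gapfilled_rice_network_validates_and_simulates(self, rice_gapfilled):
        assert not any(r.needs_fba for r in rice_gapfilled.reactions)
        res = simulate(rice_gapfilled, SimulationConfig(t_end=100.0, n_output_points=20))
        assert np.all(np.isfinite(res.concentrations))

    def test_gapfill_consistency_on_rice_network(self, rice_network):
        bounds = {r.id: (0.0, 0.05) for r in rice_network.reactions if r.needs_fba}
        st = build_stoich(rice_network, bounds=bounds, objective="TMP_c")
        sol = solve_fba(st)
        filled = gapfill_parameters(rice_network, sol)
        v = evaluate_rates(filled, filled.initial_state())
        for j, rxn in enumerate(rice_network.reactions):
            if rxn.needs_fba:
                predicted = sol.fluxes[rxn.id]
                assert v[j] == pytest.approx(predicted, rel=1e-9, abs=1e-12), rxn.id
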