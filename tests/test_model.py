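"""Metabolic-model I/O, logic coupling, FBA, synchronous iteration, and
infeasibility diagnosis."""

import itertools

import numpy as np
import pytest

import fluxlogic as fl
from fluxlogic.model import (
    InfeasibleError,
    add_rules,
    couple,
    default_objective_floor,
    fba,
    find_infeasible_rules,
    load_model,
    save_model,
    simulate_iterative,
)

from _oracles import lp_fba


class TestModelIO:
    def test_structured_text_round_trip(self, proto, tmp_path):
        path = tmp_path / "proto.mod"
        save_model(proto, str(path))
        again = load_model(str(path))
        assert again.mets == proto.mets
        assert again.rxns == proto.rxns
        np.testing.assert_allclose(again.S, proto.S)
        np.testing.assert_allclose(again.vmin, proto.vmin)
        np.testing.assert_allclose(again.vmax, proto.vmax)
        np.testing.assert_allclose(again.objective, proto.objective)
        assert again.gpr == proto.gpr
        assert again.genes == proto.genes

    def test_fixture_dimensions(self, proto):
        assert len(proto.rxns) == 10
        assert len(proto.mets) == 7
        assert len(proto.genes) == 8

    def test_sbml_round_trip(self, proto, tmp_path):
        pytest.importorskip("cobra")
        path = tmp_path / "proto.xml"
        save_model(proto, str(path), format="sbml")
        again = load_model(str(path), format="sbml")
        assert set(again.rxns) == set(proto.rxns)
        assert set(again.genes) == set(proto.genes)
        # stoichiometry preserved up to reaction order
        for rxn in proto.rxns:
            j0, j1 = proto.rxns.index(rxn), again.rxns.index(rxn)
            met_map = {m: i for i, m in enumerate(again.mets)}
            for i, met in enumerate(proto.mets):
                assert proto.S[i, j0] == pytest.approx(again.S[met_map[met], j1])
            assert proto.vmin[j0] == again.vmin[j1]
            assert proto.vmax[j0] == again.vmax[j1]

    def test_sbml_without_genes_gives_empty_gprs(self, tmp_path):
        pytest.importorskip("cobra")
        m = fl.MetabolicModel(
            ["M"], ["Rin", "Rout"], np.array([[1.0, -1.0]]),
            [0, 0], [10, 10], [0, 1], [], ["", ""],
        )
        path = tmp_path / "nogenes.xml"
        save_model(m, str(path), format="sbml")
        again = load_model(str(path), format="sbml")
        assert again.gpr == ["", ""]

    def test_malformed_file_names_the_line(self, tmp_path):
        path = tmp_path / "broken.mod"
        path.write_text("METABOLITES\nA\nREACTIONS\nR1\n")
        with pytest.raises(ValueError, match="line 4"):
            load_model(str(path))

    def test_undeclared_gpr_gene_is_autodeclared(self, capsys):
        m = fl.MetabolicModel(
            ["M"], ["Rin", "Rout"], np.array([[1.0, -1.0]]),
            [0, 0], [10, 10], [0, 1], [], ["", "gx"],
        )
        assert "gx" in m.genes
        assert "undeclared" in capsys.readouterr().err


class TestCoupling:
    def test_complex_subunits_gate_flux(self, proto_coupled):
        # reaction 5 needs both subunits: g5b off zeroes v5
        _, fluxes, _ = fba(proto_coupled, fix={"g5a": 1, "g5b": 0})
        assert fluxes["R5"] == pytest.approx(0.0, abs=1e-6)

    def test_single_isozyme_suffices(self, proto, proto_coupled):
        obj, fluxes, _ = fba(
            proto_coupled,
            fix={"g8a": 0, "g8b": 1, proto_coupled.flux_vars["R8"]: 10.0},
        )
        assert fluxes["R8"] == pytest.approx(10.0)

    def test_indicator_zero_forces_zero_flux(self, proto_coupled):
        r5 = proto_coupled.indicator_vars["R5"]
        _, fluxes, _ = fba(proto_coupled, fix={r5: 0})
        assert abs(fluxes["R5"]) <= 1e-6

    def test_every_gpr_reaction_has_coupled_indicator(self, proto, proto_coupled):
        gpr_rxns = {r for r, g in zip(proto.rxns, proto.gpr) if g.strip()}
        assert set(proto_coupled.indicator_vars) == gpr_rxns
        rownames = set(proto_coupled.problem.rownames)
        for rxn in gpr_rxns:
            assert f"cpl_{rxn}_ub" in rownames and f"cpl_{rxn}_lb" in rownames

    def test_coupling_invariant_on_random_gene_states(self, proto, rng):
        """Whenever an indicator is 0 its flux is 0, and fluxes always stay
        inside their bounds."""
        cm = couple(proto)
        for _ in range(20):
            state = {g: int(b) for g, b in zip(proto.genes, rng.integers(0, 2, 8))}
            try:
                _, fluxes, _ = fba(cm, fix={cm.gene_vars[g]: v for g, v in state.items()})
            except InfeasibleError:
                continue
            res_fix = {cm.gene_vars[g]: v for g, v in state.items()}
            from fluxlogic.compiler import solve

            p = cm.problem.copy()
            p.obj = {cm.flux_vars["R9"]: -1.0}
            for name, val in res_fix.items():
                p.set_bounds(name, val, val)
            sol = solve(p).assignment
            for rxn, r_col in cm.indicator_vars.items():
                j = proto.rxns.index(rxn)
                v = sol[cm.flux_vars[rxn]]
                assert proto.vmin[j] - 1e-6 <= v <= proto.vmax[j] + 1e-6
                if sol[r_col] == 0:
                    assert abs(v) <= 1e-6


class TestAddRules:
    def test_existing_gene_reused(self, proto_coupled):
        n = proto_coupled.problem.ncols
        add_rules(proto_coupled, ["stress => not g4"])
        # exactly: stress column + companion of g4 (+ no new gene column)
        assert proto_coupled.problem.has_variable("stress")
        assert proto_coupled.problem.ncols == n + 2

    def test_fresh_tf_adds_its_columns(self, proto_coupled):
        n = proto_coupled.problem.ncols
        add_rules(proto_coupled, ["tfA and tfB => g4"])
        assert proto_coupled.problem.ncols == n + 3  # tfA, tfB, junction indicator

    def test_duplicate_rule_is_column_noop(self, proto_coupled):
        add_rules(proto_coupled, ["stress => not g4"])
        n = proto_coupled.problem.ncols
        add_rules(proto_coupled, ["stress => not g4"])
        assert proto_coupled.problem.ncols == n

    def test_rows_only_appended(self, proto_coupled):
        before = list(proto_coupled.problem.rownames)
        add_rules(proto_coupled, ["stress => not g4"])
        assert proto_coupled.problem.rownames[: len(before)] == before


class TestFba:
    def test_all_genes_on_is_productive(self, proto, proto_coupled):
        obj, _, genes = fba(proto_coupled)
        assert obj == pytest.approx(lp_fba(proto, {g: 1 for g in proto.genes}))
        assert obj > 0

    def test_knockout_of_sole_e_producer(self, proto_coupled):
        obj, _, _ = fba(proto_coupled, fix={"g7a": 0})
        assert obj == pytest.approx(0.0, abs=1e-9)

    def test_plain_fba_reduction(self, proto):
        """With no GPRs the coupled solve equals a plain LP on (S, bounds)."""
        bare = proto.copy()
        bare.gpr = [""] * len(bare.rxns)
        bare.genes = []
        obj, _, _ = fba(couple(bare))
        assert obj == pytest.approx(lp_fba(proto))

    def test_no_objective_is_an_error(self, proto):
        m = proto.copy()
        m.objective = np.zeros(len(m.rxns))
        with pytest.raises(ValueError, match="objective"):
            fba(couple(m))

    def test_returned_gene_state_is_stable(self, proto_coupled):
        """Simultaneous solve yields a fixed point of the attached explicit
        rules."""
        add_rules(proto_coupled, ["g4 <=> g5a"])
        _, _, genes = fba(proto_coupled)
        trace = simulate_iterative(["g4 <=> g5a"], genes, max_iter=5)
        assert trace.states[1] == trace.states[0]


class TestSimulateIterative:
    def test_original_rules_switch_erg11_off(self):
        trace = simulate_iterative(
            fl.fixtures.erg11_original_rules(),
            fl.fixtures.erg11_start_state(),
            fl.fixtures.erg11_environment(),
        )
        assert trace.state_at(3)["erg11"] == 0
        assert trace.state_at(4)["erg11"] == 0
        assert trace.terminal == "fixed_point"

    def test_refined_rules_keep_erg11_on(self):
        trace = simulate_iterative(
            fl.fixtures.erg11_refined_rules(),
            fl.fixtures.erg11_start_state(),
            fl.fixtures.erg11_environment(refined=True),
        )
        assert trace.state_at(4)["erg11"] == 1

    def test_oscillator_detected_as_cycle(self):
        trace = simulate_iterative(["not x <=> x"], {"x": 0})
        assert trace.terminal == "cycle"
        assert trace.cycle_length == 2
        # extrapolation follows the cycle
        assert trace.state_at(10) == trace.state_at(12)

    def test_two_defining_rules_rejected(self):
        with pytest.raises(ValueError, match="two defining"):
            simulate_iterative(["a <=> x", "b <=> x"], {})

    def test_implication_rules_rejected(self):
        with pytest.raises(ValueError, match="explicit"):
            simulate_iterative(["a => x"], {})


class TestFindInfeasibleRules:
    def test_single_blocking_rule_identified(self, toy_gated_model):
        cm = couple(toy_gated_model)
        add_rules(cm, ["E => not g"])
        cm.problem.set_bounds("E", 1, 1)
        ids, res = find_infeasible_rules(cm)
        assert ids == [1]
        assert res.objective_value == pytest.approx(1.0)

    def test_two_independent_blockers(self, toy_gated_model):
        cm = couple(toy_gated_model)
        add_rules(cm, ["E => not g", "F => not g"])
        cm.problem.set_bounds("E", 1, 1)
        cm.problem.set_bounds("F", 1, 1)
        ids, _ = find_infeasible_rules(cm)
        assert ids == [1, 2]

    def test_feasible_model_is_an_error(self, toy_gated_model):
        cm = couple(toy_gated_model)
        add_rules(cm, ["E => g"])
        with pytest.raises(ValueError, match="nothing to diagnose"):
            find_infeasible_rules(cm)

    def test_minimality_against_subset_enumeration(self, toy_gated_model):
        """The reported set is minimum-cardinality and sufficient, verified
        by exhaustively relaxing every subset of rules."""
        rule_texts = [
            "E => not g",       # blocks
            "E => harmless",    # satisfiable
            "F => not g",       # blocks
            "harmless => E",    # satisfiable
        ]
        cm = couple(toy_gated_model)
        add_rules(cm, rule_texts)
        cm.problem.set_bounds("E", 1, 1)
        cm.problem.set_bounds("F", 1, 1)
        floor = default_objective_floor(toy_gated_model)
        found, _ = find_infeasible_rules(cm, floor)

        def feasible_without(excluded):
            cm2 = couple(toy_gated_model)
            keep = [t for i, t in enumerate(rule_texts, start=1) if i not in excluded]
            add_rules(cm2, keep)
            for env in ("E", "F"):
                if cm2.problem.has_variable(env):
                    cm2.problem.set_bounds(env, 1, 1)
            try:
                obj, _, _ = fba(cm2)
            except InfeasibleError:
                return False
            return obj >= floor - 1e-9

        assert feasible_without(set(found))
        best = min(
            (
                len(sub)
                for r in range(len(rule_texts) + 1)
                for sub in itertools.combinations(range(1, len(rule_texts) + 1), r)
                if feasible_without(set(sub))
            ),
        )
        assert len(found) == best

    def test_mass_balance_blockage_reported(self, toy_gated_model):
        m = toy_gated_model.copy()
        m.vmax[0] = 0.0  # no inflow: even without rules nothing flows
        cm = couple(m)
        add_rules(cm, ["E => not g"])
        cm.problem.set_bounds("E", 1, 1)
        with pytest.raises((InfeasibleError, ValueError)):
            find_infeasible_rules(cm, objective_floor=1.0)
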