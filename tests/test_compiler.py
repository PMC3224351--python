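"""Rule-to-MILP compilation: normalization, simplification, linearization,
solver backends, and the enumeration-equivalence contract."""

import itertools

import numpy as np
import pytest

import fluxlogic as fl
from fluxlogic.compiler import (
    LinearConstraint,
    MilpProblem,
    RuleCompiler,
    SolverOptions,
    available_backends,
    build_problem,
    compile_rules,
    simplify,
    solve,
    to_negation_normal_form,
    write_lp,
    write_mps,
)
from fluxlogic.rules import (
    Atom,
    Conditional,
    Const,
    Junction,
    Not,
    NotMode,
    Variable,
    parse_rule,
)

from _oracles import enumeration_states, grid_projection, random_rule_system


class TestNegationNormalForm:
    def test_demorgan_and(self):
        expr = Not(Junction("and", Atom("x"), Atom("y")))
        assert to_negation_normal_form(expr) == Junction(
            "or", Not(Atom("x")), Not(Atom("y"))
        )

    def test_double_negation(self):
        assert to_negation_normal_form(Not(Not(Atom("x")))) == Atom("x")

    def test_demorgan_or_with_inner_negation(self):
        expr = Not(Junction("or", Atom("x"), Not(Atom("y"))))
        nnf = to_negation_normal_form(expr)
        assert nnf == Junction("and", Not(Atom("x")), Atom("y"))
        # value-equivalence over all four assignments
        for vx, vy in itertools.product((0, 1), repeat=2):
            a = {"x": vx, "y": vy}
            assert fl.evaluate_expression(expr, a) == fl.evaluate_expression(nnf, a)

    def test_negated_conditional_flips_operator(self):
        expr = Not(Conditional(Atom("v"), "<", Const(3.0)))
        assert to_negation_normal_form(expr) == Conditional(Atom("v"), ">=", Const(3.0))


class TestSimplify:
    def test_worked_decomposition(self):
        # (x or (not y)) and z => w becomes {x or not y <=> I; I and z => w}
        rule = parse_rule("(x or (not y)) and z => w", 1)
        simple, indicators = simplify([rule])
        assert len(indicators) == 1
        assert len(simple) == 1
        (sr,) = simple
        assert sr.kind == "and" and sr.connective == "=>"
        assert indicators[0].name in sr.lhs

    def test_simple_rule_is_fixed_point(self):
        simple, indicators = simplify([parse_rule("x => z", 1)])
        assert indicators == []
        assert simple[0].kind == "atom"

    def test_indicator_bound_law(self):
        variables = {
            "x": Variable("x", 0, 1),
            "y": Variable("y", 0, 2),
            "z": Variable("z", 0, 2),
        }
        _, or_ind = simplify([parse_rule("(x or y) and z => z", 1)], variables)
        assert or_ind[0].upper == 2  # or: max of bounds
        _, and_ind = simplify([parse_rule("(x and y) or z => z", 2)], variables)
        assert and_ind[0].upper == 1  # and: min of bounds

    def test_all_binary_inputs_give_binary_indicators(self):
        rule = parse_rule("(a or b) and (c or d) => e", 1)
        _, indicators = simplify([rule])
        assert all(ind.upper == 1 for ind in indicators)

    def test_one_negation_companion_per_variable(self):
        rules = [
            parse_rule("not x and y => z", 1),
            parse_rule("not x or w => z", 2),
            parse_rule("a => not x", 3),
        ]
        rc = compile_rules(rules)
        companions = [n for n in rc.problem.varnames if n.startswith("__not_")]
        assert companions == ["__not_x"]

    def test_shared_indicator_for_identical_subexpressions(self):
        rules = [
            parse_rule("(a or b) and c => z", 1),
            parse_rule("(a or b) and d => z", 2),
        ]
        _, indicators = simplify(rules)
        assert len(indicators) == 1


class TestEncoding:
    @staticmethod
    def _projection(text, variables, mode=NotMode.PSEUDO_BINARY):
        rules = [parse_rule(text, 1)]
        rc = compile_rules(rules, variables, mode)
        return grid_projection(rc.problem, sorted(variables))

    def test_binary_and_iff_truth_table(self):
        variables = {n: Variable(n) for n in "xyz"}
        assert self._projection("x and y <=> z", variables) == {
            (0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 1)
        }

    def test_multilevel_and_forces_min(self):
        variables = {n: Variable(n, 0, 2) for n in "xyz"}
        feasible = self._projection("x and y <=> z", variables)
        assert all(z == min(x, y) for x, y, z in feasible)
        assert (1, 2, 1) in feasible

    def test_binary_or_if_truth_table(self):
        variables = {n: Variable(n) for n in "xyz"}
        feasible = self._projection("x or y => z", variables)
        assert (1, 0, 1) in feasible
        assert (1, 0, 0) not in feasible
        assert (0, 0, 0) in feasible

    def test_conditional_on_flux_threshold(self):
        rc = RuleCompiler()
        rc.problem.add_variable("EX_o2", -2.44, 0.0, "c")
        rc.variables["EX_o2"] = Variable("EX_o2", kind="flux")
        rc.add_rule(parse_rule("high_o2 <=> EX_o2 < -0.244", 1))
        for v, expected in ((-1.0, 1), (0.0, 0)):
            p = rc.problem.copy()
            p.set_bounds("EX_o2", v, v)
            res = solve(p)
            assert res.ok
            assert res.assignment["high_o2"] == expected

    def test_tautological_comparison_pins_indicator(self):
        variables = {"x": Variable("x", 0, 5), "g": Variable("g")}
        feasible = self._projection("g <=> x >= 0", variables)
        assert feasible == {(g, x) for g, x in feasible if g == 1}
        assert len(feasible) == 6

    def test_conditional_needs_finite_flux_bounds(self):
        rc = RuleCompiler()
        rc.problem.add_variable("v", 0.0, float("inf"), "c")
        rc.variables["v"] = Variable("v", kind="flux")
        with pytest.raises(ValueError, match="finite"):
            rc.add_rule(parse_rule("g <=> v > 5", 1))


class TestProblemAssembly:
    def test_dimensions(self):
        p = build_problem(
            [
                LinearConstraint({"a": 1.0, "b": -1.0}, "<", 0.0, "r1"),
                LinearConstraint({"c": 2.0}, ">", 1.0, "r2"),
            ],
            [("a", 0, 1, "b"), ("b", 0, 1, "b"), ("c", 0, 5, "i")],
        )
        assert p.A().shape == (2, 3)
        assert p.ctype == "<>"
        assert len(p.rownames) == 2

    def test_existing_variables_are_reused(self):
        rc = compile_rules([parse_rule("a => g", 1)])
        n_before = rc.problem.ncols
        rc.add_rule(parse_rule("b => g", 2))
        # only the new antecedent column appears
        assert rc.problem.ncols == n_before + 1

    def test_empty_problem_is_valid(self):
        p = build_problem([], [("v", 0, 10, "c")], {"v": 1.0})
        assert p.nrows == 0 and solve(p).ok

    def test_duplicate_row_names_rejected(self):
        p = MilpProblem()
        p.add_variable("x", 0, 1, "b")
        p.add_constraint(LinearConstraint({"x": 1.0}, "<", 1.0, "r"))
        with pytest.raises(ValueError, match="duplicate"):
            p.add_constraint(LinearConstraint({"x": 1.0}, ">", 0.0, "r"))

    def test_recompiling_same_rules_adds_nothing(self):
        texts = fl.fixtures.mig1_explicit_rules()
        rc = compile_rules([parse_rule(t, i + 1) for i, t in enumerate(texts)])
        cols, rows = rc.problem.ncols, rc.problem.nrows
        rc.add_rules([parse_rule(t, i + 10) for i, t in enumerate(texts)])
        assert (rc.problem.ncols, rc.problem.nrows) == (cols, rows)


class TestSolve:
    def test_one_variable_integer_minimum(self):
        p = build_problem(
            [LinearConstraint({"x": 1.0}, ">", 3.0, "c")], [("x", 0, 10, "i")], {"x": 1.0}
        )
        res = solve(p)
        assert res.status == "optimal" and res.objective_value == 3

    def test_infeasible_status(self):
        p = build_problem(
            [
                LinearConstraint({"x": 1.0}, ">", 1.0, "c1"),
                LinearConstraint({"x": 1.0}, "<", 0.0, "c2"),
            ],
            [("x", 0, 10, "c")],
        )
        assert solve(p).status == "infeasible"

    def test_feasible_point_of_explicit_system_is_a_reference_state(self):
        rules = [parse_rule(t, i + 1) for i, t in enumerate(fl.fixtures.mig1_explicit_rules())]
        variables = fl.collect_variables(rules)
        rc = compile_rules(rules, variables)
        res = solve(rc.problem)
        assert res.ok
        point = tuple(int(res.assignment[n]) for n in sorted(variables))
        assert point in enumeration_states(rules, variables, NotMode.PSEUDO_BINARY)

    @pytest.mark.parametrize("backend", available_backends())
    def test_backends_agree_on_fixture(self, backend):
        p = build_problem(
            [
                LinearConstraint({"x": 1.0, "y": 1.0}, ">", 3.0, "c1"),
                LinearConstraint({"x": 1.0, "y": -1.0}, "<", 1.0, "c2"),
            ],
            [("x", 0, 10, "i"), ("y", 0, 10, "i")],
            {"x": 2.0, "y": 1.0},
        )
        res = solve(p, SolverOptions(backend=backend))
        assert res.status == "optimal"
        # optimum x=0, y=3: cost 3
        assert res.objective_value == pytest.approx(3.0)

    def test_unknown_backend(self):
        p = build_problem([], [("x", 0, 1, "b")])
        with pytest.raises(ValueError, match="unknown backend"):
            solve(p, SolverOptions(backend="simplex9000"))


class TestOracleEquivalence:
    """Central contract: the compiled MILP's integer points, projected onto
    the original variables, equal exhaustive enumeration exactly."""

    N_SYSTEMS = 60  # per mode (the full 200-system sweep runs in acceptance)

    @pytest.mark.parametrize("mode", [NotMode.PSEUDO_BINARY, NotMode.INVERSION])
    def test_random_systems(self, mode, rng):
        checked = 0
        while checked < self.N_SYSTEMS:
            rules, variables = random_rule_system(rng)
            rc = compile_rules(rules, variables, mode)
            projected = grid_projection(rc.problem, sorted(variables))
            if projected is None:  # grid too large; draw another system
                continue
            expected = enumeration_states(rules, variables, mode)
            assert projected == expected, [r.source_text for r in rules]
            checked += 1

    @pytest.mark.parametrize("mode", [NotMode.PSEUDO_BINARY, NotMode.INVERSION])
    def test_indicator_bound_law_on_random_systems(self, mode, rng):
        for _ in range(40):
            rules, variables = random_rule_system(rng)
            rc = compile_rules(rules, variables, mode)
            for ind in rc.indicators:
                a, op, b = ind.defining.split(" ", 2)[0], ind.defining.split()[1], ind.defining.split()[2]
                ua = rc.problem.variable_bounds(a)[1]
                ub = rc.problem.variable_bounds(b)[1]
                expected = max(ua, ub) if op == "or" else min(ua, ub)
                assert ind.upper == expected


class TestExport:
    def test_lp_writer_contents(self, tmp_path):
        p = build_problem(
            [LinearConstraint({"x": 1.0, "y": -2.0}, "<", 3.0, "row1")],
            [("x", 0, 10, "i"), ("y", 0, 1, "b")],
            {"x": 1.0},
        )
        path = tmp_path / "p.lp"
        write_lp(p, str(path))
        text = path.read_text()
        assert "Minimize" in text and "row1: 1 x - 2 y <= 3" in text
        assert "Generals" in text and "Binaries" in text

    def test_mps_writer_roundtrips_through_glpk(self, tmp_path):
        pytest.importorskip("swiglpk")
        import swiglpk as glp

        p = build_problem(
            [LinearConstraint({"x": 1.0}, ">", 3.0, "c")], [("x", 0, 10, "i")], {"x": 1.0}
        )
        path = tmp_path / "p.mps"
        write_mps(p, str(path))
        prob = glp.glp_create_prob()
        assert glp.glp_read_mps(prob, glp.GLP_MPS_FILE, None, str(path)) == 0
        assert glp.glp_get_num_cols(prob) == 1
        glp.glp_delete_prob(prob)

    def test_deterministic_output(self, tmp_path):
        rules = [parse_rule(t, i + 1) for i, t in enumerate(fl.fixtures.mig1_implicit_rules())]
        rc1 = compile_rules(rules)
        rc2 = compile_rules(rules)
        a, b = tmp_path / "a.lp", tmp_path / "b.lp"
        write_lp(rc1.problem, str(a))
        write_lp(rc2.problem, str(b))
        assert a.read_text() == b.read_text()
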