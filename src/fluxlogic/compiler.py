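"""Compile logical rules into mixed-integer linear constraints.

Pipeline: rules are normalized (negations pushed onto atoms with DeMorgan's
laws), decomposed into *simple rules* — patterns ``x (=>|<=>) z``,
``x and y (=>|<=>) z``, ``x or y (=>|<=>) z``, ``x <op> y (=>|<=>) z`` with
atomic operands — by introducing indicator variables for compound
sub-expressions, and each simple rule is linearized over bounded integer
columns.  The normative contract: the integer points satisfying the emitted
constraints, projected onto the original variables, are exactly the
assignments accepted by :func:`fluxlogic.rules.evaluate_rule`.

Indicator bounds follow the min/max law: an ``or`` indicator's upper bound
is ``max(x̄, ȳ)``, an ``and`` indicator's is ``min(x̄, ȳ)``; all-binary
inputs therefore yield binary indicators.  Identical sub-expressions share
one indicator (hash-consing), and at most one negation-companion column is
created per original variable.

The module also holds the solver-agnostic MILP record (objective, sparse
constraint matrix, senses, bounds, variable types, row/column names), LP and
MPS text writers, and ``solve`` with HiGHS (scipy) and GLPK (swiglpk)
backends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .rules import (
    Atom,
    Conditional,
    Const,
    Expression,
    Junction,
    Not,
    NotMode,
    Rule,
    Variable,
    _CMP_NEG,
)

__all__ = [
    "LinearConstraint",
    "MilpProblem",
    "SolverOptions",
    "SolverResult",
    "SimpleRule",
    "IndicatorVariable",
    "RuleCompiler",
    "to_negation_normal_form",
    "simplify",
    "compile_rules",
    "build_problem",
    "solve",
    "write_lp",
    "write_mps",
]

DEFAULT_STRICT_TOL = 1e-6
DEFAULT_FEASIBILITY_TOL = 1e-6
DEFAULT_OPTIMALITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# MILP record
# ---------------------------------------------------------------------------

@dataclass
class LinearConstraint:
    """Sparse linear row ``sum(coefficients) sense rhs``; sense in {<,=,>}."""

    coefficients: dict[str, float]
    sense: str
    rhs: float
    name: str

    def __post_init__(self) -> None:
        if self.sense not in ("<", "=", ">"):
            raise ValueError(f"bad sense {self.sense!r}")
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError(f"constraint {self.name}: no nonzero coefficient")


class MilpProblem:
    """Mixed-integer linear program, minimization sense.

    Mirrors the standard solver record: objective vector ``obj``, sparse
    matrix ``A`` with senses ``ctype`` and right-hand side ``b``, variable
    bounds ``lb``/``ub``, per-variable type ``vartype`` ('c' continuous,
    'b' binary, 'i' integer), and descriptive ``rownames``/``varnames``.
    Variables are shared by name: adding a rule that mentions an existing
    column reuses it.
    """

    def __init__(self) -> None:
        self.varnames: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.vartype: list[str] = []
        self.obj: dict[str, float] = {}
        self.constraints: list[LinearConstraint] = []
        self._var_index: dict[str, int] = {}
        self._row_names: set[str] = set()

    # -- variables ---------------------------------------------------------
    def add_variable(self, name: str, lb: float, ub: float, vartype: str) -> int:
        """Add a column, or return the existing one (bounds must agree)."""
        if vartype not in ("c", "b", "i"):
            raise ValueError(f"bad vartype {vartype!r}")
        if name in self._var_index:
            i = self._var_index[name]
            if (self.lb[i], self.ub[i], self.vartype[i]) != (lb, ub, vartype):
                raise ValueError(
                    f"variable {name!r} redeclared with different bounds/type"
                )
            return i
        if lb > ub:
            raise ValueError(f"variable {name}: lb {lb} > ub {ub}")
        self._var_index[name] = len(self.varnames)
        self.varnames.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.vartype.append(vartype)
        return self._var_index[name]

    def has_variable(self, name: str) -> bool:
        return name in self._var_index

    def variable_index(self, name: str) -> int:
        return self._var_index[name]

    def variable_bounds(self, name: str) -> tuple[float, float]:
        i = self._var_index[name]
        return self.lb[i], self.ub[i]

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._var_index[name]
        self.lb[i], self.ub[i] = lb, ub

    # -- constraints -------------------------------------------------------
    def add_constraint(self, con: LinearConstraint) -> None:
        if con.name in self._row_names:
            raise ValueError(f"duplicate constraint name {con.name!r}")
        for var in con.coefficients:
            if var not in self._var_index:
                raise ValueError(f"constraint {con.name}: unknown variable {var!r}")
        self._row_names.add(con.name)
        self.constraints.append(con)

    # -- matrix views ------------------------------------------------------
    @property
    def nrows(self) -> int:
        return len(self.constraints)

    @property
    def ncols(self) -> int:
        return len(self.varnames)

    @property
    def rownames(self) -> list[str]:
        return [c.name for c in self.constraints]

    @property
    def ctype(self) -> str:
        return "".join(c.sense for c in self.constraints)

    @property
    def b(self) -> np.ndarray:
        return np.array([c.rhs for c in self.constraints], dtype=float)

    def A(self) -> sp.csr_matrix:
        rows, cols, data = [], [], []
        for i, con in enumerate(self.constraints):
            for var, coef in con.coefficients.items():
                rows.append(i)
                cols.append(self._var_index[var])
                data.append(float(coef))
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.nrows, self.ncols)
        )

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.ncols)
        for var, coef in self.obj.items():
            c[self._var_index[var]] = coef
        return c

    def copy(self) -> "MilpProblem":
        other = MilpProblem()
        for name, lo, up, vt in zip(self.varnames, self.lb, self.ub, self.vartype):
            other.add_variable(name, lo, up, vt)
        for con in self.constraints:
            other.add_constraint(
                LinearConstraint(dict(con.coefficients), con.sense, con.rhs, con.name)
            )
        other.obj = dict(self.obj)
        return other


def build_problem(
    constraints: Iterable[LinearConstraint],
    variables: Iterable[tuple[str, float, float, str]],
    objective: Mapping[str, float] | None = None,
) -> MilpProblem:
    """Assemble a problem record from columns ``(name, lb, ub, vartype)``,
    rows, and an objective (minimization)."""
    p = MilpProblem()
    for name, lo, up, vt in variables:
        p.add_variable(name, lo, up, vt)
    for con in constraints:
        p.add_constraint(con)
    p.obj = dict(objective or {})
    return p


# ---------------------------------------------------------------------------
# Negation normal form
# ---------------------------------------------------------------------------

def to_negation_normal_form(expr: Expression) -> Expression:
    """Push ``not`` onto atoms and conditionals via DeMorgan's laws.

    ``not (x and y)`` becomes ``(not x) or (not y)``; a negated conditional
    flips its comparison operator; double negations cancel.  The result is
    logically equivalent under pseudo-binary negation for every assignment
    (with inversion negation and unequal operand bounds DeMorgan does not
    preserve values, so the compiler uses indicator substitution instead in
    that mode).
    """
    if isinstance(expr, (Atom, Const, Conditional)):
        return expr
    if isinstance(expr, Junction):
        return Junction(
            expr.op, to_negation_normal_form(expr.left), to_negation_normal_form(expr.right)
        )
    if isinstance(expr, Not):
        inner = expr.operand
        if isinstance(inner, Not):
            return to_negation_normal_form(inner.operand)
        if isinstance(inner, Junction):
            flipped = "or" if inner.op == "and" else "and"
            return Junction(
                flipped,
                to_negation_normal_form(Not(inner.left)),
                to_negation_normal_form(Not(inner.right)),
            )
        if isinstance(inner, Conditional):
            return Conditional(inner.left, _CMP_NEG[inner.op], inner.right)
        if isinstance(inner, Const):
            return Const(1.0 if inner.value == 0 else 0.0)
        return expr  # Not(Atom)
    raise TypeError(f"not an expression: {expr!r}")


# ---------------------------------------------------------------------------
# Simple rules and indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleRule:
    """One of the four linearizable patterns over column operands."""

    kind: str  # atom | and | or | cond
    connective: str  # => | <=>
    lhs: tuple[str, ...]  # operand column names (cond: indicator column)
    rhs: str  # consequent column name
    rule_id: int = -1
    cond: Conditional | None = None  # original comparison, for kind == "cond"


@dataclass(frozen=True)
class IndicatorVariable:
    """Auxiliary integer column standing for a compound sub-expression."""

    name: str
    lower: int
    upper: int
    defining: str


class RuleCompiler:
    """Incremental rule-to-MILP compiler over a shared problem record.

    Tracks negation companions (one per original variable), hash-consed
    indicators for repeated sub-expressions, and the rows emitted for each
    rule id (used by infeasibility diagnosis to relax whole rules).
    """

    def __init__(
        self,
        problem: MilpProblem | None = None,
        variables: Mapping[str, Variable] | None = None,
        mode: NotMode = NotMode.PSEUDO_BINARY,
        strict_tol: float = DEFAULT_STRICT_TOL,
    ) -> None:
        self.problem = problem if problem is not None else MilpProblem()
        self.variables: dict[str, Variable] = dict(variables or {})
        self.mode = mode
        self.strict_tol = strict_tol
        self.rule_rows: dict[int, list[str]] = {}
        self.simple_rules: list[SimpleRule] = []
        self.indicators: list[IndicatorVariable] = []
        self._companion: dict[str, str] = {}
        self._junction_cache: dict[tuple, str] = {}
        self._cond_cache: dict[tuple, str] = {}
        self._emit_cache: dict[tuple, list[str]] = {}
        self._counter = 0

    # -- columns -----------------------------------------------------------
    def declare(self, var: Variable) -> None:
        existing = self.variables.get(var.name)
        if existing is not None and (existing.lower, existing.upper) != (
            var.lower,
            var.upper,
        ):
            raise ValueError(
                f"variable {var.name!r} redeclared with conflicting bounds"
            )
        self.variables[var.name] = var
        if var.kind != "flux":
            self._logical_column(var.name)

    def _fresh(self, prefix: str) -> str:
        self._counter += 1
        return f"__{prefix}{self._counter}"

    def _logical_column(self, name: str) -> str:
        var = self.variables.get(name)
        if var is None:
            var = Variable(name)
            self.variables[name] = var
        if var.kind == "flux":
            raise ValueError(f"flux variable {name!r} may appear only in conditionals")
        if var.lower < 0:
            raise ValueError(f"logical variable {name!r} must have lower bound >= 0")
        vt = "b" if var.is_binary else "i"
        self.problem.add_variable(name, var.lower, var.upper, vt)
        return name

    def _aux_column(self, name: str, lower: float, upper: float, integer: bool = True) -> str:
        vt = "b" if (integer and lower == 0 and upper == 1) else ("i" if integer else "c")
        self.problem.add_variable(name, lower, upper, vt)
        return name

    def _column_bounds(self, name: str) -> tuple[float, float]:
        return self.problem.variable_bounds(name)

    # -- atomization -------------------------------------------------------
    def _companion_column(self, name: str) -> str:
        """Column whose value equals ``not name`` under the compiler's mode."""
        if name in self._companion:
            return self._companion[name]
        if not self.problem.has_variable(name):
            self._logical_column(name)
        lo, up = self._column_bounds(name)
        comp = f"__not_{name}"
        if self.mode == NotMode.INVERSION:
            if not math.isfinite(up):
                raise ValueError(f"inversion negation of unbounded variable {name!r}")
            self._aux_column(comp, 0, up - lo, integer=True)
            self._add_row(
                LinearConstraint({name: 1.0, comp: 1.0}, "=", float(up), f"def_{comp}")
            )
        else:
            # binary companion: comp = 1 iff name == 0 (levels are >= 0)
            self._aux_column(comp, 0, 1, integer=True)
            self._add_row(
                LinearConstraint({name: 1.0, comp: float(up)}, "<", float(up), f"def_{comp}_a")
            )
            self._add_row(
                LinearConstraint({name: 1.0, comp: 1.0}, ">", 1.0, f"def_{comp}_b")
            )
        self._companion[name] = comp
        return comp

    def _atomize(self, expr: Expression) -> str:
        """Column whose value equals the expression's value; defines
        indicators for compound sub-expressions (shared when identical)."""
        if isinstance(expr, Atom):
            return self._logical_column(expr.name)
        if isinstance(expr, Not):
            inner = expr.operand
            if isinstance(inner, Atom):
                return self._companion_column(inner.name)
            if isinstance(inner, Conditional):
                flipped = Conditional(inner.left, _CMP_NEG[inner.op], inner.right)
                return self._conditional_indicator(flipped)
            # negated compound: companion of its indicator column
            return self._companion_column(self._atomize(inner))
        if isinstance(expr, Conditional):
            return self._conditional_indicator(expr)
        if isinstance(expr, Junction):
            a = self._atomize(expr.left)
            b = self._atomize(expr.right)
            return self._junction_indicator(expr.op, a, b)
        if isinstance(expr, Const):
            raise ValueError("a bare constant is not a logical operand")
        raise TypeError(f"not an expression: {expr!r}")

    def _junction_indicator(self, op: str, a: str, b: str) -> str:
        key = (op,) + tuple(sorted((a, b)))
        if key in self._junction_cache:
            return self._junction_cache[key]
        (alo, aup), (blo, bup) = self._column_bounds(a), self._column_bounds(b)
        if op == "and":
            lo, up = min(alo, blo), min(aup, bup)
        else:
            lo, up = max(alo, blo), max(aup, bup)
        name = self._fresh("I")
        self._aux_column(name, lo, up, integer=True)
        self._junction_cache[key] = name
        self.indicators.append(
            IndicatorVariable(name, int(lo), int(up), f"{a} {op} {b}")
        )
        self._emit_junction(op, "<=>", a, b, name, row_prefix=f"def_{name}")
        return name

    # -- conditionals ------------------------------------------------------
    def _cond_operand(self, node: Atom | Const) -> tuple[dict[str, float], float, float, float, bool]:
        """(coefficients, constant, lo, hi, is_integer) of a comparison side."""
        if isinstance(node, Const):
            return {}, float(node.value), float(node.value), float(node.value), float(
                node.value
            ).is_integer()
        var = self.variables.get(node.name)
        if var is not None and var.kind == "flux":
            if not self.problem.has_variable(node.name):
                raise ValueError(
                    f"flux variable {node.name!r} has no column; add the model first"
                )
            lo, hi = self._column_bounds(node.name)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(
                    f"conditional on {node.name!r} needs finite flux bounds for big-M"
                )
            return {node.name: 1.0}, 0.0, lo, hi, False
        col = self._logical_column(node.name)
        lo, hi = self._column_bounds(col)
        return {col: 1.0}, 0.0, lo, hi, True

    def _conditional_indicator(self, cond: Conditional) -> str:
        """Binary column g with g = 1 iff the comparison holds (strict
        comparisons up to ``strict_tol`` on continuous operands)."""
        key = (cond.left, cond.op, cond.right)
        if key in self._cond_cache:
            return self._cond_cache[key]
        if cond.op == "=":
            g_ge = self._conditional_indicator(Conditional(cond.left, ">=", cond.right))
            g_le = self._conditional_indicator(Conditional(cond.left, "<=", cond.right))
            g = self._junction_indicator("and", g_ge, g_le)
            self._cond_cache[key] = g
            return g
        if cond.op == "!=":
            eq = self._conditional_indicator(Conditional(cond.left, "=", cond.right))
            g = self._companion_column(eq)
            self._cond_cache[key] = g
            return g
        # normalize to d = L - R with op in {>=, >}
        left, op, right = cond.left, cond.op, cond.right
        if op in ("<", "<="):
            left, right = right, left
            op = {"<": ">", "<=": ">="}[op]
        lc, lconst, llo, lhi, lint = self._cond_operand(left)
        rc, rconst, rlo, rhi, rint = self._cond_operand(right)
        coeffs = dict(lc)
        for var, coef in rc.items():
            coeffs[var] = coeffs.get(var, 0.0) - coef
        coeffs = {v: c for v, c in coeffs.items() if c != 0.0}
        const = lconst - rconst  # d = coeffs·x + const
        # operand lo/hi already include any constant part, so d's range is
        # a plain difference of ranges
        d_lo, d_hi = llo - rhi, lhi - rlo
        eps = 1.0 if (lint and rint) else self.strict_tol
        g = self._fresh("cond")
        self._aux_column(g, 0, 1, integer=True)
        self._cond_cache[key] = g
        threshold = 0.0 if op == ">=" else eps  # g=1 -> d >= threshold
        cutoff = -eps if op == ">=" else 0.0  # g=0 -> d <= cutoff
        if not coeffs:
            # constant comparison: fix g
            holds = const >= threshold
            self._add_row(
                LinearConstraint({g: 1.0}, "=", 1.0 if holds else 0.0, f"def_{g}_fix")
            )
            return g
        # g=1 -> d >= threshold:  d - (threshold - d_lo) g >= d_lo
        row1 = dict(coeffs)
        row1[g] = -(threshold - d_lo)
        self._add_row(LinearConstraint(row1, ">", d_lo - const, f"def_{g}_on"))
        # g=0 -> d <= cutoff:  d - (d_hi - cutoff) g <= cutoff
        row2 = dict(coeffs)
        row2[g] = -(d_hi - cutoff)
        self._add_row(LinearConstraint(row2, "<", cutoff - const, f"def_{g}_off"))
        return g

    def encode_conditional(self, cond: Conditional) -> str:
        """Linearize a comparison; returns the binary indicator column whose
        value is 1 exactly when the comparison holds."""
        return self._conditional_indicator(cond)

    def encode_simple_rule(self, sr: SimpleRule) -> list[str]:
        """Emit the linear rows for one simple rule; returns the row names
        (identical simple rules share rows)."""
        return self._emit_simple(sr)

    # -- emission ----------------------------------------------------------
    def _add_row(self, con: LinearConstraint, sink: list[str] | None = None) -> None:
        self.problem.add_constraint(con)
        if sink is not None:
            sink.append(con.name)

    @staticmethod
    def _combine(*terms: tuple[str, float]) -> dict[str, float]:
        """Sum coefficients per column (repeated operands may collide) and
        drop exact zeros."""
        out: dict[str, float] = {}
        for var, coef in terms:
            out[var] = out.get(var, 0.0) + coef
        return {v: c for v, c in out.items() if c != 0.0}

    def _add_row_if_nonzero(
        self,
        terms: Sequence[tuple[str, float]],
        sense: str,
        rhs: float,
        name: str,
        sink: list[str] | None = None,
    ) -> None:
        """Emit a row unless it reduces to 0 (sense) rhs; a vanishing row
        that is unsatisfiable marks the whole system infeasible via a pinned
        dummy-free contradiction check."""
        coeffs = self._combine(*terms)
        if not coeffs:
            trivially_true = (
                (sense == "<" and 0.0 <= rhs)
                or (sense == ">" and 0.0 >= rhs)
                or (sense == "=" and rhs == 0.0)
            )
            if trivially_true:
                return
            raise ValueError(f"rule row {name} reduces to the contradiction 0 {sense} {rhs}")
        self._add_row(LinearConstraint(coeffs, sense, rhs, name), sink)

    def _emit_junction(
        self,
        op: str,
        connective: str,
        a: str,
        b: str,
        z: str,
        row_prefix: str,
        sink: list[str] | None = None,
    ) -> None:
        """Rows for ``a <op> b (=>|<=>) z`` with min/max semantics.

        ``and``: z >= min(a,b) via a binary selector; ``<=>`` adds z <= a,
        z <= b.  ``or``: z >= a, z >= b; ``<=>`` adds z <= max(a,b) via a
        selector.  Selector big-M constants come from column bounds.
        """
        (alo, aup) = self._column_bounds(a)
        (blo, bup) = self._column_bounds(b)
        (zlo, zup) = self._column_bounds(z)
        if not all(map(math.isfinite, (aup, bup, zup))):
            raise ValueError("junction operands must have finite bounds")
        if op == "and":
            s = self._aux_column(self._fresh("sel"), 0, 1)
            # z >= a - (aup - zlo) s ; z >= b - (bup - zlo)(1 - s)
            self._add_row_if_nonzero(
                [(z, 1.0), (a, -1.0), (s, aup - zlo)], ">", 0.0, f"{row_prefix}_ge_a", sink
            )
            self._add_row_if_nonzero(
                [(z, 1.0), (b, -1.0), (s, -(bup - zlo))],
                ">",
                -(bup - zlo),
                f"{row_prefix}_ge_b",
                sink,
            )
            if connective == "<=>":
                self._add_row_if_nonzero(
                    [(z, 1.0), (a, -1.0)], "<", 0.0, f"{row_prefix}_le_a", sink
                )
                self._add_row_if_nonzero(
                    [(z, 1.0), (b, -1.0)], "<", 0.0, f"{row_prefix}_le_b", sink
                )
        else:  # or
            self._add_row_if_nonzero(
                [(z, 1.0), (a, -1.0)], ">", 0.0, f"{row_prefix}_ge_a", sink
            )
            self._add_row_if_nonzero(
                [(z, 1.0), (b, -1.0)], ">", 0.0, f"{row_prefix}_ge_b", sink
            )
            if connective == "<=>":
                s = self._aux_column(self._fresh("sel"), 0, 1)
                # z <= a + (zup - alo) s ; z <= b + (zup - blo)(1 - s)
                self._add_row_if_nonzero(
                    [(z, 1.0), (a, -1.0), (s, -(zup - alo))], "<", 0.0, f"{row_prefix}_le_a", sink
                )
                self._add_row_if_nonzero(
                    [(z, 1.0), (b, -1.0), (s, zup - blo)],
                    "<",
                    zup - blo,
                    f"{row_prefix}_le_b",
                    sink,
                )

    def _emit_simple(self, sr: SimpleRule) -> list[str]:
        """Rows for one simple rule; identical simple rules share rows."""
        key = (sr.kind, sr.connective, sr.lhs, sr.rhs)
        if key in self._emit_cache:
            return self._emit_cache[key]
        rows: list[str] = []
        tag = f"sr{len(self._emit_cache) + 1}"
        if sr.kind in ("atom", "cond"):
            a = sr.lhs[0]
            if a == sr.rhs:  # self-implication: tautology, no row
                self._emit_cache[key] = rows
                return rows
            if sr.connective == "<=>":
                self._add_row(
                    LinearConstraint({sr.rhs: 1.0, a: -1.0}, "=", 0.0, f"{tag}_eq"), rows
                )
            else:
                self._add_row(
                    LinearConstraint({sr.rhs: 1.0, a: -1.0}, ">", 0.0, f"{tag}_ge"), rows
                )
        else:
            self._emit_junction(
                sr.kind, sr.connective, sr.lhs[0], sr.lhs[1], sr.rhs, tag, rows
            )
        self._emit_cache[key] = rows
        return rows

    # -- rule entry point --------------------------------------------------
    def add_rule(self, rule: Rule) -> list[SimpleRule]:
        """Compile one rule; returns the simple rules it reduced to."""
        # negations are compiled via companion columns rather than DeMorgan
        # rewriting: NNF preserves truth but not the multilevel *value* of a
        # pseudo-binary negation (e.g. ``not not x`` is 0/1, never x)
        ant, cons = rule.antecedent, rule.consequent
        z = self._atomize(cons)
        emitted: list[SimpleRule] = []
        if isinstance(ant, Junction):
            # keep the top junction as the simple-rule pattern; only its
            # compound operands get indicators
            a = self._atomize(ant.left)
            b = self._atomize(ant.right)
            sr = SimpleRule(ant.op, rule.connective, (a, b), z, rule.id)
        elif isinstance(ant, Conditional):
            g = self._conditional_indicator(ant)
            sr = SimpleRule("cond", rule.connective, (g,), z, rule.id, cond=ant)
        else:
            a = self._atomize(ant)
            sr = SimpleRule("atom", rule.connective, (a,), z, rule.id)
        rows = self._emit_simple(sr)
        emitted.append(sr)
        self.simple_rules.append(sr)
        self.rule_rows.setdefault(rule.id, []).extend(rows)
        return emitted

    def add_rules(self, rules: Iterable[Rule]) -> None:
        for rule in rules:
            self.add_rule(rule)


def simplify(
    rules: Sequence[Rule],
    variables: Mapping[str, Variable] | None = None,
    mode: NotMode = NotMode.PSEUDO_BINARY,
) -> tuple[list[SimpleRule], list[IndicatorVariable]]:
    """Reduce rules to simple patterns; returns them with the indicator
    variables that were introduced (bounds per the min/max law)."""
    rc = RuleCompiler(variables=variables, mode=mode)
    rc.add_rules(rules)
    return rc.simple_rules, rc.indicators


def compile_rules(
    rules: Sequence[Rule],
    variables: Mapping[str, Variable] | None = None,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    problem: MilpProblem | None = None,
) -> RuleCompiler:
    """Compile a rule set into a (new or existing) MILP record."""
    rc = RuleCompiler(problem=problem, variables=variables, mode=mode)
    for var in (variables or {}).values():
        if var.kind != "flux":
            rc.declare(var)
    rc.add_rules(rules)
    return rc


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

@dataclass
class SolverOptions:
    """Backend-independent solver knobs; tolerances must be positive.

    ``seed`` is best-effort: the bundled backends are deterministic and
    ignore it.
    """

    max_time: float | None = None
    feasibility_tol: float = DEFAULT_FEASIBILITY_TOL
    optimality_tol: float = DEFAULT_OPTIMALITY_TOL
    seed: int = 0
    backend: str | None = None  # "highs" | "glpk" | None = first available

    def __post_init__(self) -> None:
        if self.feasibility_tol <= 0 or self.optimality_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SolverResult:
    status: str  # optimal | infeasible | unbounded | time_limit | error
    objective_value: float | None
    assignment: dict[str, float] | None
    backend: str = ""
    raw_status: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _round_solution(p: MilpProblem, x: np.ndarray, tol: float) -> dict[str, float]:
    out: dict[str, float] = {}
    for i, name in enumerate(p.varnames):
        v = float(x[i])
        if p.vartype[i] in ("b", "i"):
            r = round(v)
            if abs(v - r) > max(tol * 10, 1e-4):
                raise ValueError(
                    f"integer variable {name} came back fractional ({v})"
                )
            v = float(int(min(max(r, p.lb[i]), p.ub[i])))
        out[name] = v
    return out


def _solve_highs(p: MilpProblem, opts: SolverOptions) -> SolverResult:
    from scipy.optimize import Bounds, milp
    from scipy.optimize import LinearConstraint as SciLinearConstraint

    c = p.objective_vector()
    integrality = np.array([0 if t == "c" else 1 for t in p.vartype])
    bounds = Bounds(np.array(p.lb, dtype=float), np.array(p.ub, dtype=float))
    constraints = []
    if p.nrows:
        A = p.A()
        b = p.b
        lo = np.where([s == "<" for s in p.ctype], -np.inf, b)
        hi = np.where([s == ">" for s in p.ctype], np.inf, b)
        constraints = [SciLinearConstraint(A, lo, hi)]
    options: dict = {"disp": False}
    if opts.max_time is not None:
        options["time_limit"] = opts.max_time
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options=options,
    )
    status_map = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "unbounded"}
    status = status_map.get(res.status, "error")
    assignment = None
    objective = None
    if res.x is not None:
        assignment = _round_solution(p, res.x, opts.feasibility_tol)
        objective = float(res.fun)
    if status in ("optimal", "time_limit") and assignment is None:
        status = "error"
    return SolverResult(status, objective, assignment, "highs", str(res.status))


def _solve_glpk(p: MilpProblem, opts: SolverOptions) -> SolverResult:
    import swiglpk as glp

    prob = glp.glp_create_prob()
    try:
        glp.glp_set_obj_dir(prob, glp.GLP_MIN)
        glp.glp_add_cols(prob, p.ncols)
        any_int = False
        for i, name in enumerate(p.varnames, start=1):
            glp.glp_set_col_name(prob, i, name[:250])
            lo, up = p.lb[i - 1], p.ub[i - 1]
            if lo == up:
                glp.glp_set_col_bnds(prob, i, glp.GLP_FX, lo, up)
            else:
                glp.glp_set_col_bnds(prob, i, glp.GLP_DB, lo, up)
            if p.vartype[i - 1] in ("b", "i"):
                glp.glp_set_col_kind(prob, i, glp.GLP_IV)
                any_int = True
        for name, coef in p.obj.items():
            glp.glp_set_obj_coef(prob, p.variable_index(name) + 1, coef)
        glp.glp_add_rows(prob, p.nrows)
        entries: list[tuple[int, int, float]] = []
        for r, con in enumerate(p.constraints, start=1):
            glp.glp_set_row_name(prob, r, con.name[:250])
            if con.sense == "<":
                glp.glp_set_row_bnds(prob, r, glp.GLP_UP, 0.0, con.rhs)
            elif con.sense == ">":
                glp.glp_set_row_bnds(prob, r, glp.GLP_LO, con.rhs, 0.0)
            else:
                glp.glp_set_row_bnds(prob, r, glp.GLP_FX, con.rhs, con.rhs)
            for var, coef in con.coefficients.items():
                entries.append((r, p.variable_index(var) + 1, float(coef)))
        n = len(entries)
        ia, ja, ar = glp.intArray(n + 1), glp.intArray(n + 1), glp.doubleArray(n + 1)
        for k, (r, cidx, coef) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = r, cidx, coef
        glp.glp_load_matrix(prob, n, ia, ja, ar)
        parm = glp.glp_iocp()
        glp.glp_init_iocp(parm)
        parm.presolve = glp.GLP_ON
        parm.msg_lev = glp.GLP_MSG_OFF
        if opts.max_time is not None:
            parm.tm_lim = int(opts.max_time * 1000)
        ret = glp.glp_intopt(prob, parm)
        status = glp.glp_mip_status(prob)
        if status in (glp.GLP_OPT, glp.GLP_FEAS):
            x = np.array(
                [glp.glp_mip_col_val(prob, i + 1) for i in range(p.ncols)]
            )
            assignment = _round_solution(p, x, opts.feasibility_tol)
            label = "optimal" if status == glp.GLP_OPT else "time_limit"
            return SolverResult(
                label, float(glp.glp_mip_obj_val(prob)), assignment, "glpk", str(ret)
            )
        if status == glp.GLP_NOFEAS or ret == glp.GLP_ENOPFS:
            return SolverResult("infeasible", None, None, "glpk", str(ret))
        if ret == glp.GLP_ENODFS:
            # LP relaxation has no dual feasible solution: unbounded relaxation
            return SolverResult("unbounded", None, None, "glpk", str(ret))
        return SolverResult("error", None, None, "glpk", str(ret))
    finally:
        glp.glp_delete_prob(prob)


_BACKENDS = {"highs": _solve_highs, "glpk": _solve_glpk}


def available_backends() -> list[str]:
    avail = ["highs"]
    try:
        import swiglpk  # noqa: F401

        avail.append("glpk")
    except ImportError:
        pass
    return avail


def solve(p: MilpProblem, opts: SolverOptions | None = None) -> SolverResult:
    """Solve a MILP (minimization) with the configured or first available
    backend; raises if the backend itself fails."""
    opts = opts or SolverOptions()
    names = [opts.backend] if opts.backend else available_backends()
    last_exc: Exception | None = None
    for name in names:
        if name not in _BACKENDS:
            raise ValueError(f"unknown backend {name!r}")
        try:
            return _BACKENDS[name](p, opts)
        except ImportError as exc:
            last_exc = exc
    raise RuntimeError(f"no MILP backend available: {last_exc}")


# ---------------------------------------------------------------------------
# Problem export
# ---------------------------------------------------------------------------

def _lp_name(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "_." else "_" for ch in name)


def _lp_terms(coeffs: Mapping[str, float]) -> str:
    parts = []
    for var, coef in coeffs.items():
        sign = "-" if coef < 0 else "+"
        parts.append(f"{sign} {abs(coef):.12g} {_lp_name(var)}")
    text = " ".join(parts)
    return text[2:] if text.startswith("+ ") else text


def write_lp(p: MilpProblem, path: str) -> None:
    """CPLEX-LP text export: objective, rows in insertion order, bounds,
    then integer/binary sections."""
    sense_txt = {"<": "<=", "=": "=", ">": ">="}
    if p.obj:
        obj_terms = _lp_terms(p.obj)
    elif p.varnames:
        obj_terms = f"0 {_lp_name(p.varnames[0])}"
    else:
        obj_terms = "0"
    lines = ["Minimize", f" obj: {obj_terms}"]
    lines.append("Subject To")
    for con in p.constraints:
        lines.append(
            f" {_lp_name(con.name)}: {_lp_terms(con.coefficients)} {sense_txt[con.sense]} {con.rhs:.12g}"
        )
    lines.append("Bounds")
    for name, lo, up in zip(p.varnames, p.lb, p.ub):
        lo_s = "-inf" if lo == -math.inf else f"{lo:.12g}"
        up_s = "+inf" if up == math.inf else f"{up:.12g}"
        lines.append(f" {lo_s} <= {_lp_name(name)} <= {up_s}")
    generals = [n for n, t in zip(p.varnames, p.vartype) if t == "i"]
    binaries = [n for n, t in zip(p.varnames, p.vartype) if t == "b"]
    if generals:
        lines.append("Generals")
        lines.extend(f" {_lp_name(n)}" for n in generals)
    if binaries:
        lines.append("Binaries")
        lines.extend(f" {_lp_name(n)}" for n in binaries)
    lines.append("End")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_mps(p: MilpProblem, path: str) -> None:
    """Free-form MPS export (ROWS, COLUMNS with integer markers, RHS,
    BOUNDS), rows and columns in insertion order."""
    sense_row = {"<": "L", "=": "E", ">": "G"}
    lines = ["NAME fluxlogic", "ROWS", " N obj"]
    for con in p.constraints:
        lines.append(f" {sense_row[con.sense]} {_lp_name(con.name)}")
    lines.append("COLUMNS")
    by_var: dict[str, list[tuple[str, float]]] = {n: [] for n in p.varnames}
    for name, coef in p.obj.items():
        by_var[name].append(("obj", coef))
    for con in p.constraints:
        for var, coef in con.coefficients.items():
            by_var[var].append((_lp_name(con.name), coef))
    for name, vt in zip(p.varnames, p.vartype):
        entries = by_var[name]
        is_int = vt in ("b", "i")
        if is_int:
            lines.append(" MARKER 'MARKER' 'INTORG'")
        for row, coef in entries:
            lines.append(f" {_lp_name(name)} {row} {coef:.12g}")
        if not entries:
            lines.append(f" {_lp_name(name)} obj 0")
        if is_int:
            lines.append(" MARKER 'MARKER' 'INTEND'")
    lines.append("RHS")
    for con in p.constraints:
        lines.append(f" RHS {_lp_name(con.name)} {con.rhs:.12g}")
    lines.append("BOUNDS")
    for name, lo, up in zip(p.varnames, p.lb, p.ub):
        if lo == -math.inf:
            lines.append(f" MI BND {_lp_name(name)}")
        else:
            lines.append(f" LO BND {_lp_name(name)} {lo:.12g}")
        if up == math.inf:
            lines.append(f" PL BND {_lp_name(name)}")
        else:
            lines.append(f" UP BND {_lp_name(name)} {up:.12g}")
    lines.append("ENDATA")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
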