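"""Couple metabolic models with GPR and regulatory logic.

A :class:`MetabolicModel` holds the stoichiometric matrix, flux bounds,
objective and per-reaction GPR strings.  :func:`couple` compiles every GPR
as ``GPR <=> R_i`` (one binary participation indicator per gene-associated
reaction) and ties the indicator to the flux with

    vmin_i * R_i  <=  v_i  <=  vmax_i * R_i

so reactions whose GPR is unsatisfied carry zero flux.  Regulatory rules
are appended to the same mixed-integer program, and FBA then maximizes the
flux objective subject to mass balance, bounds and all compiled logic — the
regulatory and metabolic problems are solved simultaneously, so the
returned gene state is always stable.

Also here: the structured-text model dialect, SBML I/O (delegated to
cobrapy), synchronous iteration of explicit rule sets to a fixed point or
cycle, and a minimal-relaxation diagnosis of rules that make a model unable
to reach its objective.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .compiler import (
    LinearConstraint,
    MilpProblem,
    RuleCompiler,
    SolverOptions,
    SolverResult,
    solve,
)
from .rules import (
    Atom,
    Expression,
    NotMode,
    Rule,
    Variable,
    collect_variables,
    evaluate_expression,
    parse_expression,
    parse_rule,
)

__all__ = [
    "MetabolicModel",
    "CoupledModel",
    "IterationTrace",
    "load_model",
    "save_model",
    "couple",
    "add_rules",
    "fba",
    "simulate_iterative",
    "find_infeasible_rules",
]


# ---------------------------------------------------------------------------
# Metabolic model container and I/O
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """Constraint-based model: S (metabolites x reactions), flux bounds,
    linear objective, genes, and one GPR string per reaction ('' = none)."""

    mets: list[str]
    rxns: list[str]
    S: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    objective: np.ndarray
    genes: list[str]
    gpr: list[str]

    def __post_init__(self) -> None:
        nm, nr = len(self.mets), len(self.rxns)
        self.S = np.asarray(self.S, dtype=float)
        self.vmin = np.asarray(self.vmin, dtype=float)
        self.vmax = np.asarray(self.vmax, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.S.shape != (nm, nr):
            raise ValueError(f"S is {self.S.shape}, expected ({nm}, {nr})")
        for arr, label in ((self.vmin, "vmin"), (self.vmax, "vmax"), (self.objective, "objective")):
            if arr.shape != (nr,):
                raise ValueError(f"{label} has length {arr.shape}, expected {nr}")
        if np.any(self.vmin > self.vmax):
            raise ValueError("vmin > vmax for some reaction")
        if len(self.gpr) != nr:
            raise ValueError("need one GPR string per reaction")
        self._check_gpr_genes()

    def _check_gpr_genes(self) -> None:
        """Genes referenced by a GPR but missing from the gene list are
        auto-declared (logged to stderr as a warning)."""
        import sys

        known = set(self.genes)
        for rxn, text in zip(self.rxns, self.gpr):
            if not text.strip():
                continue
            try:
                expr = parse_expression(text)
            except ValueError as exc:
                raise ValueError(f"GPR for reaction {rxn!r} does not parse: {exc}") from None
            for name in _expr_names(expr):
                if name not in known:
                    print(
                        f"warning: GPR of {rxn} references undeclared gene {name!r}; declaring it",
                        file=sys.stderr,
                    )
                    known.add(name)
                    self.genes.append(name)

    def reaction_index(self, rxn: str) -> int:
        return self.rxns.index(rxn)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.mets),
            list(self.rxns),
            self.S.copy(),
            self.vmin.copy(),
            self.vmax.copy(),
            self.objective.copy(),
            list(self.genes),
            list(self.gpr),
        )


def _expr_names(expr: Expression) -> list[str]:
    from .rules import rule_atoms

    return rule_atoms(Rule(expr, expr, "=>"))


# -- structured text dialect -------------------------------------------------

_ARROW_RE = re.compile(r"(<->|->)")


def _parse_reaction_string(text: str, lineno: int) -> tuple[dict[str, float], bool]:
    m = _ARROW_RE.search(text)
    if not m:
        raise ValueError(f"line {lineno}: reaction string needs '->' or '<->': {text!r}")
    reversible = m.group(1) == "<->"
    lhs, rhs = text[: m.start()], text[m.end() :]
    stoich: dict[str, float] = {}

    def side(chunk: str, sign: float) -> None:
        chunk = chunk.strip()
        if not chunk:
            return
        for term in chunk.split("+"):
            parts = term.split()
            if not parts:
                raise ValueError(f"line {lineno}: empty term in {text!r}")
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ValueError(f"line {lineno}: bad term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    side(lhs, -1.0)
    side(rhs, +1.0)
    return stoich, reversible


_SECTIONS = ("METABOLITES", "REACTIONS", "BOUNDS", "OBJECTIVE", "GPR", "GENES")


def _read_structured_text(path: str) -> MetabolicModel:
    mets: list[str] = []
    rxn_order: list[str] = []
    stoichs: dict[str, dict[str, float]] = {}
    reversible: dict[str, bool] = {}
    bounds: dict[str, tuple[float, float]] = {}
    objective: dict[str, float] = {}
    gprs: dict[str, str] = {}
    genes: list[str] = []
    section = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("%", 1)[0].rstrip("\n").strip()
            if not line:
                continue
            if line in _SECTIONS:
                section = line
                continue
            if section is None:
                raise ValueError(f"line {lineno}: content before any section header")
            fields = [f.strip() for f in line.split("\t")]
            if section == "METABOLITES":
                mets.append(fields[0])
            elif section == "GENES":
                genes.append(fields[0])
            elif section == "REACTIONS":
                if len(fields) != 2:
                    raise ValueError(f"line {lineno}: REACTIONS needs 'name<TAB>equation'")
                name, eqn = fields
                if name in stoichs:
                    raise ValueError(f"line {lineno}: duplicate reaction {name!r}")
                stoichs[name], reversible[name] = _parse_reaction_string(eqn, lineno)
                rxn_order.append(name)
            elif section == "BOUNDS":
                if len(fields) != 3:
                    raise ValueError(f"line {lineno}: BOUNDS needs 'name<TAB>lo<TAB>hi'")
                bounds[fields[0]] = (float(fields[1]), float(fields[2]))
            elif section == "OBJECTIVE":
                if len(fields) not in (1, 2):
                    raise ValueError(f"line {lineno}: OBJECTIVE needs 'name[<TAB>coef]'")
                objective[fields[0]] = float(fields[1]) if len(fields) == 2 else 1.0
            elif section == "GPR":
                if len(fields) != 2:
                    raise ValueError(f"line {lineno}: GPR needs 'name<TAB>rule'")
                gprs[fields[0]] = fields[1]
    for name in list(bounds) + list(objective) + list(gprs):
        if name not in stoichs:
            raise ValueError(f"unknown reaction {name!r} referenced in model file")
    if not mets:
        mets = sorted({m for st in stoichs.values() for m in st})
    S = np.zeros((len(mets), len(rxn_order)))
    met_idx = {m: i for i, m in enumerate(mets)}
    vmin = np.zeros(len(rxn_order))
    vmax = np.zeros(len(rxn_order))
    obj = np.zeros(len(rxn_order))
    gpr_list = []
    for j, name in enumerate(rxn_order):
        for met, coef in stoichs[name].items():
            if met not in met_idx:
                raise ValueError(f"reaction {name!r} uses undeclared metabolite {met!r}")
            S[met_idx[met], j] = coef
        lo, hi = bounds.get(name, (-1000.0, 1000.0) if reversible[name] else (0.0, 1000.0))
        vmin[j], vmax[j] = lo, hi
        obj[j] = objective.get(name, 0.0)
        gpr_list.append(gprs.get(name, ""))
    return MetabolicModel(mets, rxn_order, S, vmin, vmax, obj, genes, gpr_list)


def _write_structured_text(model: MetabolicModel, path: str) -> None:
    lines = ["METABOLITES"]
    lines.extend(model.mets)
    lines.append("REACTIONS")
    for j, rxn in enumerate(model.rxns):
        subs, prods = [], []
        for i, met in enumerate(model.mets):
            coef = model.S[i, j]
            if coef < 0:
                subs.append(f"{-coef:g} {met}" if coef != -1 else met)
            elif coef > 0:
                prods.append(f"{coef:g} {met}" if coef != 1 else met)
        arrow = "<->" if model.vmin[j] < 0 else "->"
        lines.append(f"{rxn}\t{' + '.join(subs)} {arrow} {' + '.join(prods)}".rstrip())
    lines.append("BOUNDS")
    for j, rxn in enumerate(model.rxns):
        lines.append(f"{rxn}\t{model.vmin[j]:g}\t{model.vmax[j]:g}")
    lines.append("OBJECTIVE")
    for j, rxn in enumerate(model.rxns):
        if model.objective[j]:
            lines.append(f"{rxn}\t{model.objective[j]:g}")
    lines.append("GPR")
    for j, rxn in enumerate(model.rxns):
        if model.gpr[j].strip():
            lines.append(f"{rxn}\t{model.gpr[j]}")
    if model.genes:
        lines.append("GENES")
        lines.extend(model.genes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# -- SBML (via cobrapy) ------------------------------------------------------

def _from_cobra(cb) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(cb)
    mets = [m.id for m in cb.metabolites]
    rxns = [r.id for r in cb.reactions]
    vmin = np.array([r.lower_bound for r in cb.reactions])
    vmax = np.array([r.upper_bound for r in cb.reactions])
    obj = np.array([r.objective_coefficient for r in cb.reactions])
    genes = [g.id for g in cb.genes]
    gpr = [r.gene_reaction_rule or "" for r in cb.reactions]
    return MetabolicModel(mets, rxns, S, vmin, vmax, obj, genes, gpr)


def _to_cobra(model: MetabolicModel):
    import cobra

    cb = cobra.Model("fluxlogic")
    cobra_mets = {m: cobra.Metabolite(m, compartment="c") for m in model.mets}
    for j, rxn in enumerate(model.rxns):
        r = cobra.Reaction(rxn)
        r.lower_bound = float(model.vmin[j])
        r.upper_bound = float(model.vmax[j])
        cb.add_reactions([r])
        r.add_metabolites(
            {
                cobra_mets[met]: float(model.S[i, j])
                for i, met in enumerate(model.mets)
                if model.S[i, j] != 0
            }
        )
        if model.gpr[j].strip():
            r.gene_reaction_rule = model.gpr[j]
    cb.objective = {
        cb.reactions.get_by_id(rxn): float(model.objective[j])
        for j, rxn in enumerate(model.rxns)
        if model.objective[j] != 0
    }
    return cb


def load_model(path: str, format: str = "structured_text") -> MetabolicModel:
    """Read a model from ``structured_text`` (native dialect) or ``sbml``."""
    if format == "structured_text":
        return _read_structured_text(path)
    if format == "sbml":
        from cobra.io import read_sbml_model

        return _from_cobra(read_sbml_model(path))
    raise ValueError(f"unknown format {format!r}")


def save_model(model: MetabolicModel, path: str, format: str = "structured_text") -> None:
    if format == "structured_text":
        _write_structured_text(model, path)
    elif format == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(_to_cobra(model), path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Coupling
# ---------------------------------------------------------------------------

def indicator_name(rxn: str) -> str:
    return f"R_{rxn}"


@dataclass
class CoupledModel:
    """A metabolic model fused with its compiled logic into one MILP."""

    model: MetabolicModel
    problem: MilpProblem
    compiler: RuleCompiler
    flux_vars: dict[str, str]
    indicator_vars: dict[str, str]
    gene_vars: dict[str, str]
    rules: list[Rule] = field(default_factory=list)
    objective_row: str | None = None

    @property
    def mode(self) -> NotMode:
        return self.compiler.mode

    def regulatory_rule_ids(self) -> list[int]:
        return [r.id for r in self.rules]


def couple(
    model: MetabolicModel,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    gene_upper: int = 1,
    couple_fluxes: bool = True,
    prefix: str = "",
    into: RuleCompiler | None = None,
) -> CoupledModel:
    """Build the coupled MILP from a metabolic model.

    Every reaction gets a continuous flux column (named after the reaction,
    so conditionals can reference fluxes directly).  Reactions with a GPR
    get an integer participation indicator defined by ``GPR <=> R_i``.  With
    ``couple_fluxes`` (the default, binary genes) the flux is tied to the
    indicator by ``vmin*R <= v <= vmax*R``.  Multilevel genes
    (``gene_upper > 1``, used by the activity-matching integration) get
    indicators bounded by the min/max composition of the GPR instead, and
    no flux tie — callers add their own activity constraints.

    ``into`` reuses an existing compiler/problem so several conditions can
    share one MILP (pass a distinct ``prefix`` per condition).
    """
    if into is not None:
        rc = into
        if rc.mode != mode:
            raise ValueError("mode of shared compiler differs")
        problem = rc.problem
    else:
        problem = MilpProblem()
        rc = RuleCompiler(problem=problem, mode=mode)
    flux_vars: dict[str, str] = {}
    for j, rxn in enumerate(model.rxns):
        col = prefix + rxn
        problem.add_variable(col, float(model.vmin[j]), float(model.vmax[j]), "c")
        rc.variables[col] = Variable(col, 0, 1, kind="flux")
        flux_vars[rxn] = col
    for i, met in enumerate(model.mets):
        coeffs = {
            flux_vars[model.rxns[j]]: float(model.S[i, j])
            for j in range(len(model.rxns))
            if model.S[i, j] != 0
        }
        if coeffs:
            problem.add_constraint(LinearConstraint(coeffs, "=", 0.0, f"{prefix}mb_{met}"))
    gene_vars: dict[str, str] = {}
    for gene in model.genes:
        col = prefix + gene
        rc.declare(Variable(col, 0, gene_upper, kind="gene"))
        gene_vars[gene] = col
    from .rules import expression_upper_bound

    indicator_vars: dict[str, str] = {}
    for j, rxn in enumerate(model.rxns):
        text = model.gpr[j].strip()
        if not text:
            continue
        try:
            gpr_expr = parse_expression(text)
        except ValueError as exc:
            raise ValueError(f"GPR for reaction {rxn!r}: {exc}") from None
        if prefix:
            gpr_expr = _rename_expression(gpr_expr, lambda n: prefix + n)
        r_up = (
            1
            if gene_upper == 1
            else int(expression_upper_bound(gpr_expr, rc.variables))
        )
        r_col = prefix + indicator_name(rxn)
        rc.declare(Variable(r_col, 0, max(r_up, 1), kind="reaction_indicator"))
        indicator_vars[rxn] = r_col
        rule = Rule(gpr_expr, Atom(r_col), "<=>", source_text=f"{text} <=> {r_col}", id=-(j + 1))
        rc.add_rule(rule)
        if couple_fluxes:
            v = flux_vars[rxn]
            problem.add_constraint(
                LinearConstraint(
                    {v: 1.0, r_col: -float(model.vmax[j])}, "<", 0.0, f"{prefix}cpl_{rxn}_ub"
                )
            )
            problem.add_constraint(
                LinearConstraint(
                    {v: 1.0, r_col: -float(model.vmin[j])}, ">", 0.0, f"{prefix}cpl_{rxn}_lb"
                )
            )
    return CoupledModel(model, problem, rc, flux_vars, indicator_vars, gene_vars)


def _rename_expression(expr: Expression, fn) -> Expression:
    from .rules import Conditional, Const, Junction, Not

    if isinstance(expr, Atom):
        return Atom(fn(expr.name))
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(_rename_expression(expr.operand, fn))
    if isinstance(expr, Junction):
        return Junction(expr.op, _rename_expression(expr.left, fn), _rename_expression(expr.right, fn))
    if isinstance(expr, Conditional):
        return Conditional(
            _rename_expression(expr.left, fn), expr.op, _rename_expression(expr.right, fn)
        )
    raise TypeError(expr)


def add_rules(
    cm: CoupledModel,
    rules: Iterable[Rule | str],
    declared: Mapping[str, Variable] | None = None,
) -> CoupledModel:
    """Attach regulatory rules to a coupled model in place.

    Existing columns are reused by name; only new columns and rows are
    appended.  String rules are parsed; ids are assigned after the highest
    existing regulatory rule id.
    """
    next_id = max((r.id for r in cm.rules), default=0) + 1
    for var in (declared or {}).values():
        cm.compiler.declare(var)
    for item in rules:
        rule = parse_rule(item) if isinstance(item, str) else item
        if rule.id < 0:
            from dataclasses import replace

            rule = replace(rule, id=next_id)
        next_id = rule.id + 1
        cm.compiler.add_rule(rule)
        cm.rules.append(rule)
    return cm


# ---------------------------------------------------------------------------
# FBA on the coupled problem
# ---------------------------------------------------------------------------

def fba(
    cm: CoupledModel,
    fix: Mapping[str, float] | None = None,
    opts: SolverOptions | None = None,
) -> tuple[float, dict[str, float], dict[str, int]]:
    """Maximize the flux objective subject to mass balance and all logic.

    ``fix`` pins named columns (genes, environment indicators, fluxes) to a
    value.  Returns (objective value, flux distribution, gene state); the
    gene state is feasible for every rule, i.e. stable.  Raises
    ``InfeasibleError`` when no solution meets the constraints.
    """
    if not np.any(cm.model.objective):
        raise ValueError("model has no objective reaction")
    p = cm.problem.copy()
    p.obj = {
        cm.flux_vars[rxn]: -float(cm.model.objective[j])
        for j, rxn in enumerate(cm.model.rxns)
        if cm.model.objective[j] != 0
    }
    for name, value in (fix or {}).items():
        if not p.has_variable(name):
            raise KeyError(f"cannot fix unknown variable {name!r}")
        p.set_bounds(name, float(value), float(value))
    res = solve(p, opts)
    if res.status == "infeasible":
        raise InfeasibleError("coupled model is infeasible under the given state")
    if not res.ok:
        raise RuntimeError(f"solver returned {res.status} ({res.backend})")
    assert res.assignment is not None
    fluxes = {rxn: res.assignment[col] for rxn, col in cm.flux_vars.items()}
    genes = {g: int(res.assignment[col]) for g, col in cm.gene_vars.items()}
    return -res.objective_value + 0.0, fluxes, genes


class InfeasibleError(RuntimeError):
    """The MILP admits no solution under the requested constraints."""


# ---------------------------------------------------------------------------
# Synchronous iteration
# ---------------------------------------------------------------------------

@dataclass
class IterationTrace:
    """States of a synchronous rule iteration; ``states[0]`` is the start.

    ``terminal`` is ``"fixed_point"``, ``"cycle"`` (with ``cycle_length``),
    or ``"max_iter"``.
    """

    states: list[dict[str, int]]
    terminal: str
    cycle_length: int = 0

    def state_at(self, iteration: int) -> dict[str, int]:
        """State after *iteration* synchronous updates, extrapolating a
        reached fixed point or cycle beyond the stored states."""
        if iteration < len(self.states):
            return self.states[iteration]
        if self.terminal == "fixed_point":
            return self.states[-1]
        if self.terminal == "cycle":
            start = len(self.states) - self.cycle_length
            return self.states[start + (iteration - start) % self.cycle_length]
        raise IndexError(f"iteration {iteration} beyond max_iter trace")


def simulate_iterative(
    rules: Sequence[Rule | str],
    init: Mapping[str, int],
    environment: Mapping[str, int] | None = None,
    max_iter: int = 100,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    declared: Mapping[str, Variable] | None = None,
) -> IterationTrace:
    """Synchronously iterate explicit (``<=>``) rules from a start state.

    Each iteration recomputes every rule-defined variable from the full
    previous state (consequent := value of antecedent).  Environment
    variables stay fixed; variables with no defining rule hold their value.
    Stops at a fixed point, a detected cycle, or ``max_iter``.
    """
    parsed = [parse_rule(r) if isinstance(r, str) else r for r in rules]
    env = dict(environment or {})
    defining: dict[str, Expression] = {}
    for rule in parsed:
        if not rule.is_iff or not isinstance(rule.consequent, Atom):
            raise ValueError(
                f"synchronous update needs explicit rules 'expr <=> var': {rule.source_text!r}"
            )
        target = rule.consequent.name
        if target in defining:
            raise ValueError(f"variable {target!r} has two defining rules")
        if target in env:
            raise ValueError(f"environment variable {target!r} cannot have a rule")
        defining[target] = rule.antecedent
    variables = collect_variables(parsed, declared)
    state = {name: 0 for name in variables}
    state.update(init)
    state.update(env)
    states = [dict(state)]
    seen = {tuple(sorted(state.items())): 0}
    terminal, cycle_length = "max_iter", 0
    for _ in range(max_iter):
        nxt = dict(state)
        for target, antecedent in defining.items():
            value = evaluate_expression(antecedent, state, mode, variables)
            upper = variables[target].upper if target in variables else 1
            nxt[target] = int(min(max(value, 0), upper))
        states.append(nxt)
        key = tuple(sorted(nxt.items()))
        if key in seen:
            length = len(states) - 1 - seen[key]
            terminal = "fixed_point" if length == 1 else "cycle"
            cycle_length = 0 if length == 1 else length
            state = nxt
            break
        seen[key] = len(states) - 1
        state = nxt
    return IterationTrace(states, terminal, cycle_length)


# ---------------------------------------------------------------------------
# Infeasibility diagnosis
# ---------------------------------------------------------------------------

def _row_box_extreme(
    con: LinearConstraint, p: MilpProblem, maximize: bool
) -> float:
    total = 0.0
    for var, coef in con.coefficients.items():
        lo, hi = p.variable_bounds(var)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"variable {var!r} needs finite bounds for relaxation big-M")
        total += coef * (hi if (coef > 0) == maximize else lo)
    return total


def default_objective_floor(model: MetabolicModel) -> float:
    """1e-3 of the objective's bound-propagation upper limit."""
    ub = 0.0
    for j in range(len(model.rxns)):
        c = model.objective[j]
        if c > 0:
            ub += c * model.vmax[j]
        elif c < 0:
            ub += c * model.vmin[j]
    if ub <= 0:
        raise ValueError("objective upper bound is nonpositive; supply objective_floor")
    return 1e-3 * ub


def find_infeasible_rules(
    cm: CoupledModel,
    objective_floor: float | None = None,
    relaxable: Sequence[int] | None = None,
    opts: SolverOptions | None = None,
) -> tuple[list[int], SolverResult]:
    """Smallest set of regulatory rules whose deactivation restores an
    objective flux of at least ``objective_floor``.

    Each candidate rule gets a binary relaxation switch; switching it on
    disables every constraint row that rule generated, with big-M slack
    derived from variable bounds.  The MILP minimizes the number of
    switched-on rules.  Raises if the model is already feasible at the
    floor (nothing to diagnose) or if even full relaxation cannot reach it.
    """
    if objective_floor is None:
        objective_floor = default_objective_floor(cm.model)
    obj_coeffs = {
        cm.flux_vars[rxn]: float(cm.model.objective[j])
        for j, rxn in enumerate(cm.model.rxns)
        if cm.model.objective[j] != 0
    }
    if not obj_coeffs:
        raise ValueError("model has no objective reaction")
    floor_row = LinearConstraint(obj_coeffs, ">", float(objective_floor), "objective_floor")

    base = cm.problem.copy()
    base.add_constraint(floor_row)
    base.obj = {}
    if solve(base, opts).status != "infeasible":
        raise ValueError("nothing to diagnose: model reaches the objective floor")

    rule_ids = list(relaxable) if relaxable is not None else cm.regulatory_rule_ids()
    row_owner: dict[str, list[int]] = {}
    for rid in rule_ids:
        for row in cm.compiler.rule_rows.get(rid, []):
            row_owner.setdefault(row, []).append(rid)

    relaxed = MilpProblem()
    for name, lo, up, vt in zip(
        cm.problem.varnames, cm.problem.lb, cm.problem.ub, cm.problem.vartype
    ):
        relaxed.add_variable(name, lo, up, vt)
    switches = {rid: f"__relax_{rid}" for rid in rule_ids}
    for col in switches.values():
        relaxed.add_variable(col, 0, 1, "b")

    def relax_row(con: LinearConstraint, owners: list[int]) -> list[LinearConstraint]:
        out = []
        pieces = (
            [(con.sense, con.rhs)]
            if con.sense != "="
            else [("<", con.rhs), (">", con.rhs)]
        )
        for k, (sense, rhs) in enumerate(pieces):
            coeffs = dict(con.coefficients)
            if sense == "<":
                M = max(_row_box_extreme(con, cm.problem, maximize=True) - rhs, 0.0)
                for rid in owners:
                    coeffs[switches[rid]] = coeffs.get(switches[rid], 0.0) - M
            else:
                M = max(rhs - _row_box_extreme(con, cm.problem, maximize=False), 0.0)
                for rid in owners:
                    coeffs[switches[rid]] = coeffs.get(switches[rid], 0.0) + M
            suffix = f"_rx{k}" if con.sense == "=" else "_rx"
            out.append(LinearConstraint(coeffs, sense, rhs, con.name + suffix))
        return out

    for con in cm.problem.constraints:
        if con.name in row_owner:
            for rc in relax_row(con, row_owner[con.name]):
                relaxed.add_constraint(rc)
        else:
            relaxed.add_constraint(con)
    relaxed.add_constraint(floor_row)
    relaxed.obj = {col: 1.0 for col in switches.values()}
    res = solve(relaxed, opts)
    if res.status == "infeasible":
        raise InfeasibleError(
            "model cannot reach the objective floor even with all rules relaxed"
        )
    if not res.ok:
        raise RuntimeError(f"solver returned {res.status}")
    assert res.assignment is not None
    culprits = sorted(rid for rid, col in switches.items() if res.assignment[col] > 0.5)
    return culprits, res
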