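"""Independent oracles used across the test suite.

These deliberately avoid the code paths they validate: feasibility of a
compiled MILP is checked by enumerating the integer grid and testing
``A x (sense) b`` directly with numpy; flux optima come from
``scipy.optimize.linprog`` on the raw stoichiometry with GPR gating done by
direct expression evaluation; MADE's matched weight is recomputed
arithmetically over explicit gene-state combinations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

import fluxlogic as fl
from fluxlogic.rules import evaluate_expression, parse_expression


def grid_projection(problem, original_names, tol=1e-9, cap=200_000):
    """Feasible integer points of a MILP projected onto *original_names*,
    by brute-force enumeration of every column's integer range.

    Returns None if the full grid exceeds *cap* points (caller should
    regenerate a smaller system).
    """
    n_cols = problem.ncols
    sizes = []
    for i in range(n_cols):
        lo, hi = problem.lb[i], problem.ub[i]
        sizes.append(int(hi) - int(lo) + 1)
    total = 1
    for s in sizes:
        total *= s
        if total > cap:
            return None
    grids = [
        np.arange(int(problem.lb[i]), int(problem.ub[i]) + 1) for i in range(n_cols)
    ]
    pts = np.array(list(itertools.product(*grids)), dtype=float)
    A = problem.A().toarray()
    b = problem.b
    Ax = pts @ A.T
    ok = np.ones(len(pts), dtype=bool)
    for r, sense in enumerate(problem.ctype):
        if sense == "<":
            ok &= Ax[:, r] <= b[r] + tol
        elif sense == ">":
            ok &= Ax[:, r] >= b[r] - tol
        else:
            ok &= np.abs(Ax[:, r] - b[r]) <= tol
    cols = [problem.variable_index(n) for n in original_names]
    return {tuple(int(v) for v in row[cols]) for row in pts[ok]}


def enumeration_states(rules, variables, mode):
    """Reference feasible states as a set of tuples ordered by sorted name."""
    names = sorted(variables)
    return {
        tuple(s[n] for n in names)
        for s in fl.enumerate_feasible_states(rules, variables, mode)
    }


def random_rule_system(rng, max_vars=5, max_level=3, with_conditionals=True):
    """A random small multilevel rule system (levels start at 0)."""
    n_vars = int(rng.integers(2, max_vars + 1))
    names = [f"v{i}" for i in range(n_vars)]
    variables = {
        n: fl.Variable(n, 0, int(rng.integers(1, max_level + 1))) for n in names
    }

    def expr(depth):
        r = rng.random()
        if depth <= 0 or r < 0.35:
            a = fl.Atom(str(rng.choice(names)))
            return fl.Not(a) if rng.random() < 0.3 else a
        if with_conditionals and r < 0.45:
            n = str(rng.choice(names))
            op = str(rng.choice(["<", "<=", ">", ">=", "=", "!="]))
            c = int(rng.integers(0, variables[n].upper + 1))
            return fl.Conditional(fl.Atom(n), op, fl.Const(float(c)))
        op = "and" if rng.random() < 0.5 else "or"
        e = fl.Junction(op, expr(depth - 1), expr(depth - 1))
        return fl.Not(e) if rng.random() < 0.2 else e

    n_rules = int(rng.integers(1, 4))
    rules = [
        fl.Rule(
            expr(2),
            expr(1),
            "<=>" if rng.random() < 0.5 else "=>",
            source_text=f"random rule {i + 1}",
            id=i + 1,
        )
        for i in range(n_rules)
    ]
    return rules, variables


def lp_fba(model, gene_state=None):
    """Plain-LP flux optimum with GPR gating by direct rule evaluation.

    Reactions whose GPR evaluates false under *gene_state* get their flux
    bounds forced to zero.  Returns the maximal objective value, or None if
    infeasible.
    """
    vmin = model.vmin.copy()
    vmax = model.vmax.copy()
    if gene_state is not None:
        for j, text in enumerate(model.gpr):
            if not text.strip():
                continue
            value = evaluate_expression(parse_expression(text), gene_state)
            if value <= 0:
                vmin[j] = vmax[j] = 0.0
    res = linprog(
        -model.objective,
        A_eq=model.S,
        b_eq=np.zeros(len(model.mets)),
        bounds=list(zip(vmin, vmax)),
        method="highs",
    )
    if not res.success:
        return None
    return -res.fun


def feasible_gene_states(model, floor):
    """All binary gene assignments whose gated LP optimum reaches *floor*."""
    genes = model.genes
    out = []
    for bits in itertools.product((0, 1), repeat=len(genes)):
        state = dict(zip(genes, bits))
        opt = lp_fba(model, state)
        if opt is not None and opt >= floor - 1e-9:
            out.append(state)
    return out


def made_weight(states_by_cond, fc, T, delta=0.05, weight=lambda p: 1.0 - p):
    """Significance-weighted count of realized expression changes for a
    candidate per-condition gene-state map."""
    total = 0.0
    for k, (i, j) in T.entries.items():
        for gene, cols in fc.fold.items():
            if k not in cols:
                continue
            f, p = cols[k], fc.pval[gene][k]
            xi, xj = states_by_cond[i][gene], states_by_cond[j][gene]
            if f > 1 + delta:
                hit = xj > xi
            elif f < 1 - delta:
                hit = xj < xi
            else:
                hit = xj == xi
            if hit:
                total += weight(p)
    return total
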