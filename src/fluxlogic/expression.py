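"""Gene-centric expression integration: GIMME, iMAT, and MADE.

All three algorithms run on the coupled metabolism+logic MILP, so every
returned gene state is feasible for the rules and meets its flux-objective
constraint.

* **GIMME** — genes at or above an expression threshold are fixed on; genes
  below default off but may be reactivated, at a cost equal to their
  distance below the threshold, so that the model still reaches a required
  fraction of its optimal objective flux.  The solver minimizes the total
  reactivation cost and reports every gene as on or off.

* **iMAT** — genes take three activity levels (0 low, 1 medium, 2 high);
  the GPR's min/max composition gives each reaction an indicator with the
  same levels.  A high indicator forces |v| >= epsilon (direction chosen by
  a binary for reversible reactions), a low indicator forces |v| <= epsilon.
  The solver maximizes the number of genes whose level equals their call.

* **MADE** — expression is compared across two or more conditions linked by
  a transition matrix; a fold change above 1 asks the gene to increase
  between the linked conditions, below 1 to decrease, near 1 to stay equal.
  One MILP over all conditions maximizes the significance-weighted number
  of realized changes while every condition keeps a minimum objective flux.

Alternate optima are broken lexicographically: a secondary objective with
weight 1e-4 prefers states with more genes on, for reproducible output
across solver backends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compiler import LinearConstraint, SolverOptions, solve
from .model import CoupledModel, InfeasibleError, MetabolicModel, couple, fba
from .rules import Atom, Conditional, Const, NotMode

__all__ = [
    "ExpressionProfile",
    "ActivityCalls",
    "FoldChangeTable",
    "TransitionMatrix",
    "IntegrationResult",
    "gimme",
    "imat",
    "made",
]

TIE_BREAK_WEIGHT = 1e-4  # secondary objective: prefer more genes on


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Per-gene expression values plus the on/off threshold (same units)."""

    values: dict[str, float]
    threshold: float

    @classmethod
    def from_tsv(cls, path: str, threshold: float) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t")
        gene_col, value_col = df.columns[0], df.columns[1]
        return cls(dict(zip(df[gene_col], df[value_col].astype(float))), threshold)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"gene": list(self.values), "expression": list(self.values.values())}
        ).to_csv(path, sep="\t", index=False)


_CALL_NAMES = {"low": 0, "medium": 1, "high": 2, "0": 0, "1": 1, "2": 2}
_LEVEL_NAMES = {0: "low", 1: "medium", 2: "high"}


@dataclass
class ActivityCalls:
    """Per-gene three-level activity calls: 0 low, 1 medium, 2 high."""

    calls: dict[str, int]

    def __post_init__(self) -> None:
        for gene, level in self.calls.items():
            if level not in (0, 1, 2):
                raise ValueError(f"activity call for {gene} must be 0, 1 or 2")

    @classmethod
    def from_tsv(cls, path: str) -> "ActivityCalls":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                str(g): _CALL_NAMES[str(v).strip().lower()]
                for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])
            }
        )

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {
                "gene": list(self.calls),
                "activity": [_LEVEL_NAMES[v] for v in self.calls.values()],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FoldChangeTable:
    """Per-gene fold change (ratio > 0) and p-value per transition column.

    ``fold[gene][k]`` and ``pval[gene][k]`` for transition columns ``k``
    numbered from 1, matching the transition matrix.
    """

    fold: dict[str, dict[int, float]]
    pval: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for gene, cols in self.pval.items():
            for k, p in cols.items():
                if not (0 < p <= 1):
                    raise ValueError(f"p-value for {gene} transition {k} not in (0, 1]")
                if self.fold[gene][k] <= 0:
                    raise ValueError(f"fold change for {gene} transition {k} must be > 0")

    @property
    def transitions(self) -> list[int]:
        ks = sorted({k for cols in self.fold.values() for k in cols})
        return ks

    @classmethod
    def from_tsv(cls, path: str) -> "FoldChangeTable":
        # header: gene, fc1, p1, fc2, p2, ...
        df = pd.read_csv(path, sep="\t")
        ncols = len(df.columns) - 1
        if ncols % 2:
            raise ValueError("fold-change table needs paired fc_k/p_k columns")
        fold: dict[str, dict[int, float]] = {}
        pval: dict[str, dict[int, float]] = {}
        for _, row in df.iterrows():
            gene = str(row.iloc[0])
            fold[gene] = {k: float(row.iloc[2 * k - 1]) for k in range(1, ncols // 2 + 1)}
            pval[gene] = {k: float(row.iloc[2 * k]) for k in range(1, ncols // 2 + 1)}
        return cls(fold, pval)

    def to_tsv(self, path: str) -> None:
        ks = self.transitions
        records = []
        for gene in self.fold:
            rec: dict[str, object] = {"gene": gene}
            for k in ks:
                rec[f"fc{k}"] = self.fold[gene][k]
                rec[f"p{k}"] = self.pval[gene][k]
            records.append(rec)
        pd.DataFrame(records).to_csv(path, sep="\t", index=False)


@dataclass
class TransitionMatrix:
    """Which fold-change column compares which pair of conditions.

    ``entry[k] = (i, j)`` means column *k* of the fold-change table compares
    condition *i* to condition *j* (a fold above 1 means higher in *j*).
    Arbitrary transition graphs are allowed, not only linear sequences.
    """

    conditions: list[str]
    entries: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition names")
        ks = sorted(self.entries)
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("transition columns must be numbered 1..n, each used once")
        for k, (i, j) in self.entries.items():
            if i not in self.conditions or j not in self.conditions:
                raise ValueError(f"transition {k} references unknown condition")
            if i == j:
                raise ValueError(f"transition {k} compares {i} with itself")

    @classmethod
    def from_matrix(cls, conditions: Sequence[str], T: np.ndarray) -> "TransitionMatrix":
        """From the square integer map with T[i, j] = k (0 = no comparison)."""
        T = np.asarray(T, dtype=int)
        entries = {}
        for a in range(len(conditions)):
            for b in range(len(conditions)):
                if T[a, b]:
                    entries[int(T[a, b])] = (conditions[a], conditions[b])
        return cls(list(conditions), entries)

    @classmethod
    def from_tsv(cls, path: str) -> "TransitionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        conditions = [str(c) for c in df.columns]
        return cls.from_matrix(conditions, df.to_numpy())

    def to_tsv(self, path: str) -> None:
        n = len(self.conditions)
        idx = {c: i for i, c in enumerate(self.conditions)}
        T = np.zeros((n, n), dtype=int)
        for k, (i, j) in self.entries.items():
            T[idx[i], idx[j]] = k
        pd.DataFrame(T, index=self.conditions, columns=self.conditions).to_csv(
            path, sep="\t"
        )


@dataclass
class IntegrationResult:
    """Per-condition gene states, fluxes and achieved objective, plus the
    genes the algorithm adjusted (with their weights) and extras."""

    gene_states: dict[str, dict[str, int]]
    fluxes: dict[str, dict[str, float]]
    objective_values: dict[str, float]
    adjusted_genes: list[tuple[str, float]] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "objective_values": self.objective_values,
            "adjusted_genes": [[g, w] for g, w in self.adjusted_genes],
            "gene_states": self.gene_states,
            **{k: v for k, v in self.details.items() if _jsonable(v)},
        }


def _jsonable(v) -> bool:
    try:
        import json

        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------

def gimme(
    cm: CoupledModel,
    profile: ExpressionProfile,
    objective_fraction: float = 0.9,
    opts: SolverOptions | None = None,
) -> IntegrationResult:
    """Threshold-and-reactivate integration on a coupled model.

    Genes at or above the threshold are fixed on; genes missing from the
    table are treated as above threshold (and logged).  Below-threshold
    genes default off but can be reactivated at cost ``threshold - expr``;
    the MILP minimizes total reactivation cost subject to the flux
    objective reaching ``objective_fraction`` of the all-genes-on optimum.
    """
    import sys

    if not 0 < objective_fraction <= 1:
        raise ValueError("objective_fraction must be in (0, 1]")
    all_on = {col: 1 for col in cm.gene_vars.values()}
    optimum, _, _ = fba(cm, fix=all_on, opts=opts)  # raises if infeasible

    below: dict[str, float] = {}
    for gene in cm.model.genes:
        if gene not in profile.values:
            print(f"warning: no expression value for {gene}; treating as on", file=sys.stderr)
            continue
        if profile.values[gene] < profile.threshold:
            below[gene] = profile.threshold - profile.values[gene]

    p = cm.problem.copy()
    obj_coeffs = {
        cm.flux_vars[rxn]: float(cm.model.objective[j])
        for j, rxn in enumerate(cm.model.rxns)
        if cm.model.objective[j] != 0
    }
    p.add_constraint(
        LinearConstraint(
            obj_coeffs, ">", objective_fraction * optimum, "objective_floor"
        )
    )
    for gene, col in cm.gene_vars.items():
        if gene not in below:
            p.set_bounds(col, 1, 1)
    p.obj = {cm.gene_vars[g]: w - TIE_BREAK_WEIGHT for g, w in below.items()}
    res = solve(p, opts)
    if res.status == "infeasible":
        raise InfeasibleError("no reactivation meets the objective fraction")
    if not res.ok:
        raise RuntimeError(f"solver returned {res.status}")
    assert res.assignment is not None
    states = {g: int(res.assignment[col]) for g, col in cm.gene_vars.items()}
    fluxes = {rxn: res.assignment[col] for rxn, col in cm.flux_vars.items()}
    achieved = sum(c * res.assignment[v] for v, c in obj_coeffs.items())
    reactivated = [(g, below[g]) for g in sorted(below) if states[g] == 1]
    return IntegrationResult(
        gene_states={"1": states},
        fluxes={"1": fluxes},
        objective_values={"1": achieved},
        adjusted_genes=reactivated,
        details={
            "reactivation_cost": sum(w for _, w in reactivated),
            "below_threshold": sorted(below),
            "optimum": optimum,
        },
    )


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

def imat(
    model: MetabolicModel,
    calls: ActivityCalls,
    epsilon: float = 1e-3,
    objective_floor: float | None = None,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    opts: SolverOptions | None = None,
) -> IntegrationResult:
    """Three-level activity matching.

    Genes are free three-level variables; each GPR reaction's indicator is
    their min/max composition.  Indicator 2 forces |v| >= epsilon,
    indicator 0 forces |v| <= epsilon; the solver maximizes the number of
    genes at their called level (called genes only).  An optional floor on
    the flux objective is applied when given.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    cm = couple(model, mode=mode, gene_upper=2, couple_fluxes=False)
    for rxn in cm.indicator_vars:
        j = model.reaction_index(rxn)
        if epsilon > max(abs(model.vmin[j]), abs(model.vmax[j])):
            raise ValueError(
                f"epsilon {epsilon} exceeds the flux capacity of reaction {rxn}"
            )
    rc, p = cm.compiler, cm.problem
    for rxn, r_col in cm.indicator_vars.items():
        j = model.reaction_index(rxn)
        v = cm.flux_vars[rxn]
        vmin, vmax = float(model.vmin[j]), float(model.vmax[j])
        r_up = p.variable_bounds(r_col)[1]
        if r_up >= 2:
            hi = rc.encode_conditional(Conditional(Atom(r_col), ">=", Const(2)))
            if vmin < 0:  # reversible: direction binary picks the sign
                d = rc._aux_column(rc._fresh("dir"), 0, 1)
                M_f = epsilon - vmin
                p.add_constraint(
                    LinearConstraint(
                        {v: 1.0, hi: -M_f, d: -M_f}, ">", epsilon - 2 * M_f, f"hi_{rxn}_fwd"
                    )
                )
                M_b = vmax + epsilon
                p.add_constraint(
                    LinearConstraint(
                        {v: 1.0, hi: M_b, d: -M_b}, "<", -epsilon + M_b, f"hi_{rxn}_bwd"
                    )
                )
            else:
                p.add_constraint(
                    LinearConstraint(
                        {v: 1.0, hi: -(epsilon - vmin)}, ">", vmin, f"hi_{rxn}_fwd"
                    )
                )
        lo = rc.encode_conditional(Conditional(Atom(r_col), "<=", Const(0)))
        if vmax > epsilon:
            p.add_constraint(
                LinearConstraint(
                    {v: 1.0, lo: vmax - epsilon}, "<", vmax, f"lo_{rxn}_ub"
                )
            )
        if vmin < -epsilon:
            p.add_constraint(
                LinearConstraint(
                    {v: 1.0, lo: vmin + epsilon}, ">", vmin, f"lo_{rxn}_lb"
                )
            )
    match_cols: dict[str, str] = {}
    for gene, level in calls.calls.items():
        if gene not in cm.gene_vars:
            continue
        match_cols[gene] = rc.encode_conditional(
            Conditional(Atom(cm.gene_vars[gene]), "=", Const(level))
        )
    if objective_floor is not None:
        obj_coeffs = {
            cm.flux_vars[rxn]: float(model.objective[j])
            for j, rxn in enumerate(model.rxns)
            if model.objective[j] != 0
        }
        p.add_constraint(
            LinearConstraint(obj_coeffs, ">", float(objective_floor), "objective_floor")
        )
    p.obj = {col: -1.0 for col in match_cols.values()}
    for col in cm.gene_vars.values():
        p.obj[col] = p.obj.get(col, 0.0) - TIE_BREAK_WEIGHT
    res = solve(p, opts)
    if res.status == "infeasible":
        raise InfeasibleError("activity constraints admit no mass-balanced flux state")
    if not res.ok:
        raise RuntimeError(f"solver returned {res.status}")
    assert res.assignment is not None
    states = {g: int(res.assignment[col]) for g, col in cm.gene_vars.items()}
    fluxes = {rxn: res.assignment[col] for rxn, col in cm.flux_vars.items()}
    matched = [g for g, col in sorted(match_cols.items()) if res.assignment[col] > 0.5]
    mismatched = [(g, 1.0) for g in sorted(match_cols) if g not in matched]
    obj_value = float(
        sum(
            model.objective[j] * fluxes[rxn]
            for j, rxn in enumerate(model.rxns)
            if model.objective[j] != 0
        )
    )
    return IntegrationResult(
        gene_states={"1": states},
        fluxes={"1": fluxes},
        objective_values={"1": obj_value},
        adjusted_genes=mismatched,
        details={
            "matched_genes": matched,
            "n_matched": len(matched),
            "indicator_levels": {
                rxn: int(res.assignment[col]) for rxn, col in cm.indicator_vars.items()
            },
            "epsilon": epsilon,
        },
    )


# ---------------------------------------------------------------------------
# MADE
# ---------------------------------------------------------------------------

_WEIGHT_FNS = {
    "one_minus_p": lambda p: 1.0 - p,
    "neg_log10_p": lambda p: -math.log10(p),
}


def made(
    models: MetabolicModel | Sequence[MetabolicModel],
    fc: FoldChangeTable,
    T: TransitionMatrix,
    objective_fraction: float = 0.9,
    weight_fn: str = "one_minus_p",
    delta: float = 0.05,
    gene_upper: int = 1,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    opts: SolverOptions | None = None,
) -> IntegrationResult:
    """Multi-condition differential-expression matching.

    One MILP spans all conditions of the transition graph.  For transition
    ``i -> j`` a fold change above ``1 + delta`` desires a higher gene state
    in *j* than in *i*, below ``1 - delta`` a lower one, and within the band
    equality; each realized desire scores ``weight(p)``.  Every condition
    must reach ``objective_fraction`` of its own optimum.
    """
    import sys

    if weight_fn not in _WEIGHT_FNS:
        raise ValueError(f"unknown weight_fn {weight_fn!r}; use one of {sorted(_WEIGHT_FNS)}")
    weight = _WEIGHT_FNS[weight_fn]
    if isinstance(models, MetabolicModel):
        models = [models] * len(T.conditions)
    if len(models) != len(T.conditions):
        raise ValueError("need one model per condition")
    used = {c for pair in T.entries.values() for c in pair}
    for cond in T.conditions:
        if cond not in used:
            print(f"warning: condition {cond} has no transition data", file=sys.stderr)

    from .compiler import MilpProblem, RuleCompiler

    rc = RuleCompiler(problem=MilpProblem(), mode=mode)
    cms: dict[str, CoupledModel] = {}
    optima: dict[str, float] = {}
    obj_rows: dict[str, dict[str, float]] = {}
    for cond, m in zip(T.conditions, models):
        cms[cond] = couple(m, mode=mode, gene_upper=gene_upper, prefix=f"{cond}__", into=rc)
        optimum, _, _ = fba(couple(m, mode=mode, gene_upper=gene_upper), opts=opts)
        optima[cond] = optimum
        obj_rows[cond] = {
            cms[cond].flux_vars[rxn]: float(m.objective[j])
            for j, rxn in enumerate(m.rxns)
            if m.objective[j] != 0
        }
        rc.problem.add_constraint(
            LinearConstraint(
                obj_rows[cond], ">", objective_fraction * optimum, f"{cond}__objective_floor"
            )
        )

    desires: list[tuple[str, int, float, str]] = []  # (gene, k, weight, match column)
    for k, (i, j) in T.entries.items():
        for gene, cols in fc.fold.items():
            if k not in cols:
                continue
            if gene not in cms[i].gene_vars:
                continue
            f, pv = cols[k], fc.pval[gene][k]
            if f > 1 + delta:
                op = ">"
            elif f < 1 - delta:
                op = "<"
            else:
                op = "="
            m_col = rc.encode_conditional(
                Conditional(Atom(cms[j].gene_vars[gene]), op, Atom(cms[i].gene_vars[gene]))
            )
            desires.append((gene, k, weight(pv), m_col))

    p = rc.problem
    p.obj = {}
    for _, _, w, col in desires:
        p.obj[col] = p.obj.get(col, 0.0) - w
    for cond in T.conditions:
        for col in cms[cond].gene_vars.values():
            p.obj[col] = p.obj.get(col, 0.0) - TIE_BREAK_WEIGHT
    res = solve(p, opts)
    if res.status == "infeasible":
        raise InfeasibleError("no joint gene state meets every condition's objective")
    if not res.ok:
        raise RuntimeError(f"solver returned {res.status}")
    assert res.assignment is not None
    gene_states = {
        cond: {g: int(res.assignment[col]) for g, col in cms[cond].gene_vars.items()}
        for cond in T.conditions
    }
    fluxes = {
        cond: {rxn: res.assignment[col] for rxn, col in cms[cond].flux_vars.items()}
        for cond in T.conditions
    }
    objective_values = {
        cond: float(sum(c * res.assignment[v] for v, c in obj_rows[cond].items()))
        for cond in T.conditions
    }
    matched_weight = 0.0
    realized: list[tuple[str, float]] = []
    for gene, k, w, col in desires:
        if res.assignment[col] > 0.5:
            matched_weight += w
            realized.append((f"{gene}@{k}", w))
    return IntegrationResult(
        gene_states=gene_states,
        fluxes=fluxes,
        objective_values=objective_values,
        adjusted_genes=realized,
        details={
            "matched_weight": matched_weight,
            "total_weight": sum(w for _, _, w, _ in desires),
            "optima": optima,
            "weight_fn": weight_fn,
            "delta": delta,
        },
    )
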