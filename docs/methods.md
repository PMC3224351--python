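# Methods

## The modelling problem

Constraint-based (COBRA) models predict metabolic capability from a
stoichiometric matrix *S*, flux bounds, and a linear objective, via flux
balance analysis (FBA): maximize `c·v` subject to `S v = 0` and
`vmin ≤ v ≤ vmax`.  The genetic layer — which enzymes exist, hence which
reactions may carry flux — is written as Boolean gene-protein-reaction (GPR)
rules (complex subunits joined by `and`, isozymes by `or`), and
transcriptional regulation as further rules over genes, proteins and
environmental cues.  `fluxlogic` compiles all of this logic into
mixed-integer linear constraints attached to the flux program, so the
regulatory and metabolic problems are solved **simultaneously**: any gene
state a solver returns is, by construction, consistent with every rule (a
stable state), in contrast to the classical iterate-until-stable approach
whose iteration count is unpredictable and which can oscillate.

## Rule language and reference semantics

A rule is `antecedent => consequent` (implication) or `antecedent <=>
consequent` (biconditional).  Expressions combine named variables with
`and`/`or`/`not` and *conditionals* comparing a variable with a constant or
another variable (`glc_ex > 10`, `t = 2`).  Variables are bounded integers;
binary bounds `[0, 1]` recover classical logic, wider bounds give
multilevel logic with

* `x and y = min(x, y)` — the scarcer promoter subunit limits output;
* `x or y  = max(x, y)` — the stronger independent activator wins;
* `not x`  — either *pseudo-binary* (1 exactly when `x = 0`: any nonzero
  level counts as "true") or *inversion* (`upper(x) − x`: the distance from
  full activation).  The mode is a per-model choice, selected by which
  biology is being approximated.

Truth of an expression is "value > 0".  A `<=>` rule requires equal values
on both sides; a `=>` rule requires `value(consequent) ≥ value(antecedent)`,
which reduces to material implication on binary variables and is the
natural monotone extension for multilevel sides (the literature defines
multilevel rules only with conditional antecedents such as `t = 2 => g`,
which are binary-valued; the `≥` form is this package's choice and is
flagged here as such).

The normative semantics is `evaluate_rule`/`enumerate_feasible_states` in
`rules.py`: plain exhaustive evaluation, used as the oracle for everything
else.

Grammar notes: operators `and`/`&`, `or`/`|`, `not`/`~`, `=>`, `<=>`,
comparisons `> >= < <= = ~=` (`!=`/`==` accepted as aliases); identifiers
are case-sensitive (`MIG1` the protein and `mig1` the gene are distinct),
may contain `_`, `[`, `]`, `.`, and can be single-quoted to admit names
like `'EX_o2(e)'`; `%` starts a comment.  Rule files may carry
`declare x in [lo, hi]` and `mode inversion|pseudo_binary` header lines.

## Compilation to mixed-integer constraints

Compilation reduces every rule to *simple rules* — `x (=>|<=>) z`,
`x and y (=>|<=>) z`, `x or y (=>|<=>) z`, `x <op> y (=>|<=>) z` with
atomic operands — by substituting an *indicator variable* for each compound
sub-expression (`x or (not y)) and z => w` becomes `x or not y <=> I` plus
`I and z => w`).  An indicator's bounds follow the min/max law: upper
`max(x̄, ȳ)` for `or`, `min(x̄, ȳ)` for `and`, so all-binary inputs give
binary indicators.  Syntactically identical sub-expressions share one
indicator (hash-consing), and each variable gets at most one negation
companion column regardless of how often its negation appears.

Design choices worth knowing:

* **Negation is compiled through companion columns, not DeMorgan
  rewriting.**  DeMorgan's laws preserve truth but not the multilevel
  *value* of a pseudo-binary negation (`not not x` is 0/1, never `x`), and
  under inversion they fail for unequal operand bounds.  A companion column
  `n` is tied to `x` by `x + n = x̄` (inversion) or by the pair
  `x + x̄·n ≤ x̄`, `x + n ≥ 1` (pseudo-binary, levels ≥ 0), which matches
  the evaluator exactly in both modes.  `to_negation_normal_form` is still
  provided as a standalone truth-preserving transformation.
* **Linearization.**  `or`-lower bounds need no auxiliary variable
  (`z ≥ a`, `z ≥ b`); `and`-lower bounds and `or`-upper bounds each use one
  binary selector with big-M constants taken from the operand bounds.
  `<=>` emits both directions, `=>` only the forcing direction.  The
  contract is *projection equivalence*: the integer points satisfying the
  emitted rows, projected onto the original variables, equal the
  enumeration oracle exactly.  This is tested on 200 random multilevel
  systems in both negation modes by enumerating the full integer grid of
  the compiled problem (no solver in the loop).
* **Conditionals** become a binary indicator `g` with two big-M rows
  (`g = 1` forces the comparison, `g = 0` forces its negation) whose
  constants derive from the operand bounds — never hard-coded.  Strict
  inequalities on continuous (flux) operands use a tolerance
  `strict_tol = 1e-6`; on integer operands the gap is exactly 1.  Equality
  (`=`) composes two one-sided indicators with an `and`; `!=` is its
  companion.  Conditionals on fluxes require finite flux bounds.
* **Logical variables must have lower bound 0.**  The pseudo-binary
  companion encoding relies on levels being nonnegative; a nonzero lower
  bound raises an error at compile time rather than mis-encoding.

The assembled problem is the conventional MILP record — objective vector,
sparse `A`, senses, right-hand side, variable bounds and types
(`c`/`b`/`i`), row and column names — with variables shared by name, so new
rules append columns and rows without recompiling old ones.  LP- and
MPS-format writers emit rows and columns in insertion order.

### Solving

`solve` is backend-agnostic and minimizes by convention.  Backends: HiGHS
through `scipy.optimize.milp` (default) and GLPK through `swiglpk`.  Both
are deterministic on these problem sizes; `SolverOptions.seed` exists for
interface stability but neither backend consumes it.  Integer variables are
rounded to the nearest level after solving, guarded by the feasibility
tolerance (default `1e-6`); a fractional residue beyond the guard is an
error, not silently rounded.

## Coupling logic to flux

Each reaction *i* with a GPR gets a binary participation indicator `R_i`
defined by `GPR_i <=> R_i` and the coupling rows

    vmin_i · R_i  ≤  v_i  ≤  vmax_i · R_i

so an unsatisfied GPR forces zero flux and `R_i = 1` restores the original
bounds.  `R_i` stays binary even when genes are multilevel — with `R_i > 1`
the coupling would relax fluxes beyond their bounds — except in the
activity-matching integration below, where indicators are multilevel and
the coupling rows are replaced by activity constraints.  Exchange fluxes
follow the convention negative = uptake, so an oxygen-availability rule
reads `high_o2 <=> EX_o2 < -0.244`.

## Synchronous iteration

`simulate_iterative` implements the classical iterate-to-stability scheme
for explicit (`<=>`, atomic-consequent) rule sets: every defined variable
is recomputed *synchronously* from the full previous state; environment
variables stay fixed; termination is a fixed point, a detected cycle (with
its length), or the iteration cap.  The oxygen-regulation case study
reproduces the reference trajectory from iteration 2 onward; its published
iteration-1 value implies some staged update order (regulators before
targets) that is not specified anywhere we could follow, so this package
deliberately implements the plain synchronous convention and reads results
from iteration 3 onward, where the trajectories coincide.

## Infeasibility diagnosis

Large regulatory networks routinely make a metabolic model unable to reach
its objective.  `find_infeasible_rules` adds one binary relaxation switch
per regulatory rule; switching it on disables every constraint row that
rule generated, with per-row big-M slack computed from variable bounds.
Minimizing the number of active switches subject to
`objective ≥ objective_floor` yields a minimum-cardinality set of rules
whose deactivation restores the phenotype (all rules weighted equally).
The default floor is `1e-3` of the objective's bound-propagation upper
limit — "cannot produce any biomass" is the symptom being diagnosed.  The
result is cross-checked in the tests against exhaustive subset enumeration.

## Expression integration

All three algorithms are gene-centric: they operate on gene variables
through the compiled GPR, not on per-reaction expression averages, and all
report explicit per-gene states that are rule-feasible and meet their flux
constraint.

**GIMME** (threshold-and-reactivate).  Genes at or above the expression
threshold are fixed on; genes below default off but may be reactivated at
cost `threshold − expression`; the MILP minimizes total cost subject to
`objective ≥ objective_fraction × optimum(all genes on)`.
`objective_fraction` defaults to 0.9 — the source method requires only "a
minimum objective flux", and 0.9 is the conventional choice.  Genes absent
from the table are treated as above threshold (unpenalized, logged):
missing data should not switch genes off.

**iMAT** (activity matching).  Genes take levels 0/1/2 (low/medium/high);
the GPR's min/max composition gives each reaction an indicator on the same
scale; level 2 forces `|v| ≥ ε`, level 0 forces `|v| ≤ ε`
(`ε = 1e-3` flux units by default, validated against every constrained
reaction's capacity at entry).  Reversible reactions get one direction
binary so the `|v| ≥ ε` disjunction is exact.  The objective maximizes the
number of *called* genes whose solved level equals their call; an optional
flux-objective floor applies when the organism has one.

**MADE** (differential expression across conditions).  Conditions form an
arbitrary transition graph encoded by a transition matrix; each fold-change
column belongs to one edge `i → j`.  Fold above `1 + δ` desires a higher
state in *j*, below `1 − δ` lower, within the band equality (`δ = 0.05`;
exact-1 comparisons are fragile on real data).  One MILP spans all
conditions; each must reach `objective_fraction` of its own optimum; the
objective maximizes `Σ weight(p) ·[desire realized]` with
`weight(p) = 1 − p` by default (`−log10 p` selectable) — the source method
prioritizes by significance without fixing a formula.  Genes are binary by
default; multilevel states are accepted via `gene_upper`, but note the
flux coupling stays binary-style only in the default configuration.

**Tie-breaking.**  Alternate optima are resolved by a secondary objective
preferring more genes on, at weight `1e-4` per gene level — small enough
never to override a primary-objective difference on these data, and large
enough to make outputs reproducible across solver backends.

## Fixtures

The worked-example network is reconstructed from its published description
rather than from printed stoichiometry: imports of A, C, F; `R4: A → B`
(g4); `R5/R6: C → D` (complex g5a∧g5b, or g6); `R7: B + D → E` (complex
g7a∧g7b) as the only producer of the objective metabolite E; `R8: F → G`
(isozymes g8a∨g8b) with G exported.  R7 consuming both B and D is what
makes the documented dependencies structural.  All fluxes are irreversible
with capacity 10 — an arbitrary positive capacity; every result depends
only on topology and logic.  The regulatory fixtures use one variable per
gene/protein pair (`hap1`, not `HAP1`+`hap1`) so that iteration closes; the
general language remains case-sensitive.

## What the tests do and do not show

The oracle-equivalence suite covers rule systems up to 5 variables with
levels up to 3 and nesting depth ≤ 2 — sizes where the full integer grid of
the compiled problem stays enumerable; the encodings contain nothing
size-dependent, but genome-scale behaviour (solver time, numerical
conditioning at thousands of rows) is not exercised here.  The expression
algorithms are validated against brute-force optima on the 8-gene fixture;
on real models their solutions are only as identifiable as the data make
them (alternate optima are resolved by the documented tie-break, not by
biology).  Iterative simulation assumes synchronous updates; biological
update order is unknown in general.  MIQP, solver warm-starts,
flux-variability analysis and thermodynamic loop removal are out of scope.
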