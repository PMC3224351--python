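# fluxlogic

Compile Boolean and multilevel regulatory logic into mixed-integer linear
programs coupled to genome-scale metabolic flux models.

Constraint-based metabolic models answer "what can this organism's
metabolism do?" with a linear program (flux balance analysis, FBA:
maximize `c·v` s.t. `S v = 0`, `vmin ≤ v ≤ vmax`).  The genetic layer —
gene-protein-reaction (GPR) rules such as `g5a and g5b` for an enzyme
complex or `g8a or g8b` for isozymes, and transcriptional-regulatory rules
such as `O2 or (not rox1) <=> hap1` — is logic, not algebra.  `fluxlogic`
turns arbitrary rules over bounded integer variables into linear integer
constraints and fuses them with the flux model, so regulation and
metabolism are solved as **one** optimization: every returned gene state is
automatically consistent with every rule.

For systems and computational biologists who want to:

* attach GPRs and regulatory networks (explicit `<=>` or implicit `=>`
  rules, negation, multilevel variables with `and` = min / `or` = max,
  flux conditionals like `high_o2 <=> EX_o2 < -0.244`) to a COBRA-style
  model and run FBA over genes rather than reactions;
* integrate expression data gene-centrically with GIMME
  (threshold-and-reactivate, reactivation weighted by distance below
  threshold), iMAT (three-level activity calls with `|v| ≥ ε` / `|v| ≤ ε`
  forcing), and MADE (multi-condition differential expression weighted by
  statistical significance over an arbitrary transition graph);
* find the minimal set of regulatory rules that makes a model unable to
  grow (`find_infeasible_rules`, a minimum-relaxation MILP);
* iterate explicit rule sets synchronously to fixed points or cycles, the
  classical alternative the simultaneous solve replaces.

Each reaction *i* with a GPR gets a binary indicator `R_i` defined by
`GPR_i <=> R_i` and coupled by `vmin_i·R_i ≤ v_i ≤ vmax_i·R_i`.  Logic is
reduced to simple patterns (`x and y => z`, …) by substituting shared
indicator variables for compound sub-expressions (an `or` indicator is
bounded by `max(x̄, ȳ)`, an `and` by `min(x̄, ȳ)`), then linearized with
bound-derived big-M constants.  The compiled MILP's feasible integer
points, projected onto the original variables, provably equal exhaustive
enumeration of the rules — this is the package's central tested contract.
Solvers: HiGHS (via scipy) by default, GLPK (via swiglpk) as an
alternative, behind one solver-agnostic interface with LP/MPS export.

## Worked example

The built-in fixture network has 10 reactions, 7 metabolites and 8 genes;
production of metabolite E (reaction `R9`) is the objective, and reaction
`R7: B + D -> E` needs the complex `g7a and g7b`.

```sh
$ fluxlogic fixtures --outdir fx
$ fluxlogic gimme --model fx/prototypic_network.mod \
                  --expr fx/table3_expression.tsv --threshold 10
gene    state
g4      1
g5a     1
g5b     1
g6      0
g7a     1
g7b     1
g8a     0
g8b     0
```

Plain thresholding at 10 would switch off `g5a, g6, g7b, g8a, g8b` and
kill all E production.  GIMME reactivates exactly `g5a` and `g7b` (each 4
expression units below threshold, total cost 8): `g7b` because both
subunits of the only E-producing enzyme are required, and `g5a` rather
than `g6` because its expression is closer to the threshold (4 < 8).  The
resulting model still reaches 9.0 of the unconstrained optimum 10.

The same library calls in Python:

```python
import fluxlogic as fl

model = fl.fixtures.build_prototypic_network()
coupled = fl.couple(model)                      # GPRs -> MILP + flux coupling
result = fl.gimme(coupled, fl.fixtures.table3_expression())
print(result.adjusted_genes)                    # [('g5a', 4), ('g7b', 4)]

objective, fluxes, genes = fl.fba(coupled, fix={"g7a": 0})
print(objective)                                # 0.0  (knockout kills E production)
```

Other subcommands: `enumerate` (feasible states of a rule file — the
explicit glucose-sensing rules admit 4 of 16 states, the implicit form 7),
`simulate` (synchronous iteration; the oxygen-regulation case study turns
`erg11` off from iteration 3 with the original rules, keeps it on with the
refined `high_o2` rule), `imat`, `made`, `diagnose`, `fba`, `convert`.

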