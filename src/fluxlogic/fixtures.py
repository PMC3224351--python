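"""Built-in worked-example fixtures.

* ``prototypic_network`` — a 10-reaction, 7-metabolite, 8-gene toy model:
  A, C and F are imported; E export (reaction 9) is the objective.  B comes
  from A (reaction 4, gene g4); D comes from C by reaction 5 (complex
  g5a and g5b) or reaction 6 (g6); reaction 7 condenses B + D -> E through
  the two-subunit complex g7a and g7b; F -> G (reaction 8) is catalyzed by
  either isozyme g8a or g8b, with G exported by reaction 10.  All fluxes
  are irreversible with capacity 10, so results depend only on topology
  and logic.

* ``mig1_system_explicit`` / ``mig1_system_implicit`` — the yeast
  glucose-sensing subnetwork around mig1/mth1/rgt1 and extracellular
  glutamine, written as explicit biconditionals or as one-directional
  implications.  The two formulations admit different feasible state sets.

* ``erg11_original`` / ``erg11_refined`` — oxygen-dependent regulation of
  hap1, rox1 and erg11 on glucose.  The original rule set turns erg11 off
  at the fixed point; the refined set restricts rox1 repression to
  low-oxygen conditions via a ``high_o2`` flux indicator and keeps erg11
  on.  One variable stands for each gene/protein pair so the update loop
  closes.

* ``table3_expression`` / ``table4_calls`` / ``table5_foldchanges`` — the
  expression datasets for the GIMME, iMAT and MADE worked examples on the
  prototypic network.

Each builder is deterministic and self-contained.
"""

from __future__ import annotations

import numpy as np

from .expression import (
    ActivityCalls,
    ExpressionProfile,
    FoldChangeTable,
    TransitionMatrix,
)
from .model import MetabolicModel

__all__ = [
    "build_prototypic_network",
    "mig1_explicit_rules",
    "mig1_implicit_rules",
    "erg11_original_rules",
    "erg11_refined_rules",
    "erg11_start_state",
    "erg11_environment",
    "table3_expression",
    "table4_calls",
    "table5_foldchanges",
    "table5_transitions",
    "FIXTURES",
]

PROTO_GENES = ["g4", "g5a", "g5b", "g6", "g7a", "g7b", "g8a", "g8b"]


def build_prototypic_network() -> MetabolicModel:
    """The 10-reaction expression-integration toy model (objective: R9)."""
    mets = ["A", "B", "C", "D", "E", "F", "G"]
    reactions = [
        ("R1", {"A": 1}, ""),
        ("R2", {"C": 1}, ""),
        ("R3", {"F": 1}, ""),
        ("R4", {"A": -1, "B": 1}, "g4"),
        ("R5", {"C": -1, "D": 1}, "g5a and g5b"),
        ("R6", {"C": -1, "D": 1}, "g6"),
        ("R7", {"B": -1, "D": -1, "E": 1}, "g7a and g7b"),
        ("R8", {"F": -1, "G": 1}, "g8a or g8b"),
        ("R9", {"E": -1}, ""),
        ("R10", {"G": -1}, ""),
    ]
    rxns = [name for name, _, _ in reactions]
    S = np.zeros((len(mets), len(rxns)))
    for j, (_, stoich, _) in enumerate(reactions):
        for met, coef in stoich.items():
            S[mets.index(met), j] = coef
    vmin = np.zeros(len(rxns))
    vmax = np.full(len(rxns), 10.0)
    objective = np.zeros(len(rxns))
    objective[rxns.index("R9")] = 1.0
    gpr = [g for _, _, g in reactions]
    return MetabolicModel(mets, rxns, S, vmin, vmax, objective, list(PROTO_GENES), gpr)


# -- regulatory rule fixtures ------------------------------------------------

def mig1_explicit_rules() -> list[str]:
    """Explicit (biconditional) form of the glucose-sensing subnetwork."""
    return [
        "not mig1 <=> mth1",
        "mth1 and (not gln_L) <=> rgt1",
    ]


def mig1_implicit_rules() -> list[str]:
    """Implicit (one-directional) form of the same interactions."""
    return [
        "mig1 => not mth1",
        "mth1 => rgt1",
        "gln_L => not rgt1",
    ]


def erg11_original_rules() -> list[str]:
    """Oxygen/heme regulation of erg11 with unconditional rox1 repression."""
    return [
        "O2 or (not rox1) <=> hap1",
        "O2 and hap1 <=> rox1",
        "glc and hap1 and (not rox1) <=> erg11",
    ]


def erg11_refined_rules() -> list[str]:
    """Refined form: rox1 represses erg11 only when oxygen uptake is low
    (the ``high_o2`` indicator disables the repression)."""
    return [
        "O2 or (not rox1) <=> hap1",
        "O2 and hap1 <=> rox1",
        "glc and hap1 and (high_o2 or not rox1) <=> erg11",
    ]


def erg11_start_state() -> dict[str, int]:
    return {"hap1": 0, "rox1": 0, "erg11": 1}


def erg11_environment(refined: bool = False) -> dict[str, int]:
    env = {"O2": 1, "glc": 1}
    if refined:
        env["high_o2"] = 1  # aerobic: oxygen uptake above 10% of maximum
    return env


# -- expression data fixtures ------------------------------------------------

def table3_expression() -> ExpressionProfile:
    """Expression values for the threshold-and-reactivate example
    (threshold 10)."""
    return ExpressionProfile(
        values={
            "g4": 13,
            "g5a": 6,
            "g5b": 12,
            "g6": 2,
            "g7a": 18,
            "g7b": 6,
            "g8a": 2,
            "g8b": 4,
        },
        threshold=10,
    )


def table4_calls() -> ActivityCalls:
    """Three-level activity calls for the activity-matching example."""
    return ActivityCalls(
        calls={
            "g4": 1,
            "g5a": 0,
            "g5b": 0,
            "g6": 2,
            "g7a": 2,
            "g7b": 2,
            "g8a": 1,
            "g8b": 2,
        }
    )


def table5_foldchanges() -> FoldChangeTable:
    """Fold changes and p-values across the three-condition cycle
    (columns: 1->2, 2->3, 3->1)."""
    data = {
        "g4": [(2.1, 0.68), (3.0, 0.08), (0.7, 0.15)],
        "g5a": [(0.5, 0.45), (8.0, 0.44), (0.8, 0.22)],
        "g5b": [(1.1, 0.07), (0.1, 0.49), (2.2, 0.03)],
        "g6": [(3.6, 0.05), (1.6, 0.22), (0.4, 0.48)],
        "g7a": [(1.4, 0.38), (4.2, 0.40), (1.8, 0.43)],
        "g7b": [(2.3, 0.04), (0.4, 0.19), (0.3, 0.12)],
        "g8a": [(1.3, 0.40), (7.3, 0.21), (0.2, 0.45)],
        "g8b": [(0.9, 0.89), (4.1, 0.83), (0.1, 0.28)],
    }
    fold = {g: {k + 1: fc for k, (fc, _) in enumerate(rows)} for g, rows in data.items()}
    pval = {g: {k + 1: p for k, (_, p) in enumerate(rows)} for g, rows in data.items()}
    return FoldChangeTable(fold, pval)


def table5_transitions() -> TransitionMatrix:
    """Transition matrix for the cyclic comparison 1->2, 2->3, 3->1."""
    return TransitionMatrix(
        conditions=["1", "2", "3"],
        entries={1: ("1", "2"), 2: ("2", "3"), 3: ("3", "1")},
    )


FIXTURES = {
    "prototypic_network": build_prototypic_network,
    "mig1_system_explicit": mig1_explicit_rules,
    "mig1_system_implicit": mig1_implicit_rules,
    "erg11_original": erg11_original_rules,
    "erg11_refined": erg11_refined_rules,
    "table3_expression": table3_expression,
    "table4_calls": table4_calls,
    "table5_foldchanges": table5_foldchanges,
}
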