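"""Rule language for regulatory and gene-protein-reaction (GPR) logic.

A *rule* joins two logical expressions with an implication operator:
``antecedent => consequent`` (if) or ``antecedent <=> consequent`` (if and
only if).  Expressions are built from variables, ``and``/``or``/``not``
operators, and *conditionals* that compare a variable against a constant or
another variable (e.g. ``glc_ex > 10 => g``).

Variables are bounded integers.  Binary variables (bounds ``[0, 1]``) give
classical Boolean logic; wider bounds give multilevel logic where ``and`` is
a minimum, ``or`` is a maximum, and ``not`` is either *pseudo-binary*
(nonzero means true, so ``not x`` is 1 exactly when ``x`` is 0) or
*inversion* (``not x = upper(x) - x``).

This module defines the AST types, a recursive-descent parser for the rule
grammar, an evaluator implementing the reference semantics, and exhaustive
enumeration of feasible states.  The enumeration is the correctness oracle
against which the MILP compiler is validated.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NotMode",
    "Variable",
    "Atom",
    "Const",
    "Not",
    "Junction",
    "Conditional",
    "Expression",
    "Rule",
    "RuleSyntaxError",
    "parse_rule",
    "parse_expression",
    "serialize",
    "evaluate_expression",
    "evaluate_rule",
    "enumerate_feasible_states",
    "expression_upper_bound",
    "collect_variables",
    "read_rule_file",
    "parse_rule_lines",
]


class NotMode(str, Enum):
    """Interpretation of ``not`` on multilevel variables."""

    PSEUDO_BINARY = "pseudo_binary"
    INVERSION = "inversion"


VariableKind = str  # gene | protein | reaction_indicator | environment | flux | synthetic_indicator


@dataclass(frozen=True)
class Variable:
    """A named, bounded integer (or continuous flux) quantity."""

    name: str
    lower: int = 0
    upper: int = 1
    kind: VariableKind = "gene"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"variable {self.name}: lower {self.lower} > upper {self.upper}")
        if self.kind != "flux" and self.upper < 1:
            raise ValueError(f"logical variable {self.name} needs upper >= 1")

    @property
    def levels(self) -> range:
        return range(int(self.lower), int(self.upper) + 1)

    @property
    def is_binary(self) -> bool:
        return self.lower == 0 and self.upper == 1


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str


@dataclass(frozen=True)
class Const:
    value: float


@dataclass(frozen=True)
class Not:
    operand: "Expression"


@dataclass(frozen=True)
class Junction:
    op: str  # "and" | "or"
    left: "Expression"
    right: "Expression"


#: comparison operator -> its negation (used when ``not`` hits a conditional)
_CMP_NEG = {"<": ">=", "<=": ">", ">": "<=", ">=": "<", "=": "!=", "!=": "="}


@dataclass(frozen=True)
class Conditional:
    """Comparison between two atomic operands (variable or constant)."""

    left: "Atom | Const"
    op: str  # one of < <= > >= = !=
    right: "Atom | Const"


Expression = Atom | Const | Not | Junction | Conditional


@dataclass(frozen=True)
class Rule:
    antecedent: Expression
    consequent: Expression
    connective: str  # "=>" | "<=>"
    source_text: str = ""
    id: int = -1

    @property
    def is_iff(self) -> bool:
        return self.connective == "<=>"


# ---------------------------------------------------------------------------
# Tokenizer / parser
# ---------------------------------------------------------------------------

class RuleSyntaxError(ValueError):
    """Malformed rule text; carries 1-based line and column."""

    def __init__(self, message: str, line: int = 1, column: int = 0) -> None:
        super().__init__(f"{message} (line {line}, column {column + 1})")
        self.line = line
        self.column = column


_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<COMMENT>%[^\n]*)
  | (?P<IFF><=>)
  | (?P<IMP>=>)
  | (?P<CMP><=|>=|~=|!=|==|<|>|=)
  | (?P<NUMBER>-?\d+(\.\d*)?([eE][-+]?\d+)?)
  | (?P<QNAME>'[^']+')
  | (?P<NAME>[A-Za-z_][A-Za-z0-9_\[\]\.]*)
  | (?P<AMP>&)
  | (?P<PIPE>\|)
  | (?P<TILDE>~)
  | (?P<LPAREN>\()
  | (?P<RPAREN>\))
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT"}


@dataclass
class _Token:
    kind: str
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, line_start = 1, 0
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleSyntaxError(
                f"unexpected character {text[pos]!r}", line, pos - line_start
            )
        kind = m.lastgroup or ""
        tok_text = m.group()
        col = pos - line_start
        pos = m.end()
        if kind == "WS":
            for i, ch in enumerate(tok_text):
                if ch == "\n":
                    line += 1
                    line_start = m.start() + i + 1
            continue
        if kind == "COMMENT":
            continue
        if kind == "NAME" and tok_text.lower() in _KEYWORDS:
            kind = _KEYWORDS[tok_text.lower()]
        elif kind == "QNAME":
            kind, tok_text = "NAME", tok_text[1:-1]
        elif kind == "AMP":
            kind = "AND"
        elif kind == "PIPE":
            kind = "OR"
        elif kind == "TILDE":
            kind = "NOT"
        elif kind == "CMP":
            tok_text = {"~=": "!=", "==": "="}.get(tok_text, tok_text)
        tokens.append(_Token(kind, tok_text, line, col))
    return tokens


class _Parser:
    """Recursive-descent parser.

    Precedence (tightest first): ``not`` > ``and`` > ``or`` > comparison >
    implication.  Parentheses override.  Comparison operands must be atomic
    (a variable or a numeric constant).
    """

    def __init__(self, tokens: list[_Token], source: str) -> None:
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def _peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> _Token:
        tok = self._peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else _Token("", "", 1, 0)
            raise RuleSyntaxError("unexpected end of input", last.line, last.column)
        self.pos += 1
        return tok

    def _expect(self, kind: str) -> _Token:
        tok = self._next()
        if tok.kind != kind:
            raise RuleSyntaxError(f"expected {kind}, got {tok.text!r}", tok.line, tok.column)
        return tok

    def parse_rule(self) -> Rule:
        antecedent = self.parse_expr()
        tok = self._peek()
        if tok is None or tok.kind not in ("IMP", "IFF"):
            where = tok or (self.tokens[-1] if self.tokens else _Token("", "", 1, 0))
            raise RuleSyntaxError(
                "a rule needs an implication operator (=> or <=>)", where.line, where.column
            )
        conn = self._next()
        consequent = self.parse_expr()
        trailing = self._peek()
        if trailing is not None:
            if trailing.kind in ("IMP", "IFF"):
                raise RuleSyntaxError(
                    "only one implication operator allowed at top level",
                    trailing.line,
                    trailing.column,
                )
            raise RuleSyntaxError(
                f"unexpected trailing token {trailing.text!r}", trailing.line, trailing.column
            )
        connective = "<=>" if conn.kind == "IFF" else "=>"
        return Rule(antecedent, consequent, connective, source_text=self.source)

    def parse_expr(self) -> Expression:
        left = self._parse_or()
        tok = self._peek()
        if tok is not None and tok.kind == "CMP":
            op = self._next().text
            right = self._parse_or()
            for side, t in ((left, tok), (right, tok)):
                if not isinstance(side, (Atom, Const)):
                    raise RuleSyntaxError(
                        "comparison operands must be a variable or a constant",
                        t.line,
                        t.column,
                    )
            return Conditional(left, op, right)
        return left

    def _parse_or(self) -> Expression:
        expr = self._parse_and()
        while (tok := self._peek()) is not None and tok.kind == "OR":
            self._next()
            expr = Junction("or", expr, self._parse_and())
        return expr

    def _parse_and(self) -> Expression:
        expr = self._parse_not()
        while (tok := self._peek()) is not None and tok.kind == "AND":
            self._next()
            expr = Junction("and", expr, self._parse_not())
        return expr

    def _parse_not(self) -> Expression:
        tok = self._peek()
        if tok is not None and tok.kind == "NOT":
            self._next()
            return Not(self._parse_not())
        return self._parse_primary()

    def _parse_primary(self) -> Expression:
        tok = self._next()
        if tok.kind == "NAME":
            return Atom(tok.text)
        if tok.kind == "NUMBER":
            return Const(float(tok.text))
        if tok.kind == "LPAREN":
            expr = self.parse_expr()
            self._expect("RPAREN")
            return expr
        raise RuleSyntaxError(f"unexpected token {tok.text!r}", tok.line, tok.column)


def parse_rule(text: str, rule_id: int = -1) -> Rule:
    """Parse a single rule like ``"not MIG1 <=> mth1"``.

    Raises :class:`RuleSyntaxError` (with line/column) on malformed input,
    including missing or doubled implication operators.
    """
    stripped = text.strip()
    tokens = _tokenize(text)
    if not tokens:
        raise RuleSyntaxError("empty rule", 1, 0)
    rule = _Parser(tokens, stripped).parse_rule()
    return replace(rule, id=rule_id)


def parse_expression(text: str) -> Expression:
    """Parse an expression with no top-level implication (e.g. a GPR string)."""
    tokens = _tokenize(text)
    if not tokens:
        raise RuleSyntaxError("empty expression", 1, 0)
    parser = _Parser(tokens, text.strip())
    expr = parser.parse_expr()
    trailing = parser._peek()
    if trailing is not None:
        raise RuleSyntaxError(
            f"unexpected trailing token {trailing.text!r}", trailing.line, trailing.column
        )
    return expr


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PLAIN_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_\[\]\.]*$")


def _quote(name: str) -> str:
    if _PLAIN_NAME_RE.match(name) and name.lower() not in _KEYWORDS:
        return name
    return f"'{name}'"


def _fmt_const(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def serialize(node: Expression | Rule) -> str:
    """Render an AST back to rule text; ``parse(serialize(x))`` equals ``x``."""
    if isinstance(node, Rule):
        return f"{serialize(node.antecedent)} {node.connective} {serialize(node.consequent)}"
    if isinstance(node, Atom):
        return _quote(node.name)
    if isinstance(node, Const):
        return _fmt_const(node.value)
    if isinstance(node, Not):
        inner = serialize(node.operand)
        if isinstance(node.operand, (Junction, Conditional)):
            inner = f"({inner})"
        return f"not {inner}"
    if isinstance(node, Conditional):
        return f"{serialize(node.left)} {node.op} {serialize(node.right)}"
    if isinstance(node, Junction):
        parts = []
        for child, is_left in ((node.left, True), (node.right, False)):
            text = serialize(child)
            # parenthesize junction/conditional children, except a same-op
            # left child (the parser folds chains left-associatively)
            if isinstance(child, Conditional) or (
                isinstance(child, Junction)
                and not (is_left and child.op == node.op)
            ):
                text = f"({text})"
            parts.append(text)
        return f" {node.op} ".join(parts)
    raise TypeError(f"cannot serialize {node!r}")


# ---------------------------------------------------------------------------
# Reference semantics
# ---------------------------------------------------------------------------

Assignment = Mapping[str, float]


def _cmp(left: float, op: str, right: float) -> bool:
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    if op == "=":
        return left == right
    if op == "!=":
        return left != right
    raise ValueError(f"unknown comparison operator {op!r}")


def expression_upper_bound(expr: Expression, variables: Mapping[str, Variable]) -> float:
    """Largest value an expression can take, from its variables' bounds.

    ``and`` takes the minimum of its operands' bounds and ``or`` the maximum;
    conditionals and (pseudo-binary) negations are capped at 1.
    """
    if isinstance(expr, Atom):
        return variables[expr.name].upper
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Conditional):
        return 1
    if isinstance(expr, Not):
        return expression_upper_bound(expr.operand, variables)
    if isinstance(expr, Junction):
        l = expression_upper_bound(expr.left, variables)
        r = expression_upper_bound(expr.right, variables)
        return min(l, r) if expr.op == "and" else max(l, r)
    raise TypeError(f"not an expression: {expr!r}")


def evaluate_expression(
    expr: Expression,
    assignment: Assignment,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    variables: Mapping[str, Variable] | None = None,
) -> float:
    """Evaluate an expression under an assignment.

    ``and`` is min, ``or`` is max; ``not`` follows *mode*; a conditional is
    1 if the comparison holds, else 0.  Truth of an expression is "value >
    0".  Inversion-mode negation needs the variables map for upper bounds.
    """
    if isinstance(expr, Atom):
        try:
            return assignment[expr.name]
        except KeyError:
            raise KeyError(f"variable {expr.name!r} is not assigned") from None
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Junction):
        l = evaluate_expression(expr.left, assignment, mode, variables)
        r = evaluate_expression(expr.right, assignment, mode, variables)
        return min(l, r) if expr.op == "and" else max(l, r)
    if isinstance(expr, Conditional):
        l = evaluate_expression(expr.left, assignment, mode, variables)
        r = evaluate_expression(expr.right, assignment, mode, variables)
        return 1 if _cmp(l, expr.op, r) else 0
    if isinstance(expr, Not):
        if isinstance(expr.operand, Conditional):
            c = expr.operand
            flipped = Conditional(c.left, _CMP_NEG[c.op], c.right)
            return evaluate_expression(flipped, assignment, mode, variables)
        value = evaluate_expression(expr.operand, assignment, mode, variables)
        if mode == NotMode.PSEUDO_BINARY:
            return 1 if value == 0 else 0
        if variables is None:
            raise ValueError("inversion mode needs variable bounds")
        upper = expression_upper_bound(expr.operand, variables)
        if upper == float("inf"):
            raise ValueError("inversion mode requires a finite upper bound")
        return upper - value
    raise TypeError(f"not an expression: {expr!r}")


def evaluate_rule(
    rule: Rule,
    assignment: Assignment,
    mode: NotMode = NotMode.PSEUDO_BINARY,
    variables: Mapping[str, Variable] | None = None,
) -> bool:
    """Whether a rule holds under an assignment.

    ``<=>`` requires equal antecedent and consequent values; ``=>`` requires
    value(consequent) >= value(antecedent), which on binary variables is
    classical implication.
    """
    va = evaluate_expression(rule.antecedent, assignment, mode, variables)
    vc = evaluate_expression(rule.consequent, assignment, mode, variables)
    return va == vc if rule.is_iff else vc >= va


def _expr_atoms(expr: Expression) -> Iterable[str]:
    if isinstance(expr, Atom):
        yield expr.name
    elif isinstance(expr, Not):
        yield from _expr_atoms(expr.operand)
    elif isinstance(expr, Junction):
        yield from _expr_atoms(expr.left)
        yield from _expr_atoms(expr.right)
    elif isinstance(expr, Conditional):
        yield from _expr_atoms(expr.left)
        yield from _expr_atoms(expr.right)


def rule_atoms(rule: Rule) -> list[str]:
    """All variable names referenced by a rule, in first-occurrence order."""
    seen: dict[str, None] = {}
    for name in itertools.chain(_expr_atoms(rule.antecedent), _expr_atoms(rule.consequent)):
        seen.setdefault(name)
    return list(seen)


def collect_variables(
    rules: Iterable[Rule],
    declared: Mapping[str, Variable] | None = None,
    default_upper: int = 1,
) -> dict[str, Variable]:
    """Variables referenced by the rules; undeclared ones get default bounds."""
    variables: dict[str, Variable] = dict(declared or {})
    for rule in rules:
        for name in rule_atoms(rule):
            variables.setdefault(name, Variable(name, 0, default_upper))
    return variables


def _references_flux(expr: Expression, variables: Mapping[str, Variable]) -> bool:
    if isinstance(expr, Atom):
        return variables[expr.name].kind == "flux"
    if isinstance(expr, Not):
        return _references_flux(expr.operand, variables)
    if isinstance(expr, (Junction, Conditional)):
        return _references_flux(expr.left, variables) or _references_flux(
            expr.right, variables
        )
    return False


def enumerate_feasible_states(
    rules: Sequence[Rule],
    variables: Mapping[str, Variable],
    mode: NotMode = NotMode.PSEUDO_BINARY,
    cap: int = 2**20,
) -> list[dict[str, int]]:
    """All assignments over *variables* satisfying every rule simultaneously.

    Exhaustive product over each variable's integer levels; this is the
    reference oracle for the MILP compilation.  States are ordered
    lexicographically by sorted variable name, then level.
    """
    names = sorted(variables)
    for rule in rules:
        if _references_flux(rule.antecedent, variables) or _references_flux(
            rule.consequent, variables
        ):
            raise ValueError("cannot enumerate rules with flux conditionals")
    total = 1
    for name in names:
        total *= len(variables[name].levels)
        if total > cap:
            raise ValueError(f"state space exceeds cap ({cap})")
    feasible = []
    for levels in itertools.product(*(variables[n].levels for n in names)):
        assignment = dict(zip(names, levels))
        if all(evaluate_rule(r, assignment, mode, variables) for r in rules):
            feasible.append(assignment)
    return feasible


# ---------------------------------------------------------------------------
# Rule files
# ---------------------------------------------------------------------------

_DECLARE_RE = re.compile(
    r"^declare\s+(?:'(?P<qname>[^']+)'|(?P<name>\S+))\s+in\s*\[\s*(?P<lo>-?\d+)\s*,\s*(?P<hi>-?\d+)\s*\]\s*$"
)
_MODE_RE = re.compile(r"^mode\s+(?P<mode>inversion|pseudo_binary)\s*$")


def parse_rule_lines(
    lines: Iterable[str],
) -> tuple[list[Rule], dict[str, Variable], NotMode | None]:
    """Parse rule-file lines: rules, ``declare x in [lo, hi]``, ``mode ...``.

    Blank lines and ``%`` comments are ignored.  Returns the rules (ids are
    1-based line order), declared variables, and the mode header if present.
    """
    rules: list[Rule] = []
    declared: dict[str, Variable] = {}
    mode: NotMode | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("%", 1)[0].strip()
        if not line:
            continue
        if m := _MODE_RE.match(line):
            mode = NotMode(m.group("mode"))
            continue
        if m := _DECLARE_RE.match(line):
            name = m.group("qname") or m.group("name")
            declared[name] = Variable(name, int(m.group("lo")), int(m.group("hi")))
            continue
        try:
            rules.append(parse_rule(line, rule_id=len(rules) + 1))
        except RuleSyntaxError as exc:
            raise RuleSyntaxError(str(exc).rsplit(" (line", 1)[0], lineno, exc.column) from None
    return rules, declared, mode


def read_rule_file(path: str) -> tuple[list[Rule], dict[str, Variable], NotMode | None]:
    """Read a UTF-8 rule file (one rule per line; see :func:`parse_rule_lines`)."""
    with open(path, encoding="utf-8") as fh:
        return parse_rule_lines(fh)
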