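"""Bracketed parametric stochastic L-systems with hierarchical organ grammars.

An L-system is a formal grammar ``{V, T, omega, P}``: starting from the axiom
``omega``, all symbols are rewritten in parallel for ``n`` iterations by the
production rules ``P``; symbols without a matching rule are copied unchanged.
Productions may be parametric (formal parameters with arithmetic successor
expressions and an optional guard condition) and stochastic (several
successors with positive weights, sampled by normalized weight).

Plants are modeled hierarchically: a plant-level grammar contains placeholder
symbols, each bound to an organ-level sub-grammar (a leaf or branch shape
grammar). :func:`expand_hierarchical` derives the plant string and splices a
freshly derived sub-grammar string into every placeholder occurrence, wrapped
in organ-span markers so the derived string can later be decomposed into the
individual organ meshes it generates.

Grammar dialect (UTF-8 text, one statement per line, ``#`` comments)::

    angle: 137.5            # default turning angle, degrees
    step:  1.0              # default forward step, length units
    axiom: A(6)
    A(n) : n > 0 -> (0.8) [ &(60) L ] /(137.5) A(n-1) | (0.2) /(137.5) A(n-1)
    sub L = rosette_leaf.lsys @ 3 class=leaf

Rules read ``pred(params) [: condition] -> (w1) succ1 | (w2) succ2 ...``;
weights may be omitted for a single successor. An optional ``terminals:``
line switches on strict symbol checking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .expressions import Expression, ExpressionError

__all__ = [
    "ModuleSymbol",
    "ProductionRule",
    "Grammar",
    "SubGrammarBinding",
    "SymbolString",
    "OrganSpan",
    "GrammarError",
    "parse_grammar",
    "load_grammar",
    "derive",
    "expand_hierarchical",
    "ORGAN_CLASSES",
    "SPAN_OPEN",
    "SPAN_CLOSE",
]

ORGAN_CLASSES = ("leaf", "branch")

#: Marker symbols delimiting an organ instance inside a derived string.
SPAN_OPEN = "%{"
SPAN_CLOSE = "%}"

_PUNCT_SYMBOLS = set("+-&^\\/|[]{}.!'")


class GrammarError(ValueError):
    """Grammar parse or validation failure; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class ModuleSymbol:
    """One parameterized symbol of a derived string (e.g. ``F(1.5)`` or ``+``)."""

    name: str
    params: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise GrammarError("symbol name must be non-empty")
        if not all(np.isfinite(self.params)):
            raise GrammarError(f"non-finite parameter in symbol {self.name!r}")

    def __str__(self) -> str:
        if not self.params:
            return self.name
        return f"{self.name}({','.join(format(p, 'g') for p in self.params)})"


@dataclass(frozen=True)
class SymbolTemplate:
    """A successor symbol whose parameters are expressions over formal params."""

    name: str
    params: tuple[Expression, ...] = ()

    def instantiate(self, env: dict[str, float]) -> ModuleSymbol:
        return ModuleSymbol(self.name, tuple(expr(env) for expr in self.params))


@dataclass(frozen=True)
class ProductionRule:
    predecessor: str
    formal_params: tuple[str, ...]
    successors: tuple[tuple[float, tuple[SymbolTemplate, ...]], ...]
    condition: Expression | None = None
    line: int | None = None

    def __post_init__(self):
        if not self.successors:
            raise GrammarError("rule needs at least one successor", self.line)
        for w, _ in self.successors:
            if not (w > 0 and np.isfinite(w)):
                raise GrammarError(f"successor weight must be positive, got {w}", self.line)

    @property
    def arity(self) -> int:
        return len(self.formal_params)

    def matches(self, symbol: ModuleSymbol) -> bool:
        if symbol.name != self.predecessor or len(symbol.params) != self.arity:
            return False
        if self.condition is None:
            return True
        env = dict(zip(self.formal_params, symbol.params))
        return bool(self.condition(env))


@dataclass(frozen=True)
class SubGrammarBinding:
    """A placeholder symbol bound to an organ-level sub-grammar."""

    grammar: "Grammar"
    iterations: int
    organ_class: str

    def __post_init__(self):
        if self.organ_class not in ORGAN_CLASSES:
            raise GrammarError(f"organ class must be one of {ORGAN_CLASSES}")
        if self.iterations < 0:
            raise GrammarError("sub-grammar iteration count must be >= 0")


@dataclass
class Grammar:
    """A validated L-system ``{V, T, omega, P}`` plus turtle defaults."""

    axiom: tuple[ModuleSymbol, ...]
    rules: tuple[ProductionRule, ...]
    default_angle: float = 90.0
    default_step: float = 1.0
    subgrammars: dict[str, SubGrammarBinding] = field(default_factory=dict)
    declared_terminals: frozenset[str] | None = None
    name: str = ""

    @property
    def nonterminals(self) -> frozenset[str]:
        return frozenset(r.predecessor for r in self.rules)

    @property
    def terminals(self) -> frozenset[str]:
        used = {t.name for _, succ in self._all_successors() for t in succ}
        used |= {s.name for s in self.axiom}
        return frozenset(used - self.nonterminals - set(self.subgrammars))

    def _all_successors(self):
        for rule in self.rules:
            yield from rule.successors

    def validate(self) -> None:
        v = self.nonterminals
        if v & set(self.subgrammars):
            dup = sorted(v & set(self.subgrammars))
            raise GrammarError(f"placeholder name(s) {dup} collide with nonterminals")
        if self.declared_terminals is not None:
            allowed = v | self.declared_terminals | set(self.subgrammars) | _PUNCT_SYMBOLS
            for sym in self.axiom:
                if sym.name not in allowed:
                    raise GrammarError(f"undeclared symbol {sym.name!r} in axiom")
            for rule in self.rules:
                for _, succ in rule.successors:
                    for t in succ:
                        if t.name not in allowed:
                            raise GrammarError(
                                f"undeclared symbol {t.name!r} in rule for "
                                f"{rule.predecessor!r}", rule.line,
                            )
        arity_by_name: dict[str, set[int]] = {}
        for rule in self.rules:
            arity_by_name.setdefault(rule.predecessor, set()).add(rule.arity)
        self._rule_arities = arity_by_name


@dataclass(frozen=True)
class OrganSpan:
    """Half-open index range of one organ instance inside a SymbolString."""

    instance_id: int
    organ_class: str
    start: int
    end: int


@dataclass(frozen=True)
class SymbolString:
    """A derived sequence of symbols with organ-instance annotations."""

    symbols: tuple[ModuleSymbol, ...]
    organ_spans: tuple[OrganSpan, ...] = ()

    def __str__(self) -> str:
        return " ".join(str(s) for s in self.symbols)

    def plain(self) -> str:
        """Concatenated bare symbol names (markers dropped); handy for tests."""
        return "".join(
            s.name for s in self.symbols if s.name not in (SPAN_OPEN, SPAN_CLOSE)
        )

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# Dialect parsing
# ---------------------------------------------------------------------------

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_SUB_RE = re.compile(
    r"^sub\s+(?P<name>[A-Za-z_][A-Za-z0-9_]*)\s*=\s*(?P<path>\S+)"
    r"\s*@\s*(?P<n>\d+)(?:\s*iterations?)?\s+class\s*=\s*(?P<cls>leaf|branch)\s*$"
)


def _split_args(body: str, line: int) -> list[str]:
    """Split a parenthesized argument body on top-level commas."""
    args, depth, start = [], 0, 0
    for i, ch in enumerate(body):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise GrammarError("unbalanced parentheses in arguments", line)
        elif ch == "," and depth == 0:
            args.append(body[start:i])
            start = i + 1
    if depth != 0:
        raise GrammarError("unbalanced parentheses in arguments", line)
    args.append(body[start:])
    return [a.strip() for a in args]


def _scan_symbols(text: str, line: int) -> list[tuple[str, list[str]]]:
    """Tokenize a symbol sequence into (name, raw-arg-strings) pairs."""
    out: list[tuple[str, list[str]]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        m = _IDENT_RE.match(text, i)
        if m:
            name = m.group(0)
            i = m.end()
        elif text.startswith(SPAN_OPEN, i) or text.startswith(SPAN_CLOSE, i):
            name = text[i : i + 2]
            i += 2
        elif ch in _PUNCT_SYMBOLS:
            name = ch
            i += 1
        else:
            raise GrammarError(f"unexpected character {ch!r}", line)
        args: list[str] = []
        if i < n and text[i] == "(":
            depth, j = 1, i + 1
            while j < n and depth:
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise GrammarError("unclosed '(' in symbol arguments", line)
            body = text[i + 1 : j - 1]
            if body.strip():
                args = _split_args(body, line)
            i = j
        out.append((name, args))
    return out


def _parse_symbol_sequence(text: str, line: int) -> tuple[ModuleSymbol, ...]:
    symbols = []
    for name, args in _scan_symbols(text, line):
        try:
            params = tuple(float(Expression(a)({})) for a in args)
        except ExpressionError as exc:
            raise GrammarError(str(exc), line) from exc
        symbols.append(ModuleSymbol(name, params))
    return tuple(symbols)


def _parse_template_sequence(
    text: str, formals: Sequence[str], line: int
) -> tuple[SymbolTemplate, ...]:
    templates = []
    for name, args in _scan_symbols(text, line):
        exprs = []
        for a in args:
            try:
                expr = Expression(a)
            except ExpressionError as exc:
                raise GrammarError(str(exc), line) from exc
            extra = expr.variables - set(formals)
            if extra:
                raise GrammarError(
                    f"parameter(s) {sorted(extra)} not declared in rule head", line
                )
            exprs.append(expr)
        templates.append(SymbolTemplate(name, tuple(exprs)))
    return tuple(templates)


def _parse_rule(line_text: str, line: int) -> ProductionRule:
    head, _, tail = line_text.partition("->")
    if not tail:
        raise GrammarError("rule is missing '->'", line)
    head = head.strip()
    cond_expr: Expression | None = None
    if ":" in head:
        head, _, cond_src = head.partition(":")
        try:
            cond_expr = Expression(cond_src)
        except ExpressionError as exc:
            raise GrammarError(str(exc), line) from exc
        head = head.strip()
    m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)\s*(?:\((.*)\))?$", head)
    if not m:
        raise GrammarError(f"bad rule predecessor {head!r}", line)
    pred = m.group(1)
    formals: tuple[str, ...] = ()
    if m.group(2) is not None and m.group(2).strip():
        formals = tuple(p.strip() for p in m.group(2).split(","))
        for p in formals:
            if not _IDENT_RE.fullmatch(p):
                raise GrammarError(f"bad formal parameter {p!r}", line)
        if len(set(formals)) != len(formals):
            raise GrammarError("duplicate formal parameter", line)
    if cond_expr is not None:
        extra = cond_expr.variables - set(formals)
        if extra:
            raise GrammarError(
                f"condition uses undeclared parameter(s) {sorted(extra)}", line
            )
    successors = []
    for branch in _split_alternatives(tail, line):
        branch = branch.strip()
        weight = 1.0
        wm = re.match(r"^\(\s*([0-9.eE+\-]+)\s*\)\s*", branch)
        if wm:
            weight = float(wm.group(1))
            branch = branch[wm.end():]
        successors.append((weight, _parse_template_sequence(branch, formals, line)))
    return ProductionRule(pred, formals, tuple(successors), cond_expr, line)


def _split_alternatives(tail: str, line: int) -> list[str]:
    """Split successors on top-level '|' ('|' inside no parens — the turtle
    symbol '|' never starts a branch because branches start with '(' weights
    or symbols; we split only on '|' surrounded by whitespace at depth 0)."""
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(tail):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "|" and depth == 0:
            before = tail[max(0, i - 1) : i]
            after = tail[i + 1 : i + 2]
            if (before == "" or before.isspace()) and (after == "" or after.isspace()):
                parts.append(tail[start:i])
                start = i + 1
    parts.append(tail[start:])
    return parts


def parse_grammar(
    text: str,
    *,
    search_path: str | Path | None = None,
    name: str = "",
) -> Grammar:
    """Parse a grammar-dialect document into a validated :class:`Grammar`.

    ``sub`` statements load their referenced grammar file relative to
    *search_path* (required if any ``sub`` line is present).
    """
    axiom: tuple[ModuleSymbol, ...] | None = None
    rules: list[ProductionRule] = []
    angle, step = 90.0, 1.0
    terminals: frozenset[str] | None = None
    subs: dict[str, SubGrammarBinding] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lowered = line.lower()
        if lowered.startswith("angle:"):
            angle = float(line.split(":", 1)[1])
        elif lowered.startswith("step:"):
            step = float(line.split(":", 1)[1])
        elif lowered.startswith("axiom:"):
            axiom = _parse_symbol_sequence(line.split(":", 1)[1], lineno)
        elif lowered.startswith("terminals:"):
            terminals = frozenset(line.split(":", 1)[1].split())
        elif lowered.startswith("sub "):
            m = _SUB_RE.match(line)
            if not m:
                raise GrammarError(f"bad sub-grammar binding {line!r}", lineno)
            placeholder = m.group("name")
            if placeholder in subs:
                raise GrammarError(f"duplicate placeholder {placeholder!r}", lineno)
            if search_path is None:
                raise GrammarError(
                    "sub-grammar binding requires a search path", lineno
                )
            sub_path = Path(search_path) / m.group("path")
            if not sub_path.exists():
                raise GrammarError(f"sub-grammar file not found: {sub_path}", lineno)
            sub = load_grammar(sub_path)
            subs[placeholder] = SubGrammarBinding(sub, int(m.group("n")), m.group("cls"))
        else:
            rules.append(_parse_rule(line, lineno))

    if axiom is None:
        raise GrammarError("grammar has no 'axiom:' line")
    g = Grammar(
        axiom=axiom,
        rules=tuple(rules),
        default_angle=angle,
        default_step=step,
        subgrammars=subs,
        declared_terminals=terminals,
        name=name,
    )
    g.validate()
    return g


def load_grammar(path: str | Path) -> Grammar:
    """Load and parse a ``.lsys`` grammar file; ``sub`` paths resolve
    relative to the file's directory."""
    path = Path(path)
    return parse_grammar(
        path.read_text(encoding="utf-8"), search_path=path.parent, name=path.stem
    )


# ---------------------------------------------------------------------------
# Derivation
# ---------------------------------------------------------------------------


def _draw_uniform(seed: int, iteration: int, position: int) -> float:
    """One uniform draw from a counter-based stream keyed on
    (seed, iteration, position), so stochastic choices at one position are
    unaffected by rewrites elsewhere in the string."""
    ss = np.random.SeedSequence((int(seed) & 0x7FFFFFFF, iteration, position))
    return float(np.random.default_rng(ss).random())


def _rewrite_symbol(
    symbol: ModuleSymbol,
    rules_for: dict[str, list[ProductionRule]],
    seed: int,
    iteration: int,
    position: int,
) -> tuple[ModuleSymbol, ...]:
    candidates = rules_for.get(symbol.name)
    if candidates is None:
        return (symbol,)
    matching = [r for r in candidates if r.matches(symbol)]
    if not matching:
        arities = {r.arity for r in candidates}
        if len(symbol.params) not in arities:
            raise GrammarError(
                f"symbol {symbol} has {len(symbol.params)} parameter(s) but rules "
                f"for {symbol.name!r} expect arity {sorted(arities)}"
            )
        return (symbol,)  # all conditions false: identity
    rule = matching[0]
    env = dict(zip(rule.formal_params, symbol.params))
    if len(rule.successors) == 1:
        _, templates = rule.successors[0]
    else:
        weights = np.array([w for w, _ in rule.successors], dtype=float)
        cdf = np.cumsum(weights / weights.sum())
        u = _draw_uniform(seed, iteration, position)
        idx = int(np.searchsorted(cdf, u, side="right"))
        idx = min(idx, len(rule.successors) - 1)
        _, templates = rule.successors[idx]
    return tuple(t.instantiate(env) for t in templates)


def derive(grammar: Grammar, n: int, seed: int = 0) -> SymbolString:
    """Apply the production rules in parallel for *n* iterations.

    Deterministic given ``(grammar, n, seed)``; ``n = 0`` returns the axiom.
    Placeholder symbols bound to sub-grammars are left unexpanded.
    """
    if n < 0:
        raise ValueError("iteration count must be >= 0")
    rules_for: dict[str, list[ProductionRule]] = {}
    for rule in grammar.rules:
        rules_for.setdefault(rule.predecessor, []).append(rule)
    current: tuple[ModuleSymbol, ...] = grammar.axiom
    for it in range(n):
        out: list[ModuleSymbol] = []
        for pos, sym in enumerate(current):
            out.extend(_rewrite_symbol(sym, rules_for, seed, it, pos))
        current = tuple(out)
    return SymbolString(current)


def _child_seed(seed: int, occurrence: int) -> int:
    ss = np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 0x5EED, occurrence))
    return int(ss.generate_state(1)[0] % (2**31))


def expand_hierarchical(plant: Grammar, n_plant: int, seed: int = 0) -> SymbolString:
    """Derive the plant string and splice a derived sub-grammar string into
    every placeholder occurrence, wrapped in organ-span markers.

    Placeholders are replaced left-to-right; occurrence *k* (0-based) gets a
    fresh instance id ``k+1`` and a child seed derived from ``(seed, k)``, so
    each organ's internal stochastic choices are independent and the whole
    expansion is reproducible.
    """
    skeleton = derive(plant, n_plant, seed)
    placeholders = set(plant.subgrammars)
    symbols: list[ModuleSymbol] = []
    spans: list[OrganSpan] = []
    next_id = 1
    class_code = {cls: i + 1 for i, cls in enumerate(ORGAN_CLASSES)}
    for sym in skeleton.symbols:
        if sym.name in placeholders:
            binding = plant.subgrammars[sym.name]
            organ = derive(binding.grammar, binding.iterations, _child_seed(seed, next_id - 1))
            inst = next_id
            next_id += 1
            symbols.append(
                ModuleSymbol(SPAN_OPEN, (float(inst), float(class_code[binding.organ_class])))
            )
            start = len(symbols)
            symbols.extend(organ.symbols)
            end = len(symbols)
            symbols.append(ModuleSymbol(SPAN_CLOSE))
            spans.append(OrganSpan(inst, binding.organ_class, start, end))
        else:
            symbols.append(sym)
    return SymbolString(tuple(symbols), tuple(spans))
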