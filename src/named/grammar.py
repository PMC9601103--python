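"""Parser for KEGG module DEFINITION strings.

A KEGG module definition is a Boolean expression over gene accessions
describing the alternative gene complements that realise a pathway
segment.  The (undocumented but conventional) syntax is:

* whitespace separates consecutive reaction steps (logical AND);
* a comma separates alternatives (logical OR) and binds looser than space;
* ``+`` joins subunits of an enzyme complex (all required);
* ``-`` prefixes a non-essential (optional) component;
* ``--`` is a gap: a reaction step with no known gene;
* parentheses group subexpressions.

``parse_definition`` builds a normalised expression tree
(:class:`DefinitionNode`), ``serialize_definition`` renders the canonical
string form (a round-trip identity), and ``enumerate_paths`` expands the
tree into explicit alternative step paths, each a sequence of accession
sets that must all be present for the step to count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .accessions import Accession, AccessionError, parse_accession

__all__ = [
    "DefinitionNode",
    "ModuleDefinition",
    "DefinitionParseError",
    "GAP_STEP",
    "parse_definition",
    "serialize_definition",
    "enumerate_paths",
    "count_paths",
    "read_kegg_module_file",
    "read_kegg_module_text",
    "write_kegg_module_file",
]

logger = logging.getLogger(__name__)

#: Marker for an unsatisfiable (gap) step inside a path: the empty set.
GAP_STEP: frozenset = frozenset()


class DefinitionParseError(ValueError):
    """Raised when a DEFINITION string cannot be parsed; carries the offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


@dataclass(frozen=True)
class DefinitionNode:
    """A node of the definition expression tree.

    ``kind`` is one of ``LEAF``, ``AND``, ``OR``, ``COMPLEX``, ``OPTIONAL``,
    ``GAP``.  ``children`` is empty for LEAF/GAP; ``accession`` is set for
    LEAF only.
    """

    kind: str
    children: tuple["DefinitionNode", ...] = ()
    accession: Accession | None = None

    def __post_init__(self):
        if self.kind in ("AND", "OR", "COMPLEX") and len(self.children) < 2:
            raise ValueError(f"{self.kind} node requires >=2 children")
        if self.kind == "OPTIONAL" and len(self.children) != 1:
            raise ValueError("OPTIONAL node requires exactly 1 child")
        if self.kind in ("LEAF", "GAP") and self.children:
            raise ValueError(f"{self.kind} node takes no children")
        if self.kind == "LEAF" and self.accession is None:
            raise ValueError("LEAF node requires an accession")

    def leaves(self) -> Iterator[Accession]:
        if self.kind == "LEAF":
            yield self.accession
        for c in self.children:
            yield from c.leaves()


@dataclass
class ModuleDefinition:
    """A KEGG module record: id, name, raw definition and its parsed tree."""

    module_id: str
    name: str
    raw_definition: str
    root: DefinitionNode = field(repr=False)


# ---------------------------------------------------------------------------
# Tokeniser

_TOKEN_CHARS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789.*:_")


def _tokenize(raw: str) -> list[tuple[str, str, int]]:
    """Return (type, text, offset) tokens.

    Types: ``ACC``, ``(``, ``)``, ``,``, ``+``, ``-``, ``GAP``, ``WS``.
    """
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(raw)
    while i < n:
        ch = raw[i]
        if ch.isspace():
            j = i
            while j < n and raw[j].isspace():
                j += 1
            tokens.append(("WS", " ", i))
            i = j
        elif ch in "(),+":
            tokens.append((ch, ch, i))
            i += 1
        elif ch == "-":
            if i + 1 < n and raw[i + 1] == "-":
                tokens.append(("GAP", "--", i))
                i += 2
            else:
                tokens.append(("-", "-", i))
                i += 1
        elif ch in _TOKEN_CHARS:
            j = i
            while j < n and raw[j] in _TOKEN_CHARS:
                j += 1
            tokens.append(("ACC", raw[i:j], i))
            i = j
        else:
            raise DefinitionParseError(f"unexpected character {ch!r}", i)
    return tokens


# ---------------------------------------------------------------------------
# Recursive-descent parser
#
# or_expr  := and_expr ("," and_expr)*
# and_expr := unit (WS unit)*
# unit     := ["-"] complex
# complex  := primary (("+" | "-") primary)*
# primary  := "(" or_expr ")" | ACC | GAP


class _Parser:
    def __init__(self, raw: str):
        self.raw = raw
        self.tokens = [t for t in _tokenize(raw)]
        self.pos = 0

    def _peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int] | None:
        tok = self._peek()
        if tok is not None:
            self.pos += 1
        return tok

    def _skip_ws(self):
        while (t := self._peek()) is not None and t[0] == "WS":
            self.pos += 1

    def parse(self) -> DefinitionNode:
        self._skip_ws()
        if self._peek() is None:
            raise DefinitionParseError("empty definition")
        node = self.or_expr()
        self._skip_ws()
        if (t := self._peek()) is not None:
            if t[0] == ")":
                raise DefinitionParseError("unbalanced parentheses: unmatched ')'", t[2])
            raise DefinitionParseError(f"unexpected token {t[1]!r}", t[2])
        return node

    def or_expr(self) -> DefinitionNode:
        branches = [self.and_expr()]
        while True:
            self._skip_ws()
            t = self._peek()
            if t is None or t[0] != ",":
                break
            self._next()
            self._skip_ws()
            nxt = self._peek()
            if nxt is None or nxt[0] in (",", ")"):
                raise DefinitionParseError("empty OR branch", t[2])
            branches.append(self.and_expr())
        if len(branches) == 1:
            return branches[0]
        return _flatten("OR", branches)

    def and_expr(self) -> DefinitionNode:
        units = [self.unit()]
        while True:
            save = self.pos
            self._skip_ws()
            t = self._peek()
            if t is None or t[0] in (",", ")"):
                self.pos = save
                break
            units.append(self.unit())
        if len(units) == 1:
            return units[0]
        return _flatten("AND", units)

    def unit(self) -> DefinitionNode:
        self._skip_ws()
        t = self._peek()
        if t is not None and t[0] == "-":
            self._next()
            child = self.complex_expr()
            return DefinitionNode("OPTIONAL", (child,))
        return self.complex_expr()

    def complex_expr(self) -> DefinitionNode:
        parts = [(False, self.primary())]
        while (t := self._peek()) is not None and t[0] in ("+", "-"):
            optional = t[0] == "-"
            self._next()
            nxt = self._peek()
            if nxt is None or nxt[0] not in ("ACC", "(", "GAP"):
                raise DefinitionParseError(
                    f"dangling {'-' if optional else '+'} operator", t[2]
                )
            parts.append((optional, self.primary()))
        if len(parts) == 1:
            return parts[0][1]
        children = tuple(
            DefinitionNode("OPTIONAL", (node,)) if optional else node
            for optional, node in parts
        )
        return _flatten("COMPLEX", list(children))

    def primary(self) -> DefinitionNode:
        t = self._next()
        if t is None:
            raise DefinitionParseError("unexpected end of definition")
        kind, text, off = t
        if kind == "(":
            self._skip_ws()
            node = self.or_expr()
            self._skip_ws()
            closing = self._next()
            if closing is None or closing[0] != ")":
                raise DefinitionParseError("unbalanced parentheses: missing ')'", off)
            return node
        if kind == "GAP":
            return DefinitionNode("GAP")
        if kind == "ACC":
            try:
                acc = parse_accession(text)
            except AccessionError as exc:
                raise DefinitionParseError(f"malformed accession token {text!r}: {exc}", off)
            return DefinitionNode("LEAF", accession=acc)
        raise DefinitionParseError(f"unexpected token {text!r}", off)


def _flatten(kind: str, children: list[DefinitionNode]) -> DefinitionNode:
    """Flatten nested same-kind nodes and collapse singletons (normal form)."""
    flat: list[DefinitionNode] = []
    for c in children:
        if c.kind == kind:
            flat.extend(c.children)
        else:
            flat.append(c)
    if len(flat) == 1:
        return flat[0]
    return DefinitionNode(kind, tuple(flat))


def normalize(node: DefinitionNode) -> DefinitionNode:
    """Re-apply flattening bottom-up; idempotent on parser output."""
    if node.kind in ("LEAF", "GAP"):
        return node
    children = [normalize(c) for c in node.children]
    if node.kind == "OPTIONAL":
        return DefinitionNode("OPTIONAL", (children[0],))
    return _flatten(node.kind, children)


def parse_definition(raw: str) -> DefinitionNode:
    """Parse a DEFINITION string into a normalised expression tree."""
    if not raw or not raw.strip():
        raise DefinitionParseError("empty definition")
    depth = 0
    for i, ch in enumerate(raw):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise DefinitionParseError("unbalanced parentheses: unmatched ')'", i)
    if depth != 0:
        raise DefinitionParseError("unbalanced parentheses: missing ')'", len(raw))
    return _Parser(raw).parse()


# ---------------------------------------------------------------------------
# Serialisation

_LEVEL = {"OR": 0, "AND": 1, "COMPLEX": 2, "OPTIONAL": 2, "LEAF": 3, "GAP": 3}


def _serialize(node: DefinitionNode, min_level: int) -> str:
    if node.kind == "LEAF":
        s = node.accession.code
    elif node.kind == "GAP":
        s = "--"
    elif node.kind == "OPTIONAL":
        s = "-" + _serialize(node.children[0], 3)
    elif node.kind == "COMPLEX":
        parts = [_serialize(node.children[0], 3)]
        for c in node.children[1:]:
            if c.kind == "OPTIONAL":
                parts.append("-" + _serialize(c.children[0], 3))
            else:
                parts.append("+" + _serialize(c, 3))
        s = "".join(parts)
    elif node.kind == "AND":
        s = " ".join(_serialize(c, 1) for c in node.children)
    elif node.kind == "OR":
        s = ",".join(_serialize(c, 1) for c in node.children)
    else:  # pragma: no cover
        raise ValueError(f"unknown node kind {node.kind}")
    if _LEVEL[node.kind] < min_level:
        return f"({s})"
    return s


def serialize_definition(root: DefinitionNode) -> str:
    """Render the canonical string form; ``parse(serialize(T)) == T``."""
    return _serialize(root, 0)


# ---------------------------------------------------------------------------
# Path enumeration

StepPath = tuple  # tuple[frozenset[Accession], ...]


def count_paths(node: DefinitionNode) -> int:
    """Number of distinct step paths the tree expands to."""
    if node.kind in ("LEAF", "GAP", "OPTIONAL"):
        # OPTIONAL components are always omitted: one (empty) choice.
        return 1
    if node.kind == "OR":
        return sum(count_paths(c) for c in node.children)
    # AND and COMPLEX multiply their children's alternatives.
    total = 1
    for c in node.children:
        total *= count_paths(c)
    return total


def _expand(node: DefinitionNode) -> Iterator[StepPath]:
    if node.kind == "LEAF":
        yield (frozenset({node.accession}),)
    elif node.kind == "GAP":
        yield (GAP_STEP,)
    elif node.kind == "OPTIONAL":
        yield ()
    elif node.kind == "OR":
        for c in node.children:
            yield from _expand(c)
    elif node.kind == "AND":
        yield from _expand_product(node.children, 0, ())
    elif node.kind == "COMPLEX":
        # Every combination of child paths collapses into a single step
        # requiring the union of all member sets; a gap anywhere makes the
        # whole complex step unsatisfiable.
        for combo in _expand_product(node.children, 0, ()):
            if any(step == GAP_STEP for step in combo):
                yield (GAP_STEP,)
            else:
                members = frozenset().union(*combo) if combo else frozenset()
                yield (members,) if members else ()
    else:  # pragma: no cover
        raise ValueError(f"unknown node kind {node.kind}")


def _expand_product(children, idx, prefix) -> Iterator[StepPath]:
    if idx == len(children):
        yield prefix
        return
    for p in _expand(children[idx]):
        yield from _expand_product(children, idx + 1, prefix + p)


def enumerate_paths(
    root: DefinitionNode, max_paths: int = 10_000
) -> tuple[list[StepPath], bool]:
    """Expand the tree into explicit alternative step paths.

    Each path is a tuple of step-sets; a step-set is the frozenset of
    accessions that must all be present for the step to be satisfied
    (:data:`GAP_STEP`, the empty set, marks an unsatisfiable gap step).
    Returns ``(paths, truncated)``; enumeration stops after ``max_paths``
    with ``truncated=True``.
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    paths: list[StepPath] = []
    truncated = False
    for p in _expand(root):
        if len(paths) >= max_paths:
            truncated = True
            break
        paths.append(p)
    return paths, truncated


# ---------------------------------------------------------------------------
# KEGG flat-file reader / writer


def read_kegg_module_text(text: str, origin: str = "<string>") -> list[ModuleDefinition]:
    """Parse KEGG module flat-file text (ENTRY/NAME/DEFINITION, ///-separated)."""
    modules: list[ModuleDefinition] = []
    records = [r for r in text.split("///") if r.strip()]
    for rec in records:
        fields: dict[str, str] = {}
        key = None
        for line in rec.splitlines():
            if not line.strip():
                continue
            if line[0].isspace():
                if key is not None:
                    fields[key] += " " + line.strip()
                continue
            parts = line.split(None, 1)
            key = parts[0]
            value = parts[1].strip() if len(parts) > 1 else ""
            if key in fields:
                fields[key] += " " + value
            else:
                fields[key] = value
        entry = fields.get("ENTRY", "").split()
        module_id = entry[0] if entry else "?"
        if "DEFINITION" not in fields:
            logger.warning("record %s in %s has no DEFINITION line; skipped", module_id, origin)
            continue
        raw = fields["DEFINITION"]
        modules.append(
            ModuleDefinition(
                module_id=module_id,
                name=fields.get("NAME", ""),
                raw_definition=raw,
                root=parse_definition(raw),
            )
        )
    if not modules:
        raise ValueError(f"no parseable module records found in {origin}")
    return modules


def read_kegg_module_file(path: str | Path) -> list[ModuleDefinition]:
    """Read a KEGG module flat file; records lacking DEFINITION are skipped."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return read_kegg_module_text(text, origin=str(path))


def write_kegg_module_file(modules: list[ModuleDefinition], path: str | Path) -> None:
    lines = []
    for m in modules:
        lines.append(f"ENTRY       {m.module_id}")
        lines.append(f"NAME        {m.name}")
        lines.append(f"DEFINITION  {m.raw_definition}")
        lines.append("///")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
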