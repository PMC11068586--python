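"""Bare-phrase-structure trees: data model, bracket I/O, geometry.

Syntactic objects are strictly binary-branching trees over lexical
leaves.  A leaf carries a :class:`LexicalItem` (category, optional overt
form, formal features) and optionally a copy index linking it to other
occurrences of a moved element; a branch carries exactly two children
and an optional categorial label (adjunction and bar-level nodes may be
unlabeled).

Bracket dialect
---------------
One canonical labeled-bracket dialect renders every structure:

* branch:      ``[Label child child]`` — label ``_`` for an unlabeled node
* leaf:        ``[Cat form]`` (form quoted if it contains spaces),
               ``[Cat]`` for a silent head (null form)
* features:    trailing ``+X`` tokens on a leaf, e.g. ``[D "which game" +Q +N]``
* copy index:  ``~i`` suffix on the category of the highest (overt)
               occurrence, e.g. ``[DP~1 what]``
* lower copy:  ``[<Cat~i>]`` — unpronounced occurrence of mover ``i``

``parse_bracketed`` and ``write_bracketed`` round-trip exactly after
whitespace normalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "Feature",
    "LexicalItem",
    "SyntacticObject",
    "TreeAddress",
    "ParseError",
    "parse_bracketed",
    "write_bracketed",
    "node_count",
    "depth",
    "dominates",
    "c_command",
]


@dataclass(frozen=True, order=True)
class Feature:
    """A formal feature such as Q, N or Focus; rendered ``+Q``."""

    name: str
    present: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")

    def __str__(self) -> str:
        return ("+" if self.present else "-") + self.name


def features(*names: str) -> frozenset:
    """Convenience: ``features("Q", "N")`` -> frozenset of present features."""
    return frozenset(Feature(n) for n in names)


@dataclass(frozen=True)
class LexicalItem:
    """A lexical atom: category, optional overt form, feature set.

    ``form`` is ``None`` for silent heads (phonologically null C, T and
    unpronounced copies).
    """

    category: str
    form: Optional[str] = None
    features: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.category:
            raise ValueError("category must be nonempty")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("a feature set contains each name at most once")


@dataclass(frozen=True)
class TreeAddress:
    """Root-relative path of ``L``/``R`` steps."""

    path: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", tuple(self.path))
        if any(step not in ("L", "R") for step in self.path):
            raise ValueError("address steps must be 'L' or 'R'")

    def child(self, step: str) -> "TreeAddress":
        return TreeAddress(self.path + (step,))

    def is_prefix_of(self, other: "TreeAddress") -> bool:
        return other.path[: len(self.path)] == self.path

    def sister(self) -> "TreeAddress":
        if not self.path:
            raise ValueError("the root has no sister")
        flip = {"L": "R", "R": "L"}
        return TreeAddress(self.path[:-1] + (flip[self.path[-1]],))

    def __len__(self) -> int:
        return len(self.path)

    def __str__(self) -> str:
        return "/".join(self.path) if self.path else "<root>"


class ParseError(ValueError):
    """Malformed labeled-bracket text; message names the offending span."""


@dataclass(frozen=True)
class SyntacticObject:
    """A leaf or binary branch; constructed via :meth:`leaf` / :meth:`branch`.

    Binary branching is enforced structurally: a branch stores exactly
    ``left`` and ``right``.  ``copy_index`` links all occurrences of a
    moved element; ``is_lower_copy`` marks the unpronounced ones.
    """

    item: Optional[LexicalItem] = None
    left: Optional["SyntacticObject"] = None
    right: Optional["SyntacticObject"] = None
    label: Optional[str] = None
    copy_index: Optional[int] = None
    is_lower_copy: bool = False

    @classmethod
    def leaf(
        cls,
        item: LexicalItem,
        copy_index: Optional[int] = None,
        is_lower_copy: bool = False,
    ) -> "SyntacticObject":
        return cls(item=item, copy_index=copy_index, is_lower_copy=is_lower_copy)

    @classmethod
    def branch(
        cls,
        left: "SyntacticObject",
        right: "SyntacticObject",
        label: Optional[str] = None,
        copy_index: Optional[int] = None,
    ) -> "SyntacticObject":
        if left is None or right is None:
            raise ValueError("a branch has exactly two children")
        return cls(left=left, right=right, label=label, copy_index=copy_index)

    # -- structure ----------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return self.item is not None

    @property
    def category(self) -> Optional[str]:
        """Categorial identity: leaf category, or branch label (may be None)."""
        return self.item.category if self.is_leaf else self.label

    def children(self):
        return () if self.is_leaf else (self.left, self.right)

    def at(self, address: TreeAddress) -> "SyntacticObject":
        node = self
        for i, step in enumerate(address.path):
            if node.is_leaf:
                raise ValueError(
                    f"address {address} invalid at step {i}: reached a leaf"
                )
            node = node.left if step == "L" else node.right
        return node

    def walk(self, prefix: TreeAddress = TreeAddress()) -> Iterator:
        """Pre-order (node, address) pairs, left before right."""
        yield self, prefix
        if not self.is_leaf:
            yield from self.left.walk(prefix.child("L"))
            yield from self.right.walk(prefix.child("R"))

    def leaves(self):
        for node, addr in self.walk():
            if node.is_leaf:
                yield node, addr

    def addresses(self):
        for _, addr in self.walk():
            yield addr


# ---------------------------------------------------------------------
# bracket I/O
# ---------------------------------------------------------------------

_TOKEN = re.compile(r'\[|\]|"[^"]*"|[^\s\[\]"]+')
_CAT = re.compile(r"^(?P<lower><)?(?P<cat>[^<>~]+)(~(?P<idx>\d+))?(?(lower)>)$")


def _tokenize(text: str):
    pos = 0
    for m in _TOKEN.finditer(text):
        between = text[pos : m.start()]
        if between.strip():
            raise ParseError(f"unexpected text {between.strip()!r} at offset {pos}")
        pos = m.end()
        yield m.group(0), m.start()
    if text[pos:].strip():
        raise ParseError(f"unexpected text {text[pos:].strip()!r} at offset {pos}")


def parse_bracketed(text: str) -> SyntacticObject:
    """Parse one labeled-bracket structure (see module docstring).

    Raises :class:`ParseError` on unbalanced brackets, a branch without
    exactly two children, or malformed category tokens, naming the
    offending span.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise ParseError("empty input")
    tree, rest = _parse_node(tokens, 0)
    if rest != len(tokens):
        tok, off = tokens[rest]
        raise ParseError(f"trailing material {tok!r} at offset {off}")
    return tree


def _parse_node(tokens, i):
    tok, off = tokens[i]
    if tok != "[":
        raise ParseError(f"expected '[' at offset {off}, found {tok!r}")
    i += 1
    if i >= len(tokens):
        raise ParseError(f"unclosed bracket opened at offset {off}")
    head, head_off = tokens[i]
    if head in ("[", "]"):
        raise ParseError(f"missing label/category at offset {head_off}")
    m = _CAT.match(head)
    if m is None:
        raise ParseError(f"malformed category token {head!r} at offset {head_off}")
    cat = m.group("cat")
    idx = int(m.group("idx")) if m.group("idx") else None
    lower = bool(m.group("lower"))
    i += 1

    children = []
    words: list = []
    feats: list = []
    while i < len(tokens):
        tok, off = tokens[i]
        if tok == "]":
            i += 1
            return _build_node(cat, idx, lower, children, words, feats, off), i
        if tok == "[":
            child, i = _parse_node(tokens, i)
            children.append((child, off))
        else:
            if tok.startswith("+") and len(tok) > 1:
                feats.append(Feature(tok[1:]))
            elif tok.startswith('"'):
                words.append(tok[1:-1])
            else:
                words.append(tok)
            i += 1
    raise ParseError("unclosed bracket at end of input")


def _build_node(cat, idx, lower, children, words, feats, off):
    if children and words:
        raise ParseError(
            f"bracket closing at offset {off} mixes sub-structures and words"
        )
    if children:
        if len(children) != 2:
            raise ParseError(
                f"branch closing at offset {off} has {len(children)} children; "
                "binary branching requires exactly 2"
            )
        if lower:
            raise ParseError(f"lower copy at offset {off} cannot have children")
        label = None if cat == "_" else cat
        return SyntacticObject.branch(children[0][0], children[1][0], label, idx)
    form = " ".join(words) if words else None
    item = LexicalItem(category=cat, form=form, features=frozenset(feats))
    return SyntacticObject.leaf(item, copy_index=idx, is_lower_copy=lower)


def write_bracketed(t: SyntacticObject) -> str:
    """Render to the canonical dialect; inverse of :func:`parse_bracketed`."""
    if t.is_leaf:
        cat = t.item.category
        if t.copy_index is not None:
            cat = f"{cat}~{t.copy_index}"
        if t.is_lower_copy:
            feats = "".join(f" {f}" for f in sorted(t.item.features))
            return f"[<{cat}>{feats}]"
        parts = [cat]
        if t.item.form is not None:
            form = t.item.form
            parts.append(f'"{form}"' if any(ch.isspace() for ch in form) else form)
        parts.extend(str(f) for f in sorted(t.item.features))
        return "[" + " ".join(parts) + "]"
    label = t.label if t.label is not None else "_"
    if t.copy_index is not None:
        label = f"{label}~{t.copy_index}"
    return f"[{label} {write_bracketed(t.left)} {write_bracketed(t.right)}]"


# ---------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------

def node_count(t: SyntacticObject) -> int:
    """Every branch node and every leaf counts; bar-levels and silent
    heads occupy tree positions and therefore count."""
    return sum(1 for _ in t.walk())


def depth(t: SyntacticObject) -> int:
    """Longest root-to-leaf branch count (a leaf has depth 0)."""
    if t.is_leaf:
        return 0
    return 1 + max(depth(t.left), depth(t.right))


def dominates(t: SyntacticObject, a: TreeAddress, b: TreeAddress) -> bool:
    """Reflexive dominance: ``a`` dominates ``b`` iff ``a`` lies on the
    path from the root to ``b`` (every node dominates itself)."""
    t.at(a), t.at(b)  # validate both addresses
    return a.is_prefix_of(b)


def c_command(t: SyntacticObject, a: TreeAddress, b: TreeAddress) -> bool:
    """``a`` c-commands ``b`` iff a's sister dominates-or-equals ``b``
    and ``a`` does not dominate ``b`` (hence never itself or its
    descendants or ancestors)."""
    t.at(a), t.at(b)
    if not a.path:
        return False
    if a.is_prefix_of(b):
        return False
    return a.sister().is_prefix_of(b)
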