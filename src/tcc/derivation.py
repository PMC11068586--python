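"""MERGE engine over workspaces, with the economy-condition checkers.

A workspace holds the root syntactic objects of a derivation in
progress plus the lexicon it may draw from.  MERGE is the only
structure-building operation:

* external MERGE introduces a lexical item (or combines two existing
  roots) to form ``{Z, {X, Y}}``;
* internal MERGE re-merges a subterm of a root at that root's edge,
  leaving an unpronounced lower copy — movement under the copy theory.

All operations are persistent: inputs are never mutated, so previously
built structure is preserved by construction (the No Tampering
Condition), and each checker re-verifies the condition it names on an
arbitrary :class:`DerivationStep`.

Accounting conventions (Resource Restriction):

* accessible terms = all subterms of all roots; lower copies are the
  same object as their antecedent and do not add to the count;
* workspace size = accessible terms + number of roots (the root object
  counts in both, the default convention; ``count_roots_in_terms=False``
  gives the alternative);
* external merge of a fresh lexical item is modeled as selection into
  the workspace followed by MERGE, so that each MERGE step proper adds
  exactly one accessible element (the new set node).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .syntree import (
    LexicalItem,
    SyntacticObject,
    TreeAddress,
    parse_bracketed,
    write_bracketed,
)

__all__ = [
    "Workspace",
    "DerivationStep",
    "DerivationError",
    "merge_external",
    "merge_internal",
    "check_no_tampering",
    "check_resource_restriction",
    "workspace_size",
    "accessible_terms",
    "markov_check",
    "successor_operations",
    "run_script",
    "enumerate_derivations",
]


class DerivationError(ValueError):
    """Illegal derivation step (bad operand, self-merge, missing root)."""


@dataclass(frozen=True)
class Workspace:
    """Ordered collection of root syntactic objects plus a lexicon."""

    roots: tuple = ()
    lexicon: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "roots", tuple(self.roots))
        object.__setattr__(self, "lexicon", tuple(self.lexicon))

    def replace_root(self, index: int, new_root: SyntacticObject) -> "Workspace":
        roots = list(self.roots)
        roots[index] = new_root
        return replace(self, roots=tuple(roots))

    def canonical(self) -> frozenset:
        """Order-insensitive identity: the multiset of rendered roots."""
        rendered = sorted(write_bracketed(r) for r in self.roots)
        return tuple(rendered)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Workspace):
            return NotImplemented
        return self.canonical() == other.canonical() and self.lexicon == other.lexicon

    def __hash__(self) -> int:
        return hash((self.canonical(), self.lexicon))


@dataclass(frozen=True)
class DerivationStep:
    kind: str  # "external_merge" | "internal_merge"
    operands: tuple
    before: Workspace
    after: Workspace


def _subterms(t: SyntacticObject):
    """All subterms, skipping lower copies (same object as antecedent)."""
    if t.is_lower_copy:
        return
    yield t
    for child in t.children():
        yield from _subterms(child)


def accessible_terms(ws: Workspace) -> int:
    """Number of computationally accessible terms across all roots."""
    return sum(1 for root in ws.roots for _ in _subterms(root))


def workspace_size(ws: Workspace, count_roots_in_terms: bool = True) -> int:
    """Accessible terms plus number of syntactic objects (roots)."""
    terms = accessible_terms(ws)
    if not count_roots_in_terms:
        terms -= sum(1 for r in ws.roots)
    return terms + len(ws.roots)


def merge_external(
    ws: Workspace,
    x: Union[LexicalItem, int],
    y: int,
    label: Optional[str] = None,
) -> DerivationStep:
    """MERGE a new lexical item, or another root, with root ``y``.

    ``x`` is a :class:`LexicalItem` drawn from the lexicon, or the index
    of another root.  Returns the step whose ``after`` workspace has
    ``{x, y}`` in place of ``y`` (and, for root-root merge, with ``x``
    removed from the root list).
    """
    if not (0 <= y < len(ws.roots)):
        raise DerivationError(f"no root at index {y}")
    if isinstance(x, LexicalItem):
        x_obj = SyntacticObject.leaf(x)
        before = replace(ws, roots=ws.roots + (x_obj,))
        x_index = len(before.roots) - 1
    else:
        if not (0 <= x < len(ws.roots)):
            raise DerivationError(f"no root at index {x}")
        if x == y:
            raise DerivationError("external merge needs two distinct roots")
        before = ws
        x_index, x_obj = x, ws.roots[x]
    new_root = SyntacticObject.branch(x_obj, before.roots[y], label=label)
    roots = [r for i, r in enumerate(before.roots) if i not in (x_index, y)]
    # keep the derived object in y's slot ordering
    insert_at = min(x_index, y) if isinstance(x, int) else y
    roots.insert(min(insert_at, len(roots)), new_root)
    after = replace(before, roots=tuple(roots))
    return DerivationStep("external_merge", (repr(x), y, label), before, after)


def merge_internal(
    ws: Workspace,
    root: int,
    target: TreeAddress,
    label: Optional[str] = None,
    copy_index: Optional[int] = None,
) -> DerivationStep:
    """Re-merge the subterm at ``target`` to the edge of ``root``.

    The result is ``{target, root}``: a fresh copy of the target sits at
    the edge, and the original occurrence becomes an unpronounced lower
    copy sharing a copy index.
    """
    if not (0 <= root < len(ws.roots)):
        raise DerivationError(f"no root at index {root}")
    if not target.path:
        raise DerivationError("self-merge of the root is excluded")
    old_root = ws.roots[root]
    moved = old_root.at(target)
    if moved.is_lower_copy:
        raise DerivationError("cannot re-merge a lower copy")
    idx = copy_index if copy_index is not None else _fresh_copy_index(ws)
    trace_item = LexicalItem(category=_category_of(moved), form=None)
    trace = SyntacticObject.leaf(trace_item, copy_index=idx, is_lower_copy=True)
    gutted = _replace_at(old_root, target, trace)
    mover = _with_copy_index(moved, idx)
    new_root = SyntacticObject.branch(mover, gutted, label=label)
    after = ws.replace_root(root, new_root)
    return DerivationStep("internal_merge", (root, target.path, label), ws, after)


def _category_of(t: SyntacticObject) -> str:
    if t.category is not None:
        return t.category
    # unlabeled branch: project the head category of the left child
    return _category_of(t.left)


def _fresh_copy_index(ws: Workspace) -> int:
    used = [
        node.copy_index
        for root in ws.roots
        for node, _ in root.walk()
        if node.copy_index is not None
    ]
    return max(used, default=0) + 1


def _replace_at(
    t: SyntacticObject, address: TreeAddress, new: SyntacticObject
) -> SyntacticObject:
    if not address.path:
        return new
    step, rest = address.path[0], TreeAddress(address.path[1:])
    if t.is_leaf:
        raise DerivationError(f"address {address} runs past a leaf")
    if step == "L":
        return replace(t, left=_replace_at(t.left, rest, new))
    return replace(t, right=_replace_at(t.right, rest, new))


def _with_copy_index(t: SyntacticObject, idx: int) -> SyntacticObject:
    return replace(t, copy_index=idx)


# ---------------------------------------------------------------------
# economy checkers
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CheckResult:
    passed: bool
    witness: Optional[str] = None

    def __bool__(self) -> bool:
        return self.passed


def check_no_tampering(step: DerivationStep) -> CheckResult:
    """Pass iff every pre-existing subtree occurs node-identically after.

    Comparison is modulo the copy theory: a lower copy stands for the
    very object it is a copy of, so occurrences are compared after
    expanding each lower copy to its antecedent's content and erasing
    copy marks.  Anything else missing is tampering, reported with a
    witness address and rendering.
    """
    after_parts = {
        _copy_neutral(node, _antecedents(step.after))
        for root in step.after.roots
        for node, _ in root.walk()
    }
    before_ante = _antecedents(step.before)
    for root in step.before.roots:
        for node, addr in root.walk():
            if _copy_neutral(node, before_ante) not in after_parts:
                return CheckResult(
                    False, witness=f"{addr}: {write_bracketed(node)}"
                )
    return CheckResult(True)


def _antecedents(ws: Workspace) -> dict:
    out = {}
    for root in ws.roots:
        for node, _ in root.walk():
            if node.copy_index is not None and not node.is_lower_copy:
                out[node.copy_index] = node
    return out


def _copy_neutral(t: SyntacticObject, antecedents: dict, _depth: int = 0) -> str:
    """Copy-erased rendering: lower copies expand to their antecedent."""
    if _depth > 64:  # defensive guard against malformed copy chains
        return "<cycle>"
    if t.is_leaf and t.is_lower_copy:
        ante = antecedents.get(t.copy_index)
        if ante is not None and ante is not t:
            return _copy_neutral(ante, antecedents, _depth + 1)
        return write_bracketed(replace(t, copy_index=None, is_lower_copy=False))
    if t.is_leaf:
        return write_bracketed(replace(t, copy_index=None))
    left = _copy_neutral(t.left, antecedents, _depth + 1)
    right = _copy_neutral(t.right, antecedents, _depth + 1)
    label = t.label if t.label is not None else "_"
    return f"[{label} {left} {right}]"


def check_resource_restriction(step: DerivationStep) -> CheckResult:
    """Pass iff accessible elements grow by at most one across the step."""
    delta = accessible_terms(step.after) - accessible_terms(step.before)
    if delta <= 1:
        return CheckResult(True)
    return CheckResult(False, witness=f"accessible terms grew by {delta}")


def successor_operations(ws: Workspace) -> frozenset:
    """Signatures of every legal MERGE applicable to a workspace."""
    ops = set()
    n = len(ws.roots)
    for y in range(n):
        for item in ws.lexicon:
            ops.add(("EM-lex", item.category, item.form, _shape(ws.roots[y])))
        for x in range(n):
            if x != y:
                ops.add(("EM", _shape(ws.roots[x]), _shape(ws.roots[y])))
        for node, addr in ws.roots[y].walk():
            if addr.path and not node.is_lower_copy:
                ops.add(("IM", _shape(ws.roots[y]), addr.path))
    return frozenset(ops)


def _shape(t: SyntacticObject) -> str:
    return write_bracketed(t)


def markov_check(
    history_a: Sequence[DerivationStep], history_b: Sequence[DerivationStep]
) -> bool:
    """Two histories reaching equal workspaces license equal successors.

    Precondition: both histories end in structurally equal workspaces
    (raises :class:`DerivationError` otherwise).  Returns whether the
    sets of legal successor operations coincide — with workspace
    equality this is the Markov property made explicit.
    """
    wa = history_a[-1].after
    wb = history_b[-1].after
    if wa != wb:
        raise DerivationError("histories end in different workspaces")
    return successor_operations(wa) == successor_operations(wb)


# ---------------------------------------------------------------------
# derivation scripts and enumeration
# ---------------------------------------------------------------------

def run_script(text: str, lexicon: Sequence[LexicalItem]) -> list:
    """Replay a derivation script, one operation per line.

    ``EM <category> <root-index> [label]`` merges the first lexicon item
    of that category with the indexed root; ``IM <root-index> <address>
    [label]`` re-merges the subterm at ``address`` (``L/R`` path, or
    ``-`` for root).  Lines starting with ``#`` are comments.  Returns
    the list of steps; ``steps[-1].after`` is the final workspace.
    """
    by_cat = {}
    for item in lexicon:
        by_cat.setdefault(item.category, item)
    ws = Workspace(roots=(), lexicon=tuple(lexicon))
    steps: list = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        op = parts[0].upper()
        try:
            if op == "EM":
                cat, rootidx = parts[1], int(parts[2])
                label = parts[3] if len(parts) > 3 else None
                if rootidx == -1:  # first item: seed the workspace
                    ws = replace(
                        ws,
                        roots=ws.roots
                        + (SyntacticObject.leaf(by_cat[cat]),),
                    )
                    continue
                step = merge_external(ws, by_cat[cat], rootidx, label)
            elif op == "IM":
                rootidx = int(parts[1])
                path = () if parts[2] == "-" else tuple(parts[2])
                label = parts[3] if len(parts) > 3 else None
                step = merge_internal(ws, rootidx, TreeAddress(path), label)
            else:
                raise DerivationError(f"unknown operation {op!r}")
        except (KeyError, IndexError) as exc:
            raise DerivationError(f"line {lineno}: {line!r}: {exc}") from exc
        steps.append(step)
        ws = step.after
    return steps


def steps_to_json(steps: Sequence[DerivationStep]) -> str:
    records = [
        {
            "kind": s.kind,
            "operands": list(map(str, s.operands)),
            "after": [write_bracketed(r) for r in s.after.roots],
        }
        for s in steps
    ]
    return json.dumps(records, indent=2)


def enumerate_derivations(
    lexicon: Sequence[LexicalItem], max_steps: int
) -> Iterator:
    """Yield every derivation (list of steps) of at most ``max_steps``
    MERGE operations from a workspace seeded with one of each item.

    Used by the property suite to verify Resource Restriction and the
    Markov property exhaustively at small sizes.
    """
    seed = Workspace(
        roots=tuple(SyntacticObject.leaf(i) for i in lexicon),
        lexicon=tuple(lexicon),
    )

    def expand(history, ws, budget):
        yield history
        if budget == 0:
            return
        n = len(ws.roots)
        for y in range(n):
            for x in range(n):
                if x == y:
                    continue
                step = merge_external(ws, x, y)
                yield from expand(history + [step], step.after, budget - 1)
            for node, addr in ws.roots[y].walk():
                if addr.path and not node.is_lower_copy:
                    step = merge_internal(ws, y, addr)
                    yield from expand(history + [step], step.after, budget - 1)

    yield from expand([], seed, max_steps)
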