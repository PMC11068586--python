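"""Minimal search, labeling, Relativised Minimality, movement paths.

Minimal search is the breadth-first, least-embedding-first traversal by
which a probe (e.g. interrogative C) locates a feature-matching goal in
its domain.  The step- and depth-counting conventions are the ones
calibrated on the worked interrogative structures (see
``docs/methods.md``):

* search *steps* count each labeled node entered on the path from the
  probe down to the goal — the probe's own node is excluded, the goal's
  included;
* search *depth* counts every labeled node on the root-to-goal path,
  both endpoints included (0 in the degenerate case goal = root).

Unlabeled bar-level nodes occupy positions but are skipped by both
counts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .syntree import (
    Feature,
    SyntacticObject,
    TreeAddress,
    c_command,
    dominates,
)

__all__ = [
    "Probe",
    "SearchResult",
    "RMResult",
    "minimal_search",
    "search_to",
    "search_depth",
    "rm_check",
    "label_of",
    "movement_path",
]


@dataclass(frozen=True)
class Probe:
    """A searching node and the feature set it seeks."""

    origin: TreeAddress
    sought: frozenset

    def __post_init__(self) -> None:
        if not self.sought:
            raise ValueError("feature search needs a nonempty sought set")


@dataclass(frozen=True)
class SearchResult:
    """Probe-to-goal search outcome.

    ``path_labels`` lists the labels of the labeled nodes on the
    origin-to-goal path, origin first, goal last; ``steps`` is the
    number of labeled nodes entered (path_labels minus the origin).
    ``ties`` holds further goals at the same minimal embedding, which
    downstream comparison treats as jointly licensed.
    """

    goal: Optional[TreeAddress]
    path_labels: tuple = ()
    steps: int = 0
    ties: tuple = ()
    nodes_exhausted: int = 0


def _node_features(node: SyntacticObject) -> frozenset:
    return node.item.features if node.is_leaf else frozenset()


def _matches(node: SyntacticObject, sought: frozenset) -> bool:
    if node.is_lower_copy:
        return False
    return sought <= _node_features(node)


def _labels_on_path(t: SyntacticObject, start: TreeAddress, goal: TreeAddress):
    labels = []
    node = t.at(start)
    if node.category is not None:
        labels.append(node.category)
    for i in range(len(start.path), len(goal.path)):
        node = node.left if goal.path[i] == "L" else node.right
        if node.category is not None:
            labels.append(node.category)
    return tuple(labels)


def search_to(
    t: SyntacticObject, origin: TreeAddress, goal: TreeAddress
) -> SearchResult:
    """Search result for an externally fixed goal (used to score the
    ungrammatical alternative a probe is *forced* to reach)."""
    if not origin.is_prefix_of(goal):
        raise ValueError("goal must lie in the origin's domain")
    labels = _labels_on_path(t, origin, goal)
    origin_labeled = t.at(origin).category is not None
    steps = len(labels) - (1 if origin_labeled else 0)
    return SearchResult(goal=goal, path_labels=labels, steps=steps)


def minimal_search(t: SyntacticObject, probe: Probe) -> SearchResult:
    """Find the least-embedded feature-matching node below the probe.

    Breadth-first by embedding depth, left child before right at equal
    depth.  Equally shallow matches are returned as ties (goal = the
    leftmost).  With no match anywhere, ``goal`` is None and
    ``nodes_exhausted`` reports the size of the searched domain.
    """
    origin_node = t.at(probe.origin)
    queue = deque()
    for step in ("L", "R"):
        if not origin_node.is_leaf:
            queue.append(probe.origin.child(step))
    matches: list = []
    match_depth: Optional[int] = None
    visited = 0
    while queue:
        addr = queue.popleft()
        d = len(addr.path)
        if match_depth is not None and d > match_depth:
            break
        node = t.at(addr)
        visited += 1
        if _matches(node, probe.sought):
            matches.append(addr)
            match_depth = d
        if not node.is_leaf:
            queue.append(addr.child("L"))
            queue.append(addr.child("R"))
    if not matches:
        return SearchResult(goal=None, nodes_exhausted=visited)
    goal, ties = matches[0], tuple(matches[1:])
    result = search_to(t, probe.origin, goal)
    return SearchResult(
        goal=goal,
        path_labels=result.path_labels,
        steps=result.steps,
        ties=ties,
        nodes_exhausted=visited,
    )


def search_depth(
    t: SyntacticObject, origin: TreeAddress, goal: TreeAddress
) -> int:
    """Labeled nodes on the origin-to-goal path, endpoints included."""
    if origin.path == goal.path:
        return 0
    if not origin.is_prefix_of(goal):
        raise ValueError("goal must lie below the origin")
    return len(_labels_on_path(t, origin, goal))


# ---------------------------------------------------------------------
# Relativised Minimality
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class RMResult:
    licensed: bool
    intervener: Optional[TreeAddress] = None

    def __bool__(self) -> bool:
        return self.licensed


def rm_check(t: SyntacticObject, probe: Probe, goal: TreeAddress) -> RMResult:
    """Relativised Minimality: an intervener fully matching the relevant
    features blocks the probe-goal relation.

    Z blocks iff Z is c-commanded by the probe, c-commands the goal, and
    Z's features contain both the probe's sought set and the goal's
    feature set (a featurally poorer intervener does not block a richer
    mover).  Monotone: enriching Z's features never unblocks.
    """
    if not c_command(t, probe.origin, goal) and not dominates(
        t, probe.origin, goal
    ):
        raise ValueError("probe must c-command (or dominate) the goal")
    goal_feats = _node_features(t.at(goal))
    for node, addr in t.walk():
        if addr.path == goal.path or addr.path == probe.origin.path:
            continue
        if node.is_lower_copy or not node.is_leaf:
            continue
        between = (
            c_command(t, probe.origin, addr) or dominates(t, probe.origin, addr)
        ) and c_command(t, addr, goal)
        if not between:
            continue
        feats = _node_features(node)
        if probe.sought <= feats and goal_feats <= feats:
            return RMResult(False, intervener=addr)
    return RMResult(True)


# ---------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------

def label_of(branch: SyntacticObject) -> Optional[str]:
    """Label a merged set by minimal search for its most prominent head.

    {head, phrase} labels as the head's category; {phrase, phrase}
    labels by a shared feature if there is exactly one, else None
    (unlabelable, as in unresolved {XP, YP} configurations).  Lower
    copies are invisible: a set {XP-copy, YP} labels from YP.
    """
    if branch.is_leaf:
        raise ValueError("only branch nodes are labeled")
    left, right = branch.left, branch.right
    if left.is_lower_copy and right.is_lower_copy:
        return None
    if left.is_lower_copy:
        return _projected(right)
    if right.is_lower_copy:
        return _projected(left)
    if left.is_leaf and not right.is_leaf:
        return left.item.category
    if right.is_leaf and not left.is_leaf:
        return right.item.category
    if left.is_leaf and right.is_leaf:
        return left.item.category  # head-complement: labeled at once
    shared = _node_leaf_features(left) & _node_leaf_features(right)
    if len(shared) == 1:
        return next(iter(shared)).name
    return None


def _projected(t: SyntacticObject) -> Optional[str]:
    return t.category if t.category is not None else label_of(t)


def _node_leaf_features(t: SyntacticObject) -> frozenset:
    out = frozenset()
    for leaf, _ in t.leaves():
        if not leaf.is_lower_copy:
            out = out | leaf.item.features
    return out


# ---------------------------------------------------------------------
# movement paths
# ---------------------------------------------------------------------

def movement_path(t: SyntacticObject, copy_index: int) -> tuple:
    """Occurrence addresses of mover ``copy_index``, base site first.

    Ordered from the most deeply embedded occurrence (the initially
    merged position) through intermediate landing sites to the terminal
    landing site.  Raises if the element occurs fewer than twice.
    """
    sites = [
        addr for node, addr in t.walk() if node.copy_index == copy_index
    ]
    if len(sites) < 2:
        raise ValueError(
            f"copy index {copy_index} occurs {len(sites)} time(s); "
            "a movement path needs at least two occurrences"
        )
    sites.sort(key=lambda a: (-len(a.path), a.path))
    return tuple(sites)
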