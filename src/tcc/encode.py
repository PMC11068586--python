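"""Serializers from syntactic structure to the scored symbol sequences.

Four encoders, one per empirical domain:

* ``node_terminal`` — top-to-bottom (pre-order, left before right)
  enumeration of every node label and terminal element of a tree;
* ``search_path`` — the probe-to-goal search trace; by default one
  symbol per traversed labeled node, with the calibrated ``step_pairs``
  variant emitting each node *step* as its (source, target) label pair;
* ``movement_path`` — one symbol per landing site of a moved element,
  base site first;
* ``label_sequence`` — the left-to-right sequence of phrase labels of
  the overt constituent chunks (silent heads contribute nothing; copy
  sites contribute per the copy policy).

All encoders are deterministic: identical tree + config -> identical
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .complexity import SymbolSequence, binarize_sequence
from .search import SearchResult
from .syntree import SyntacticObject, TreeAddress

__all__ = [
    "EncodingConfig",
    "encode_node_terminal",
    "encode_search_path",
    "encode_movement_path",
    "encode_label_sequence",
    "encode",
]

MODES = ("node_terminal", "search_path", "movement_path", "label_sequence")
SYMBOL_POLICIES = ("per_distinct_label", "per_category", "per_site_category")
COPY_POLICIES = ("same_symbol_as_antecedent", "distinct_symbol")

#: Marker emitted for unlabeled nodes in node_terminal mode.
UNLABELED_MARK = "·"


@dataclass(frozen=True)
class EncodingConfig:
    mode: str = "node_terminal"
    symbol_policy: str = "per_category"
    copy_policy: str = "same_symbol_as_antecedent"
    binarize: bool = False
    #: calibrated search-path variant: emit (source, target) per step
    step_pairs: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.symbol_policy not in SYMBOL_POLICIES:
            raise ValueError(f"unknown symbol policy {self.symbol_policy!r}")
        if self.copy_policy not in COPY_POLICIES:
            raise ValueError(f"unknown copy policy {self.copy_policy!r}")


def _finish(symbols, provenance: str, config: EncodingConfig) -> SymbolSequence:
    seq = SymbolSequence(tuple(symbols), provenance=provenance)
    if config.binarize:
        return binarize_sequence(seq)
    return seq


def _leaf_symbol(node: SyntacticObject, config: EncodingConfig) -> Optional[str]:
    cat = node.item.category
    if node.is_lower_copy:
        if config.copy_policy == "same_symbol_as_antecedent":
            return cat
        return f"<{cat}>"
    return node.item.form if node.item.form is not None else cat


def encode_node_terminal(
    t: SyntacticObject, config: EncodingConfig = EncodingConfig()
) -> SymbolSequence:
    """Pre-order enumeration of node labels and terminal elements.

    Branch labels come first (parent before children), terminals appear
    in surface order; unlabeled nodes contribute the category-less
    marker.  For the adjunction structure ``[α λ [α β [γ δ ε]]]`` this
    yields exactly ``α λ α β γ δ ε``.
    """
    symbols = []
    for node, _ in t.walk():
        if node.is_leaf:
            symbols.append(_leaf_symbol(node, config))
        else:
            symbols.append(node.label if node.label is not None else UNLABELED_MARK)
    return _finish(symbols, "node_terminal", config)


def encode_search_path(
    result: SearchResult, config: EncodingConfig = EncodingConfig(mode="search_path")
) -> SymbolSequence:
    """Serialize a probe-to-goal search trace.

    Plain form: one symbol per traversed labeled node (``CP TP T' V``).
    With ``step_pairs`` (the calibrated scoring form), each of the
    search's node steps contributes the pair of labels it connects:
    ``CP TP · TP T' · T' V``.
    """
    if result.goal is None or not result.path_labels:
        raise ValueError("cannot encode a search without a goal")
    labels = list(result.path_labels)
    if config.symbol_policy == "per_distinct_label":
        seen: dict = {}
        distinct = []
        for lab in labels:
            seen[lab] = seen.get(lab, -1) + 1
            distinct.append(f"{lab}.{seen[lab]}")
        labels = distinct
    if config.step_pairs:
        symbols = []
        for a, b in zip(labels, labels[1:]):
            symbols.extend((a, b))
    else:
        symbols = labels
    return _finish(symbols, "search_path", config)


def _site_symbol(t: SyntacticObject, site: TreeAddress) -> str:
    """Category of the node dominating a landing site; an unlabeled
    bar-level projects its head's category, marked with a bar tick."""
    if not site.path:
        node = t.at(site)
        return node.category or UNLABELED_MARK
    parent = t.at(TreeAddress(site.path[:-1]))
    if parent.category is not None:
        return parent.category
    head = parent.left
    while head is not None and head.category is None:
        head = head.left
    return (head.category if head is not None else UNLABELED_MARK) + "'"


def encode_movement_path(
    path: Sequence[TreeAddress],
    t: SyntacticObject,
    config: EncodingConfig = EncodingConfig(mode="movement_path"),
) -> SymbolSequence:
    """One symbol per movement site, base site first.

    Under ``per_site_category`` each site is represented by the
    category of its dominating node; under ``per_distinct_label`` every
    site gets a unique symbol; a same-symbol policy collapses all sites
    of the one mover to a single symbol.
    """
    sites = list(path)
    if len(sites) < 2:
        raise ValueError("a movement path needs at least two sites")
    if config.symbol_policy == "per_distinct_label":
        symbols = [f"site{i}" for i in range(len(sites))]
    else:
        symbols = [_site_symbol(t, s) for s in sites]
    return _finish(symbols, "movement_path", config)


def encode_label_sequence(
    t: SyntacticObject, config: EncodingConfig = EncodingConfig(mode="label_sequence")
) -> SymbolSequence:
    """Left-to-right phrase labels of the overt constituent chunks.

    Every overt leaf contributes the category label of the phrase it
    projects; silent heads and unlabeled adjunction nodes contribute no
    symbol.  Copy sites contribute their antecedent's category under
    the default copy policy (a copy is the same object), or a bracketed
    distinct symbol; this keeps derived positions visible to the
    interpretive enumeration while lower copies stay invisible to
    labeling itself.
    """
    symbols = []
    for node, _ in t.walk():
        if not node.is_leaf:
            continue
        if node.is_lower_copy:
            if config.copy_policy == "same_symbol_as_antecedent":
                symbols.append(node.item.category)
            else:
                symbols.append(f"<{node.item.category}>")
        elif node.item.form is not None or node.copy_index is not None:
            symbols.append(node.item.category)
    if not symbols:
        raise ValueError("structure has no overt labeled material")
    return _finish(symbols, "label_sequence", config)


def encode(obj, config: EncodingConfig, tree: Optional[SyntacticObject] = None):
    """Dispatch on ``config.mode``."""
    if config.mode == "node_terminal":
        return encode_node_terminal(obj, config)
    if config.mode == "search_path":
        return encode_search_path(obj, config)
    if config.mode == "movement_path":
        return encode_movement_path(obj, tree, config)
    return encode_label_sequence(obj, config)
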