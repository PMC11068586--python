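"""MERGE engine and the economy-condition checkers."""

import pytest

from tcc.derivation import (
    DerivationError,
    DerivationStep,
    Workspace,
    accessible_terms,
    check_no_tampering,
    check_resource_restriction,
    enumerate_derivations,
    markov_check,
    merge_external,
    merge_internal,
    run_script,
    successor_operations,
    workspace_size,
)
from tcc.fixtures import structure
from tcc.syntree import (
    LexicalItem,
    SyntacticObject,
    TreeAddress,
    write_bracketed,
)


def leaf(cat):
    return SyntacticObject.leaf(LexicalItem(category=cat))


@pytest.fixture
def xy_workspace():
    return Workspace(roots=(leaf("X"), leaf("Y")))


class TestExternalMerge:
    def test_forms_z_x_y(self, xy_workspace):
        step1 = merge_external(xy_workspace, 0, 1)
        (xy,) = step1.after.roots
        assert write_bracketed(xy) == "[_ [X] [Y]]"
        step2 = merge_external(step1.after, LexicalItem(category="Z"), 0)
        (zxy,) = step2.after.roots
        assert write_bracketed(zxy) == "[_ [Z] [_ [X] [Y]]]"

    def test_two_single_roots_merge_to_three_nodes(self, xy_workspace):
        step = merge_external(xy_workspace, 0, 1)
        assert sum(1 for _ in step.after.roots[0].walk()) == 3

    def test_adjunction_derives_licensed_structure(self):
        ws = Workspace(roots=(structure("2a"),))
        step = merge_external(ws, LexicalItem(category="λ"), 0, label="α")
        assert write_bracketed(step.after.roots[0]) == write_bracketed(
            structure("2b")
        )

    def test_missing_root_rejected(self, xy_workspace):
        with pytest.raises(DerivationError):
            merge_external(xy_workspace, 0, 5)


class TestInternalMerge:
    def test_forms_x_x_y(self, xy_workspace):
        merged = merge_external(xy_workspace, 0, 1).after
        step = merge_internal(merged, 0, TreeAddress(("L",)))
        root = step.after.roots[0]
        assert root.left.copy_index == 1 and not root.left.is_lower_copy
        assert root.right.left.is_lower_copy
        assert root.right.left.copy_index == 1

    def test_self_merge_excluded(self, xy_workspace):
        merged = merge_external(xy_workspace, 0, 1).after
        with pytest.raises(DerivationError):
            merge_internal(merged, 0, TreeAddress())

    def test_raising_geometry(self):
        # moving the subject chunk from the alpha position to the root
        # reproduces the raising-structure geometry: highest copy overt,
        # lower copy silent, category shared
        t13a = structure("13a")
        ws = Workspace(roots=(t13a,))
        subject = TreeAddress(("R", "L"))
        step = merge_internal(ws, 0, subject, label="δ", copy_index=9)
        root = step.after.roots[0]
        assert root.label == "δ"
        assert root.left.copy_index == 9
        assert root.left.item.form == "the student"
        lower = root.right.at(subject)
        assert lower.is_lower_copy and lower.item.category == "D"


class TestNoTampering:
    def test_extension_passes(self):
        ws = Workspace(roots=(structure("2a"),))
        step = merge_external(ws, LexicalItem(category="λ"), 0, label="α")
        assert check_no_tampering(step)

    def test_counter_cyclic_modification_violates(self):
        tampered = DerivationStep(
            "external_merge",
            (),
            Workspace(roots=(structure("2a"),)),
            Workspace(roots=(structure("2c"),)),
        )
        result = check_no_tampering(tampered)
        assert not result
        assert result.witness is not None

    def test_identity_step_passes(self, xy_workspace):
        step = DerivationStep("external_merge", (), xy_workspace, xy_workspace)
        assert check_no_tampering(step)

    def test_engine_outputs_never_tamper(self, small_lexicon):
        for steps in enumerate_derivations(small_lexicon, 3):
            if steps:
                assert check_no_tampering(steps[-1])


class TestResourceRestriction:
    def test_empty_workspace_size_zero(self):
        assert workspace_size(Workspace()) == 0

    def test_xy_counts(self, xy_workspace):
        merged = merge_external(xy_workspace, 0, 1).after
        assert accessible_terms(merged) == 3  # X, Y, {X,Y}
        assert workspace_size(merged) == 4
        assert workspace_size(merged, count_roots_in_terms=False) == 3

    def test_fresh_item_merge_passes(self, xy_workspace):
        step = merge_external(xy_workspace, LexicalItem(category="Z"), 0)
        assert check_resource_restriction(step)

    def test_duplication_violates(self, xy_workspace):
        doubled = Workspace(
            roots=xy_workspace.roots + (leaf("P"), leaf("Q"))
        )
        step = DerivationStep("external_merge", (), xy_workspace, doubled)
        result = check_resource_restriction(step)
        assert not result and "2" in result.witness

    def test_internal_merge_counts_copies_once(self, xy_workspace):
        merged = merge_external(xy_workspace, 0, 1).after
        step = merge_internal(merged, 0, TreeAddress(("L",)))
        assert check_resource_restriction(step)
        assert accessible_terms(step.after) == accessible_terms(merged) + 1


class TestMarkov:
    def test_commuting_merges_reach_same_workspace(self):
        lex = tuple(LexicalItem(category=c) for c in "ABCD")
        seed = Workspace(roots=tuple(map(SyntacticObject.leaf, lex)))
        ab_first = [merge_external(seed, 0, 1)]
        ab_first.append(merge_external(ab_first[-1].after, 1, 2))
        cd_first = [merge_external(seed, 2, 3)]
        cd_first.append(merge_external(cd_first[-1].after, 0, 1))
        assert ab_first[-1].after == cd_first[-1].after
        assert markov_check(ab_first, cd_first)

    def test_unequal_workspaces_rejected(self, xy_workspace):
        a = [merge_external(xy_workspace, 0, 1)]
        b = [merge_external(xy_workspace, 1, 0)]
        with pytest.raises(DerivationError):
            markov_check(a, b)

    def test_coincident_workspaces_in_enumeration(self, small_lexicon):
        by_ws = {}
        for steps in enumerate_derivations(small_lexicon, 4):
            if steps:
                by_ws.setdefault(steps[-1].after, []).append(steps)
        for histories in by_ws.values():
            first = successor_operations(histories[0][-1].after)
            for other in histories[1:]:
                assert markov_check(histories[0], other)
                assert successor_operations(other[-1].after) == first


class TestScripts:
    SCRIPT = """
    # build {Z, {X, Y}} then re-merge X at the edge
    EM X -1
    EM Y 0 V
    EM Z 0 v
    IM 0 RL v
    """

    def test_replay_is_deterministic(self, small_lexicon):
        a = run_script(self.SCRIPT, small_lexicon)
        b = run_script(self.SCRIPT, small_lexicon)
        assert [write_bracketed(r) for r in a[-1].after.roots] == [
            write_bracketed(r) for r in b[-1].after.roots
        ]
        assert a[-1].after.roots[0].left.copy_index is not None

    def test_unknown_operation_rejected(self, small_lexicon):
        with pytest.raises(DerivationError):
            run_script("XM X 0", small_lexicon)
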