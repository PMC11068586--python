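"""Minimal search, step/depth counting, Relativised Minimality, labeling."""

import pytest

from tcc.fixtures import goal_6b_embedded, probe_6b, structure
from tcc.search import (
    Probe,
    label_of,
    minimal_search,
    movement_path,
    rm_check,
    search_depth,
    search_to,
)
from tcc.syntree import (
    LexicalItem,
    SyntacticObject,
    TreeAddress,
    features,
    node_count,
    parse_bracketed,
)

from conftest import random_tree


class TestMinimalSearch:
    def test_probe_finds_matrix_verb_three_steps(self):
        t = structure("6b")
        result = minimal_search(t, probe_6b())
        assert result.goal == TreeAddress(("R", "R", "R"))
        assert result.path_labels == ("CP", "TP", "T'", "V")
        assert result.steps == 3

    def test_forced_embedded_goal_four_steps(self):
        t = structure("6b")
        result = search_to(t, TreeAddress(), goal_6b_embedded())
        assert result.path_labels == ("CP", "TP", "DP", "CP", "TP")
        assert result.steps == 4

    def test_no_match_exhausts_domain(self):
        t = parse_bracketed("[α [β x] [γ y]]")
        probe = Probe(origin=TreeAddress(), sought=features("Q"))
        result = minimal_search(t, probe)
        assert result.goal is None
        assert result.nodes_exhausted == 2

    def test_leaf_probe_searches_nothing(self):
        t = parse_bracketed("[N dog]")
        result = minimal_search(
            t, Probe(origin=TreeAddress(), sought=features("Q"))
        )
        assert result.goal is None and result.nodes_exhausted == 0

    def test_goal_is_least_embedded_match(self, rng):
        # exhaustive over all feature-matching nodes on decorated trees
        import random

        checked = 0
        while checked < 60:
            t = random_tree(rng)
            if node_count(t) > 15 or t.is_leaf:
                continue
            decorated = _decorate(t, rng)
            probe = Probe(origin=TreeAddress(), sought=features("F"))
            result = minimal_search(decorated, probe)
            matches = [
                addr
                for node, addr in decorated.walk()
                if addr.path
                and node.is_leaf
                and features("F") <= node.item.features
            ]
            checked += 1
            if not matches:
                assert result.goal is None
                continue
            best = min(len(a.path) for a in matches)
            assert len(result.goal.path) == best
            for tie in result.ties:
                assert len(tie.path) == best

    def test_equally_shallow_goals_returned_as_ties(self):
        t = parse_bracketed("[α [D x +F] [D y +F]]")
        result = minimal_search(
            t, Probe(origin=TreeAddress(), sought=features("F"))
        )
        assert result.goal == TreeAddress(("L",))
        assert result.ties == (TreeAddress(("R",)),)


def _decorate(t, rng):
    if t.is_leaf:
        feats = features("F") if rng.random() < 0.3 else frozenset()
        return SyntacticObject.leaf(
            LexicalItem(t.item.category, t.item.form, feats),
            t.copy_index,
            t.is_lower_copy,
        )
    return SyntacticObject.branch(
        _decorate(t.left, rng), _decorate(t.right, rng), t.label
    )


class TestSearchDepth:
    def test_long_extraction_depth_eleven(self):
        t = structure("9a")
        base = movement_path(t, 1)[0]
        assert search_depth(t, TreeAddress(), base) == 11

    def test_short_extraction_depth_nine(self):
        t = structure("9b")
        base = movement_path(t, 1)[0]
        assert search_depth(t, TreeAddress(), base) == 9

    def test_goal_at_origin_is_zero(self):
        t = structure("9a")
        assert search_depth(t, TreeAddress(), TreeAddress()) == 0


class TestRelativisedMinimality:
    def probe(self):
        return Probe(origin=TreeAddress(("R", "L")), sought=features("Q"))

    def base(self, t):
        return next(
            addr for node, addr in t.walk() if node.is_lower_copy
        )

    def test_feature_superset_intervener_blocks(self):
        t = structure("3a")
        verdict = rm_check(t, self.probe(), self.base(t))
        assert not verdict
        intervener = t.at(verdict.intervener)
        assert intervener.item.form == "which game"

    def test_featurally_poorer_intervener_does_not_block(self):
        t = structure("3b")
        assert rm_check(t, self.probe(), self.base(t))

    def test_no_intervener_licensed(self):
        t = parse_bracketed(
            "[_ [C do +Q] [_ [V see] [D~1 what +Q]]]"
        )
        probe = Probe(origin=TreeAddress(("L",)), sought=features("Q"))
        assert rm_check(t, probe, TreeAddress(("R", "R")))

    def test_monotone_in_intervener_features(self):
        # enriching the intervener never converts blocked -> licensed
        blocked = structure("3a")
        richer = parse_bracketed(
            structure_text_with_extra_feature()
        )
        p = self.probe()
        assert not rm_check(blocked, p, self.base(blocked))
        assert not rm_check(richer, p, self.base(richer))


def structure_text_with_extra_feature():
    from tcc.fixtures import STRUCTURES

    return STRUCTURES["3a"].replace("+Q +N", "+Q +N +Focus")


class TestLabeling:
    def test_head_phrase_labels_as_head(self):
        t = parse_bracketed("[_ [Z z] [_ [X x] [Y y]]]")
        assert label_of(t) == "Z"

    def test_head_complement_pair_labeled_at_once(self):
        t = parse_bracketed("[_ [V see] [D it]]")
        assert label_of(t) == "V"

    def test_lower_copy_invisible(self):
        # {XP, YP} where XP is a lower copy labels from YP
        t13b = structure("13b")
        alpha = t13b.at(TreeAddress(("R", "R")))
        assert alpha.left.is_lower_copy
        assert label_of(alpha) == "P"

    def test_two_phrases_shared_feature(self):
        t = parse_bracketed(
            "[_ [_ [D who +Q] [D x]] [_ [C +Q] [V go]]]"
        )
        assert label_of(t) == "Q"

    def test_two_phrases_no_shared_feature_unlabeled(self):
        t = parse_bracketed("[_ [_ [D a] [N b]] [_ [P c] [V d]]]")
        assert label_of(t) is None


class TestMovementPath:
    def test_long_extraction_has_six_sites(self):
        t = structure("9a")
        path = movement_path(t, 1)
        assert len(path) == 6
        depths = [len(a.path) for a in path]
        assert depths == sorted(depths, reverse=True)  # base first
        assert path[-1] == TreeAddress(("L",))  # terminal site: Spec-CP

    def test_short_extraction_has_four_sites(self):
        t = structure("9b")
        assert len(movement_path(t, 1)) == 4

    def test_unmoved_element_rejected(self):
        t = parse_bracketed("[_ [D~3 it] [V go]]")
        with pytest.raises(ValueError):
            movement_path(t, 3)
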