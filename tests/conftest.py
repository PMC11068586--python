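import random

import pytest

from tcc.syntree import LexicalItem, SyntacticObject

CATEGORIES = ("C", "T", "v", "V", "N", "D", "P", "A")
FORMS = ("ka", "mo", "ri", "su", "ten", None)


def random_tree(rng: random.Random, max_depth: int = 4) -> SyntacticObject:
    if max_depth == 0 or rng.random() < 0.35:
        item = LexicalItem(
            category=rng.choice(CATEGORIES), form=rng.choice(FORMS)
        )
        return SyntacticObject.leaf(item)
    label = rng.choice(CATEGORIES + (None, None))
    return SyntacticObject.branch(
        random_tree(rng, max_depth - 1),
        random_tree(rng, max_depth - 1),
        label=label,
    )


@pytest.fixture
def rng():
    return random.Random(20260923)


@pytest.fixture
def small_lexicon():
    return [LexicalItem(category=c) for c in ("X", "Y", "Z")]
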