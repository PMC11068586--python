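"""Worked-example structures, transliterated once into the canonical dialect.

Each structure a claim is evaluated on ships here as a labeled-bracket
string, together with the probes, goals and encoder configurations the
calibration selected (``docs/methods.md`` records the conventions and
their rationale).  Transliteration notes:

* Greek-letter schematic structures keep their Greek labels as the
  category inventory.
* Bar-level projections of C and V are unlabeled nodes (category
  projected from the head); T' is labeled, as in the printed
  interrogative structure.
* In the ungrammatical long-movement structure the fronted object
  originates inside the infinitival complement and its path includes
  the two phase-edge landing sites (embedded VP and CP) that
  successive-cyclic movement requires from there; the grammatical
  counterpart's higher origin needs no extra sites.
* The raising structures are coarse: each overt chunk ("seems to be
  likely", "the student", "to", "understand the theory") is one leaf,
  so the label sequence is the phrase-label enumeration V-D-P-V plus
  copy sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .complexity import CalibrationPair, SymbolSequence
from .encode import EncodingConfig, encode_label_sequence, encode_movement_path, \
    encode_node_terminal, encode_search_path
from .search import Probe, movement_path, search_to
from .syntree import TreeAddress, features, parse_bracketed

__all__ = [
    "STRUCTURES",
    "ANNOTATIONS",
    "structure",
    "calibration_pairs",
    "contrast_sequences",
    "PRINTED_VALUES",
]

STRUCTURES: Mapping[str, str] = {
    # -- adjunction vs counter-cyclic modification (schematic) --------
    "2a": "[α [β] [γ [δ] [ε]]]",
    "2b": "[α [λ] [α [β] [γ [δ] [ε]]]]",
    "2c": "[α [β] [γ [δ] [ε [ε] [λ]]]]",
    # -- Relativised Minimality pair ----------------------------------
    "3a": (
        '[_ [DP~1 how +Q] [_ [C do +Q] [_ [V wonder] '
        '[_ [DP "which game" +Q +N] [_ [C +Q] [_ [V play] [<DP~1> +Q]]]]]]]'
    ),
    "3b": (
        '[_ [DP~1 "which game" +Q +N] [_ [C do +Q] [_ [V wonder] '
        '[_ [DP how +Q] [_ [C +Q] [_ [V play] [<DP~1> +Q +N]]]]]]]'
    ),
    # -- polar interrogative with relative clause ---------------------
    "6b": (
        "[CP [C Do] [TP [DP [DP poems] [CP [C that] [TP rhyme +V]]] "
        "[T' [T] [V evaporate +V]]]]"
    ),
    # -- wh-extraction pair (copy theory) -----------------------------
    "9a": (
        "[CP [DP~1 what] [_ [C did] [TP [DP you] [T' [T pres] "
        "[VP [<DP~1>] [_ [V persuade] [CP [<DP~1>] [_ [C] [TP [<DP~1>] "
        "[T' [T] [VP [DP who] [PP [P to] [VP [<DP~1>] "
        "[_ [V sell] [<DP~1>]]]]]]]]]]]]]]]"
    ),
    "9b": (
        "[CP [DP~1 who] [_ [C did] [TP [DP you] [T' [T pres] "
        "[VP [<DP~1>] [_ [V persuade] [CP [C] [TP [<DP~1>] "
        "[T' [T] [VP [<DP~1>] [PP [P to] [VP [V sell] [DP what]]]]]]]]]]]]]"
    ),
    # -- raising / labeling pair --------------------------------------
    "13a": (
        '[γ [V "seems to be likely"] [α [D~1 "the student"] '
        '[_ [P to] [_ [<D~1>] [V "understand the theory"]]]]]'
    ),
    "13b": (
        '[δ [D~1 "the student"] [γ [V "seems to be likely"] '
        '[α [<D~1>] [_ [P to] [_ [<D~1>] [V "understand the theory"]]]]]]'
    ),
    # -- Bulgarian multiple wh-fronting (schematic clause structures) --
    "10": "[CP [C +Q] [TP [D koj +Q] [_ [V vidjal] [D kogo +Q]]]]",
    "11": "[CP [C +Q] [TP [D Ivan] [_ [D kogo +Q] [_ [V pital] [D kakvo +Q]]]]]",
    "12": "[CP [C +Q] [TP [D koj +Q] [_ [V pital] [_ [D kogo +Q] [D kakvo +Q]]]]]",
}

#: Grammaticality annotations for the contrast pairs (testing only).
ANNOTATIONS: Mapping[str, bool] = {
    "2b": True, "2c": False,
    "3a": False, "3b": True,
    "9a": False, "9b": True,
    "13a": False, "13b": True,
}

#: The printed complexity values the calibration grid is scored against.
PRINTED_VALUES: Mapping[str, float] = {
    "2b": 1.88, "2c": 1.99,
    "6b_CV": 1.72, "6b_CTP": 2.01,
    "9a": 2.15, "9b": 1.5,
    "13a": 1.86, "13b": 1.66,
}


def structure(name: str):
    try:
        return parse_bracketed(STRUCTURES[name])
    except KeyError:
        raise KeyError(f"unknown fixture structure {name!r}") from None


# calibrated encoder configurations, one per mode
CONFIGS: Mapping[str, EncodingConfig] = {
    "node_terminal": EncodingConfig(mode="node_terminal", binarize=True),
    "search_path": EncodingConfig(mode="search_path", step_pairs=True),
    "movement_path": EncodingConfig(mode="movement_path",
                                    symbol_policy="per_site_category"),
    "label_sequence": EncodingConfig(mode="label_sequence"),
}


def probe_6b() -> Probe:
    """The interrogative C probe searching for a verbal goal."""
    return Probe(origin=TreeAddress(), sought=features("V"))


def goal_6b_embedded() -> TreeAddress:
    """Address of the embedded TP 'rhyme' (the forced, illicit goal)."""
    return TreeAddress(("R", "L", "R", "R"))


def contrast_sequences(variant: str = "calibrated") -> Mapping[str, SymbolSequence]:
    """The eight scored sequences of the four worked contrasts.

    ``variant`` selects the encoder convention family; ``calibrated``
    is the shipped default, ``plain`` disables the node-terminal
    binarization and the search step-pair emission (retained so the
    calibration grid can compare them).
    """
    if variant == "calibrated":
        nt_cfg = CONFIGS["node_terminal"]
        sp_cfg = CONFIGS["search_path"]
    elif variant == "plain":
        nt_cfg = EncodingConfig(mode="node_terminal", binarize=False)
        sp_cfg = EncodingConfig(mode="search_path", step_pairs=False)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    t6 = structure("6b")
    res_cv = search_to(t6, TreeAddress(), TreeAddress(("R", "R", "R")))
    res_ctp = search_to(t6, TreeAddress(), goal_6b_embedded())
    t9a, t9b = structure("9a"), structure("9b")
    return {
        "2b": encode_node_terminal(structure("2b"), nt_cfg),
        "2c": encode_node_terminal(structure("2c"), nt_cfg),
        "6b_CV": encode_search_path(res_cv, sp_cfg),
        "6b_CTP": encode_search_path(res_ctp, sp_cfg),
        "9a": encode_movement_path(movement_path(t9a, 1), t9a,
                                   CONFIGS["movement_path"]),
        "9b": encode_movement_path(movement_path(t9b, 1), t9b,
                                   CONFIGS["movement_path"]),
        "13a": encode_label_sequence(structure("13a"), CONFIGS["label_sequence"]),
        "13b": encode_label_sequence(structure("13b"), CONFIGS["label_sequence"]),
    }


_CONTRASTS = {
    "2b": ("adjunction", True), "2c": ("adjunction", False),
    "6b_CV": ("search", True), "6b_CTP": ("search", False),
    "9a": ("movement", False), "9b": ("movement", True),
    "13a": ("labeling", False), "13b": ("labeling", True),
}


def calibration_pairs() -> list:
    """Calibration input: per printed value, the candidate sequences of
    each encoding-convention variant."""
    by_variant = {v: contrast_sequences(v) for v in ("calibrated", "plain")}
    pairs = []
    for key, target in PRINTED_VALUES.items():
        contrast, gram = _CONTRASTS[key]
        pairs.append(
            CalibrationPair(
                name=key,
                candidates={v: by_variant[v][key] for v in by_variant},
                target=target,
                grammatical=gram,
                contrast=contrast,
            )
        )
    return pairs
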