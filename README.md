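# tcc-syntax

Scoring minimalist syntactic derivations by algorithmic compressibility.

## The problem

Generative syntax explains grammaticality contrasts with *economy
conditions*: minimal search (a probe relates to the least-embedded
matching goal), Relativised Minimality (an intervener carrying a
feature superset blocks the relation), the No Tampering Condition
(MERGE never rewrites previously built structure), and Resource
Restriction (each MERGE step adds at most one accessible element).
These conditions can be given a common quantitative reading: encode the
relevant aspect of a derivation — the structure's node-and-terminal
enumeration, a probe-goal search trace, a movement path, a phrase-label
sequence — as a finite symbol string, and estimate its Kolmogorov
complexity.  The **Turing–Chomsky Compression (TCC)** principle says
that among competing operations on a shared workspace, the option whose
resulting encoding compresses to lower complexity is the grammatically
licensed one; exact ties are jointly licensed.

Since Kolmogorov complexity K(x) = min{|p| : M(p) = x} is not
computable, the package uses the Lempel–Ziv (1976) phrase count c(n) as
the standard effective proxy: scanning a sequence S = s₁s₂…sₙ left to
right, c(n) counts the phrases of the exhaustive history (each phrase
ends at the first substring not previously encountered).  The shipped
normalization is the Kaspar–Schuster rate

    C(S) = c(n) · log₂(n) / n,

selected by a calibration grid over an explicit scheme family (three
formulas × two log bases × optional fixed-width binarization); every
result records the scheme that produced it.

The package is for computational linguists and cognitive scientists who
want to reproduce, probe, or extend compression-based grammaticality
predictions on small, fully explicit derivations.

## What's inside

| module | contents |
| --- | --- |
| `tcc.syntree` | binary bare-phrase-structure trees, labeled-bracket I/O, dominance / c-command / depth |
| `tcc.derivation` | MERGE engine (external + copy-theoretic internal), No Tampering, Resource Restriction, Markov property, derivation scripts |
| `tcc.search` | minimal search, step/depth counting, Relativised Minimality, labeling, movement-path extraction |
| `tcc.encode` | the four structure-to-sequence serializers |
| `tcc.complexity` | LZ76 phrase count, brute-force oracle, normalization schemes, calibration grid |
| `tcc.compare` | the TCC comparator, multiple-wh-fronting prediction, MERGE-closure enumeration, worked-example fixtures |
| `tcc.cli` | `tcc complexity / compare / fixtures / calibrate / enumerate` |

## Worked example

The classic extraction asymmetry: questioning the deeply embedded
object (`*What did you persuade who to sell?`) versus the higher
argument (`Who did you persuade to sell what?`).  Both structures ship
as fixtures with their movement paths marked by indexed copies:

```python
>>> from tcc.compare import run_fixture
>>> outcome = run_fixture("ex9_movement")
>>> for cid, r in sorted(outcome.report.results.items()):
...     print(cid, r.phrase_count, r.length, round(r.normalized, 3))
9a 5 6 2.154
9b 3 4 1.5
>>> sorted(outcome.licensed)
['9b']
```

The illicit long extraction needs six landing sites (base, embedded VP
and CP phase edges, embedded TP, matrix VP, Spec-CP); its site-category
sequence `V' VP TP CP VP CP` parses into 5 LZ phrases over 6 symbols,
normalized complexity **2.154**.  The licit extraction's path `VP TP VP
CP` parses into 3 phrases over 4 symbols, complexity **1.5** — lower,
so it is the licensed option, matching the acceptability judgment.  The
same trees give root-to-base search depths of 11 vs 9 labeled nodes.

All eight shipped contrasts behave this way:

```sh
$ tcc fixtures
fixture         status  licensed        expected
ex2_tamper      pass    ['2b']          ['2b']
ex3_rm          pass    ['3b']          ['3b']
ex6_search      pass    ['6b_CV']       ['6b_CV']
ex9_movement    pass    ['9b']          ['9b']
ex13_labeling   pass    ['13b']         ['13b']
ex10_wh         pass    ["('koj', 'kogo')"]     ...
```

`ex13_labeling` is the stringent case: the *licensed* structure is the
larger tree by node count, and only the compression rate separates the
pair.  The Bulgarian fixtures (`ex10`–`ex12`) check that with multiple
fronted wh-phrases the structurally highest must move first and equally
embedded movers are licensed in either order (their movement encodings
tie exactly).

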