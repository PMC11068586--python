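# Methods

This note records the model, the measurement conventions, and the
design decisions behind them — in particular where a published figure
under-determines its own computation and a convention had to be fixed
by calibration.

## Model and assumptions

Syntactic objects are strictly binary trees over lexical leaves
(category, optional overt form, formal features).  MERGE is the only
structure-builder: external MERGE forms {Z, {X, Y}} from a lexical item
or another root; internal MERGE re-merges a subterm at the root's edge,
leaving an unpronounced lower copy that shares a copy index with its
antecedent (copy theory of movement).  The engine is persistent — no
operation mutates its input — so No Tampering holds by construction for
engine output, and the checker re-verifies it for arbitrary steps by
comparing subtree multisets modulo copy expansion (a lower copy stands
for the very object it copies).

Resource accounting follows the workspace-size proposal: size =
accessible terms + number of root objects, with the root counted in
both (the alternative convention sits behind
`workspace_size(..., count_roots_in_terms=False)`).  Lower copies do
not add to the accessible count — recursion here removes previously
manipulated material from further computation, which is also what makes
derivations Markovian: `markov_check` makes the property explicit by
comparing legal-successor sets of coincident workspaces.  External
merge of a fresh item is modeled as selection-into-workspace followed
by MERGE, so each MERGE step proper adds exactly one accessible element
(the new set node).  Phase-based opacity (the Phase Impenetrability
Condition) is *not* operationalized: all subterms are accessible.  This
is a known extension point.

Minimal search is breadth-first by embedding depth, left child before
right at equal depth; equally shallow goals are returned as ties, which
the comparator treats as jointly licensed.  Relativised Minimality:
Z blocks a probe-goal relation iff Z lies between them (c-commanded by
the probe, c-commanding the goal) and Z's features contain both the
probe's sought set and the goal's features — so a feature-superset
intervener blocks a poorer mover but not vice versa, and the check is
monotone in Z's features.  Labeling: {head, phrase} labels as the head;
{phrase, phrase} labels by a uniquely shared feature or not at all;
lower copies are invisible to labeling.

## Complexity estimation

`lz76_phrase_count` implements the exhaustive-history LZ76 parse:
scanning left to right, a phrase ends at the first substring that has
not occurred starting at any earlier position (occurrences may overlap
the phrase).  Conventions fixed because published variants differ:

* the final phrase counts even when it has been seen before
  (a constant sequence of length ≥ 2 has c = 2);
* phrases include their terminating novel symbol
  (`a b a b c a b d` parses `a | b | abc | abd`, c = 4).

A brute-force oracle (explicit substring-set enumeration, capped at
length 12) independently recomputes the count; the suite checks
equality exhaustively for all binary strings of length ≤ 9 and ternary
strings of length ≤ 7, plus 10,000 seeded random strings.

Normalization is searched over an explicit finite family: formulas
{c·log(n)/n, c/(n/log n), raw c} × log bases {2, alphabet size} ×
optional binarization (symbols recoded to 0-padded fixed-width binary
by first-appearance index).  The shipped default is the calibration
winner, c·log₂(n)/n without pre-binarization, and every
`ComplexityResult` records its scheme id.  LZ estimates on sequences
shorter than 10 symbols are noisy; the library warns rather than
refuses, because the worked syntactic examples are all short — which is
precisely why the *orderings* between competing encodings, not the
absolute values, are the load-bearing empirical surface.

## Calibration: what is fixed, and why

The published analyses print normalized complexities for four contrasts
(adjunction 1.88/1.99; interrogative search 1.72/2.01; wh-extraction
2.15/1.5; raising/labeling 1.86/1.66) and two integer counts (search
depths 11/9), but not the encoding conventions or normalization formula
behind them.  All eight printed values are consistent with
c·log₂(n)/n at small integer (c, n); `calibrate_scheme` grid-searches
scheme × encoding-convention combinations against them, preferring
configurations that reproduce every grammatical-below-ungrammatical
ordering and, among those, minimal total residual.  The calibrated
conventions, shipped as defaults:

* **node_terminal**: pre-order (parent first, left before right)
  enumeration of labels and terminals — exactly the printed
  `α λ α β γ δ ε` for the adjunction structure — scored after
  fixed-width binarization.
* **search_path**: each node step of the probe-goal descent contributes
  its (source, target) label pair: `CP TP · TP T' · T' V`.  The plain
  one-symbol-per-node form remains available (`step_pairs=False`).
* **movement_path**: one symbol per landing site, base first, each site
  represented by the category of its dominating node (bar-level
  parents project their head category: `V'`).
* **label_sequence**: left-to-right categories of the overt phrase
  chunks; silent heads contribute nothing; copy sites contribute their
  antecedent's category (derived positions stay visible to the
  interpretive enumeration even though lower copies are invisible to
  labeling itself).
* **step and depth counting**: search *steps* count labeled nodes
  entered (probe excluded, goal included) — 3 vs 4 on the interrogative
  structure; search *depth* counts labeled nodes on the root-to-goal
  path inclusive — 11 vs 9 on the extraction pair.  Bar-levels of C and
  V are unlabeled in the transliterations (they are not printed as
  independent projections in the source bracketings that fix the
  counts); T' is labeled.

Under these conventions the toolkit reproduces 1.72, 2.15, 1.5, 1.86
and both integer depths exactly.  Three printed values resist exact
reproduction under *any* member of the documented family:

* the adjunction pair (1.88/1.99): the printed 7-symbol enumerations of
  the two structures have identical LZ phrase counts, so no
  un-binarized symbol-level scheme can separate them at all, and the
  printed values imply sequence lengths (8 and 10) that no traversal of
  the printed structures yields.  The shipped binarized encoding
  restores the strict ordering (1.046 < 1.255) that the contrast
  requires, at the cost of the absolute values;
* the illicit search path (2.01 vs computed 1.875) and the raised
  structure's label sequence (1.66 vs computed 1.723): each printed
  value implies a (c, n) one symbol away from what the convention that
  reproduces its *partner* exactly yields.  Both orderings hold.

`tcc calibrate` prints the full residual table; the residuals are
reported, never absorbed.

## Fixture transliterations

Every worked structure ships once, in one canonical bracket dialect
(`[Label child child]`, `[Cat form]`, `[Cat]` silent, `[<Cat~i>]` lower
copy, `+F` features).  Two transliteration choices go beyond the
printed schematics:

* the illicit long-extraction structure includes the two
  successive-cyclic phase-edge copies (embedded VP and CP edges) that
  movement from the most deeply embedded complement position requires;
  the printed schematic omits them, but both the printed movement
  complexity (2.15) and the printed depth (11) presuppose them.  The
  licit extraction starts higher and its printed sites are used as-is;
* the raising pair is coarse-grained: each overt chunk ("seems to be
  likely", "the student", "to", "understand the theory") is one leaf,
  matching the V-D-P-V granularity of the published label enumeration.

The Greek-letter schematic structures keep Greek categories; the
schematic clause labels of the raising pair (δ, γ, α) label tree nodes
but are not phrase-category symbols, so they do not appear in label
sequences.  The Bulgarian multiple-wh clauses are schematic CP
structures whose lexical content is irrelevant: only the relative
embedding of the [+Q] phrases matters, and in the three-wh clause the
two object wh-phrases are represented at equal embedding (the
configuration in which their remaining paths have equal length, hence
equal complexity, hence joint licensing).

## Wh-order prediction

`predict_wh_order` licenses exactly the fronting orders in which every
wh-phrase fronts and each mover is among the least-embedded wh-phrases
remaining at its turn.  This derives highest-first for the two-wh
clauses and order freedom among the equally embedded non-initial movers
of the three-wh clause; the tie is corroborated by encoding the two
competing movements through the MERGE engine and checking their LZ
complexities are equal.

## MERGE-closure enumeration

`enumerate_merge_closure` counts distinct workspaces reachable per
MERGE step by exhaustive search with canonical de-duplication (objects
are unordered sets; workspaces are root multisets).  Unrestricted mode
permits root-root merge and internal/sideward merge with the source
material left in place, which is what makes the combinatorics explode;
restricted mode takes only Resource-Restriction-compliant steps.  The
implementation is exact but desk-scale: tests enumerate 4–6 steps (tens
of thousands of states, seconds of work); the documented cap returns a
truncated partial result instead of failing.  Combinatorial growth at
8 steps from two atoms reaches the millions; the suite checks growth
shape, not that headline figure, since the convention set behind it is
not fully specified.

## What the fixtures do and do not show

The worked structures are hand-transliterated schematics, not parsed
corpus material: lexical content is largely placeholder, bar-structure
is only as fine as the printed analyses require, and feature
inventories contain exactly the features the contrasts turn on.
Passing tests therefore show that the formal pipeline — MERGE, economy
checkers, encoders, LZ estimation — reproduces the published
quantitative contrasts under documented conventions.  They do not show
that the conventions generalize to arbitrary sentences, that LZ76 is
the right complexity estimator for long or non-i.i.d. derivational
sequences, or anything about processing or neural realization.

## Known limitations

* Two published absolute values (and one to within 0.06–0.14) are not
  reproduced; see the calibration section.
* No Agree/feature valuation, case, head movement, linearization,
  multidominance, or n-ary branching.
* Phase opacity is not enforced in accessibility.
* The comparator requires explicitly supplied candidates; it does not
  search derivation space.
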