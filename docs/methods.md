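# Methods

This note documents the models, parameter choices and numerical conventions
of `ddikernels`, and what the synthetic-data experiments do and do not show.

## Candidate representation

A candidate instance is one sentence with an unordered pair of drug
mentions. The textually earlier mention is blinded to `drug1`, the later to
`drug2`, and every other drug mention to `drug0`; the token indices of the
blinded drugs are `d1 < d2`, with `END` the last token. Multi-token
mentions collapse to a single blinded token; dependency edges are remapped
onto the collapsed indices (intra-span edges vanish, duplicates are
dropped). This collapse is a design choice — it keeps the area arithmetic
of the feature kernel exact (`inner count = d2 − d1 − 1`) at the cost of
discarding intra-mention structure, which carries no pair-discriminative
signal. When a non-candidate mention is a proper prefix of its whitespace
token (trailing punctuation), the residue is kept (`drug0.`), matching
whitespace tokenization of running text. Pairs whose mentions overlap
another mention's span are skipped with a warning rather than guessed at.

## Feature-based kernel

All lexical features are binary. Three families cover the sentence:

- **Abon**: 1–3-grams bagged per general area (left / inner / right).
- **San**: 1–3-grams from the four 4-token windows flanking each drug.
- **Cpn**: conjunctions `D1_side^D2_side^distance = g1^g2^d` where the
  sides of drug1 are the **left and inner areas** and the sides of drug2
  the **inner and right areas** (same n on both sides). The area reading —
  rather than the 4-token windows — is deliberate: it is the only reading
  under which the canonical worked-example strings (e.g. `Plasma^are^5`,
  `are decreased when^are decreased when^5`) are produced. The distance is
  the **inner token count** `d2 − d1 − 1`, discretized into the bins
  {0,1,2,3,4,5,6∼7,8∼10,11∼15,16∼20,21∼30,31∼40,40∼}, which partition the
  non-negative integers (41 and above fall in `40∼`).

Five domain features complete the vector:

- **Negative word** — one binary flag: any whole-token (or consecutive
  multi-token) match of {no, not, neither, fail, fail to, fails to, failed,
  failed to, failure} anywhere in the instance. A single presence flag is
  used; a per-word rendering would only duplicate it.
- **NameIsDrug** — ±1 per entity; +1 iff the original surface is
  drug/drugs/Drug/Drugs (generic mentions are inconsistently annotated as
  drug names in real corpora, and the flag lets the learner discount them).
- **Keyword** — one binary feature per lexicon entry matching a token
  *strictly between* the drugs. The inner-area restriction is a choice: a
  cue verb between the names is what signals the relation. Matching is
  lower-cased surface/lemma plus a light suffix-stripping variant match
  (-ing, -ion, -ed, -es, -s, -d, -e; stems shorter than 3 characters are
  not produced), so "decreased" matches "decrease" and "activation"
  matches "activate". The shipped lexicon is a ~60-entry seed list of
  interaction verbs (`src/ddikernels/data/keywords.txt`); it is data, not
  code — any user list loads via `Lexicons.from_files`.
- **Semantic type** — two categorical features, the sorted comma-joined
  type codes of each entity (e.g. `semtype1=carb,phsu`); absent
  annotations simply emit nothing.
- **DrugBank** — per field (indication, pharmacology, description), binary
  word vectors over the union vocabulary of the two drugs' field texts;
  the flag is 1 iff cosine ≥ 0.4 (configurable; 0.4 is the conventional
  operating point for this feature). Bags are lower-cased alphabetic
  tokens, no stop-word removal; unknown drugs are empty bags and score 0.

The level-0 learner for this kernel is a linear SVM with c = 0.006, the
small regularization appropriate for very high-dimensional sparse binary
features.

## All-paths graph kernel

Each instance maps to one block-diagonal graph with two components. The
parse component has a word vertex per token (labels: lemma — lower-cased
surface when no lemma is attached — and POS) and a link vertex per
dependency edge (label: the relation string), wired head → link →
dependent. The shortest path between the drugs is computed on the
*undirected* dependency skeleton (breadth-first, first-found tie-break);
vertices and link vertices on it receive additional `label_IP` copies, and
their edges carry weight 0.9 versus 0.3 elsewhere. The linear component
chains the tokens left-to-right (weight 0.3) with positional tags B/M/A on
lemma and POS labels; the drug vertices themselves are labeled `drug1` /
`drug2`. If the drugs are disconnected, no specialization is applied and a
warning is logged.

The walk-sum matrix is computed in closed form, G = (I−A)⁻¹ − I, after
checking the spectral radius of A is below 1 (with weights < 1 this holds
for all graphs built here); the truncated power series is retained only as
a verification oracle. The kernel is
K = Σ_{(a,b)} R′(a,b)·R″(a,b) with R(a,b) = Σ_{i∋a, j∋b} G_ij, evaluated
as L G Lᵀ over the shared label vocabulary; it is an inner product of
label-projected walk matrices and therefore positive semidefinite.
Embedding both components in one adjacency is equivalent to summing
per-component kernels (cross-component walk weights are zero).

## Convolution tree kernel

The Collins–Duffy recursion: C = 0 for differing productions, C = λ for
matching preterminals (the production includes the word), otherwise
C = λ·Π(1 + C(children)). λ is not dictated by the task; the default 0.4
is the customary mid-range value for this kernel family and is exposed in
`TreeKernelConfig`. At λ = 1 the kernel equals the exact count of common
subtree fragments, which the test suite verifies by explicit enumeration.

Two structures feed the kernel. The SPT is the subtree rooted at the
lowest common ancestor of the entity leaves, pruned to constituents
overlapping the inter-entity span; while it has fewer than 4 leaves and a
parent exists, the full subtree one level up replaces it (iterated
expansion; a single-step variant is available via
`single_step_expansion`). The dependency-path tree encodes each path edge
as `(REL (head dependent))` under a `DEPENDENCY` root, ordered from drug1
to drug2 with the true head/dependent orientation of each edge. Paths
shorter than 3 edges are extended with exactly two off-path edges, taken
from the left of drug1 when two lie entirely at or before `d1` (nearest
first), otherwise from the right of drug2; if neither side offers two, no
extension is applied. A disconnected pair yields a `NOPATH` marker tree.

The instance-level score is the **sum of the two cosine-normalized
kernels** (SPT pair + path-tree pair; a missing structure contributes 0).
How the two structures combine is genuinely open; the normalized sum
keeps both on the same scale and makes the self-score exactly 2.

## Stacking

`build_level1_dataset` runs seeded, label-stratified J-fold
cross-validation (default J = 10, matching common tuning practice;
configurable). Each row of the level-1 set is produced by models whose
training fold excluded that instance; the fold provenance is stored and
`audit_provenance` re-checks it. Level-1 learners:

- **MLR** — least squares on 0/1 responses (binary case: one response,
  threshold 0.5); a rank-deficient design falls back to ridge with
  ε = 1e−8 (logged).
- **Linear SVM** — c = 0.1, threshold at decision value 0.
- **Ranking SVM** — c = 10, trained on the M·N positive-minus-negative
  difference vectors. The canonical formulation uses one-sided +1 pairs
  (`ranksvm_pairs` emits these by default, mirrored optional); the solver
  fits the equivalent mirrored ±1 problem with no intercept, whose hinge
  objective has the same minimizer. A ranking score assigns no class by
  itself, so the decision threshold is chosen to maximize F on the
  level-1 training scores (configuration-free and documented; any other
  rule can be substituted by setting `LinearModel.threshold`). When M·N
  exceeds a cap (default 100 000) a seeded subsample of exactly that many
  pairs is drawn.

Level-0 scores are raw signed decision values; probability calibration is
deliberately omitted. The final model re-fits all level-0 learners on the
full training data. Fixed-weight mixing (`normalize_kernel`,
`combine_kernels`) renormalizes non-negative weights to sum 1 and
preserves positive semidefiniteness.

## Evaluation

P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R); MCC with the standard
formula; AUC by rank statistics with tie averaging. Zero denominators
return 0 with the convention applied uniformly (flags in the report
carry the counts so degenerate cases are visible). Percentages are
reported to 2 decimals; internal values keep full precision. Note that an
F recomputed from 2-decimal-rounded P and R can differ from an F computed
on unrounded values by up to ~0.01.

## Synthetic data: what it shows and what it does not

The generator builds sentences from five templates (cue-bearing 2- and
3-entity patterns, neutral patterns, a negated pattern) whose dependency
trees and bracketings are written by hand and therefore exact, connected
and projective by construction. Knobs: number of sentences; entities per
sentence (2–3); pair-level positive rate (default 0.10 — the ≈1:9
imbalance typical of pharmacology corpora; the per-sentence interaction
probability is derived from it in closed form); noise rate (fraction of
sentences whose labels contradict their wording, default 0.05); generic
mention rate (default 0.08); a mandatory seed (byte-identical output for a
fixed seed). The toy DrugBank snapshot gives interacting drug groups six
shared words plus two unique words per field (cosine 0.75 within a group,
0 across), so the 0.4-threshold feature carries signal.

Passing end-to-end tests on this corpus shows that the kernels, the
stacking machinery and the I/O round-trip are implemented correctly and
that a recoverable signal is recovered. It does **not** show performance
on real biomedical text: the templates have no lexical or syntactic
diversity, no parser errors, no annotation inconsistencies, and the cue
vocabulary coincides with the keyword lexicon. Benchmark-scale F-scores
require the original shared-task corpus, full lexicons and parsers, all
outside this package's scope.

## Problem sizes used in the shipped experiments

Unit and property suites use 20–50 random structures or 10–20-instance
Gram matrices; the stacking-recovery study uses 500 simulated instances ×
20 seeds; end-to-end kernel stacking runs on corpora of 20–50 sentences
(≈40–100 candidate pairs). These sizes were chosen so the full suite
completes in well under a minute on one CPU while still exercising every
code path at non-trivial scale.

## Known limitations

- The keyword lexicon is a seed list, not a curated 500-entry resource;
  recall on real text depends on supplying a fuller list.
- The suffix-stripping variant matcher is intentionally crude (no real
  morphology); it can both under- and over-match rare forms.
- SPT extraction assumes the constituency tree's leaves align 1:1 with the
  corpus tokens (enforced at parse-attachment time).
- The graph kernel densifies the adjacency and inverts (I−A); fine for
  sentence-scale graphs (tens of vertices), not for document graphs.
- Ranking-SVM training materializes difference vectors up to the cap;
  extremely imbalanced corpora rely on the seeded subsample.
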