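# Methods

## Scope and model

`genecontent` reconstructs ancestral gene content on a rooted species tree
under a single-origin / multiple-loss (Dollo) model of homology-group (HG)
evolution. The unit of analysis is the HG — a Markov cluster of a protein
similarity graph, which may span one gene family or a superfamily of
paralogs — not the individual gene. Presence of an HG in a genome means
occupancy count ≥ 1; copy numbers are carried through reports but never
enter classification, because similarity-based clustering cannot resolve
duplication histories reliably.

## Similarity graph

BLAST `-outfmt 6` hits are admitted at e-value ≤ `evalue_max`
(default 1e−5; the threshold is a parameter because published descriptions
of such pipelines are sometimes ambiguous between 1e−4 and 1e−5, and both
readings should be reproducible). Edge weight is
`w = min(−log10 e, weight_cap)` with cap 200 — the standard transform for
MCL on BLAST graphs; a reported e-value of exactly 0 gets the cap.
Reciprocal hits are combined by maximum (options: min, mean). All passing
hits are used by default; a best-reciprocal-style pre-filter can be
emulated with the `min` rule, since whether hits should be restricted
before clustering is itself a methodological ambiguity in the literature.
Proteins named in the ID universe but lacking passing hits become isolated
nodes and cluster as singletons.

## Markov clustering

The transition matrix is column-normalised after adding one self-loop per
node weighted at the node's maximum incident edge weight (1.0 for isolated
nodes) — the usual MCL regularisation. Each iteration applies expansion
(matrix power, default 2), inflation (entrywise power, default granularity
2.0, followed by column renormalisation), then pruning of entries below
1e−5 with renormalisation; a column pruned empty keeps its node as its own
attractor. Convergence is declared when the maximum entrywise change drops
below 1e−6 (cap 100 iterations; non-convergence warns and clusters the
last iterate). Clusters are the connected components of the converged
matrix's support, which makes the result independent of node input order
(nodes are processed sorted). Column sums are tracked every iteration; the
worst deviation from 1 is exposed in `MCLStats` and stays at machine
precision (~1e−15) in practice.

## Classification rules

For node N with child subtrees C₁…C_k, possessor set S(H), leaf set L(N):

* **Ancestral, `two_lineage` mode (default):** |{i : S(H) ∩ L(Cᵢ) ≠ ∅}| ≥ 2.
  This is the operational "witnessed by two main lineages" rule; it is
  robust to single-genome artifacts but cannot see presence carried by one
  lineage plus outgroups.
* **Ancestral, `dollo` mode:** S(H) ∩ L(N) ≠ ∅ and (≥ 2 occupied child
  subtrees or S(H) ⊄ L(N)). This is exactly membership of N in the
  minimal-loss single-gain reconstruction (gain at the MRCA; presence on
  the union of MRCA-to-possessor paths), which the test suite verifies by
  exhaustive enumeration on 6-leaf trees.
* **Novel:** ≥ 2 occupied child subtrees and S(H) ⊆ L(N); at a leaf,
  species-exclusive HGs. Both modes share this definition, and it is
  equivalent to MRCA(S(H)) = N, so every possessed HG is novel at exactly
  one node. On polytomies "two main lineages" generalises to "≥ 2 occupied
  child subtrees" (requiring *all* children would break the
  novel-at-exactly-the-MRCA property).
* **Core:** absences within the clade ≤ `allowed_absences` (default 1) and
  — by default (`require_two_lineages=True`) — every child subtree still
  occupied. The one-absence allowance is the designed tolerance for one
  incomplete genome: deleting any single genome's entire column never
  removes a previously all-present HG from Novel Core (exhaustively
  checked). The child-lineage condition can be relaxed for small clades.
* **Lost:** S(H) ∩ L(N) = ∅, a sibling subtree is occupied, and a
  possessor exists outside the parent's clade. Children of the root have
  no possible outside witness; their Lost set is defined empty and a
  warning is logged — loss inference is inherently sensitive to the
  choice of sister/outgroup, so no number is invented there.

In `dollo` mode these definitions satisfy, for every internal node whose
parent is not the root, the bookkeeping recurrence
`ancestral(C) = (ancestral(parent) − lost(C)) ⊎ novel(C)` on binary trees,
which the tests check on ~10,000 simulated HGs over a 62-leaf tree.

Classification is vectorised: a single postorder pass accumulates, per
node, the count of possessor species inside its clade for all HGs at once
(an `n_nodes × n_HGs` int32 array), from which all category masks are
boolean expressions. A 62-leaf, 10,000-HG classification takes well under
a second.

## Queries

The query grammar is a conjunction of clade quantifiers (`all`, `none`,
`any`, `at_least(C,k)`, `exactly(C,k)`, `all_minus(C,k)`), with `!C` for
the complement leaf set and species as size-1 clades. Disjunction is
deliberately omitted: every classifier rule is expressible as a
conjunction, and conjunction-only semantics are easy to audit (novelty and
core rules are cross-checked against the classifier in the tests).
Quantifiers count clade species with count ≥ 1; `k` must not exceed the
clade size; empty clades satisfy `all` and `none` vacuously.

## Synthetic data

The birth–death generator draws Poisson(`origins_per_branch`) origins on
every branch (the root's stem included) uniformly — branch lengths are
ignored, the simplest exchangeable choice, since no rate model is being
estimated. Conditional on origin, each descendant branch loses the whole
HG with probability `loss_prob`, evaluated only where the lineage still
carries it, so the survival probability at a leaf is
(1 − loss_prob)^(path length from origin), which a Monte-Carlo test checks
against the closed form. Occupancy counts are 0/1 (no copy-number
process); downstream classification only uses presence, so this loses no
generality. HGs lost in every lineage remain as all-zero rows aligned with
the truth table. Genome incompleteness is a separate, independent
per-present-cell dropout with a per-species rate, matching how assembly
and annotation gaps act on real data.

Defaults (origins 5 per branch, loss 0.1, missingness 0) are deliberately
mid-range: enough losses to exercise Lost sets without driving many HGs
extinct. What the generator does *not* emulate: gene duplication and copy
number, lateral transfer, fission/fusion artifacts of homology assignment,
and correlated (clade-biased) genome quality. Tests passing on this
generator therefore validate the bookkeeping and the inference rules, not
the robustness of homology assignment itself on real proteomes.

The planted-partition generator (defaults: 20 clusters × 50 nodes,
p_in = 0.3, p_out = 0.01) draws within-cluster weights uniformly from
20–100 and between-cluster weights from 2–9 on the −log10 e-value scale:
true homologs align with e-values many orders of magnitude stronger than
the spurious cross-family hits that barely pass a 1e−5 threshold
(weight ≈ 5–9). That separation — not density alone — is what makes
similarity graphs clusterable, and with it MCL at inflation 2.0 recovers
the planted labels with adjusted Rand index ≳ 0.92 across seeds.
Synthetic BLAST serialisation writes one 12-column line per edge with
e-value 10^(−w) (shortest round-trip float formatting), so
parse → build reproduces the graph to ≤ 1e−9 in weight; weights at the cap
are not invertible and are written at e-value 0.

## Numerical and formatting choices

Percentages are reported at one decimal plus a nearest-integer twin
mirroring prose usage; fractions with zero denominators are NaN/"NA",
never 0%. All tabular outputs are single-header TSV without
locale-dependent formatting; reruns under an identical config and seed are
byte-identical (the run manifest records parameters and seed, no
timestamps). All randomness flows through `numpy.random.default_rng`
seeded from explicit parameters.

Problem sizes used by the test suite and the acceptance script — 6-leaf
trees for exhaustive oracle enumeration (63 patterns), a 62-leaf random
binary tree with ~10,000 simulated HGs for the recurrence/origin checks,
and the 1,000-node planted partition for MCL recovery — are the package's
standard validation settings: large enough for tight Monte-Carlo bounds
(3 standard errors) while keeping the whole suite in seconds.

## Known limitations

Ancestral content is a minimal inventory: HGs lost in *all* surviving
lineages are invisible, and `two_lineage` ancestral sets exclude HGs held
by one daughter lineage plus outgroups (the `dollo` mode includes them;
both are available precisely because the two operational readings
disagree there). Loss counts depend strongly on the sister group, hence
the empty-by-definition Lost sets at the root's children. The MCL
implementation uses canonical threshold pruning rather than any specific
historical release's per-column selection scheme; partitions on
well-separated graphs agree with a naive dense reference implementation,
but borderline granularity can differ from other MCL builds. No
probabilistic (likelihood-based) gene birth–death estimation is attempted.
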