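# Methods

## Model

`psnet` quantifies inter-series similarity for OMIM phenotypic series (PS)
on a clinical axis (HPO annotations of member diseases) and a biological
axis (GO annotations of the causal gene products), builds weighted
similarity networks from the all-pairs coefficients, and studies how the
networks fragment as the edge-weight threshold rises.

### Information content

Resnik information content is computed from annotation frequency:
`count(t)` is the number of annotated entities (diseases for HPO, gene
products for each GO sub-ontology) annotated to `t` or any descendant,
`p(t) = count(t)/count(root)` and `IC(t) = −ln p(t)`, in nats. The root has
IC 0 exactly and IC is monotone non-decreasing from parent to child. Terms
with no annotated descendants receive the maximum observed IC rather than
infinity, so coefficients stay finite. Natural log is used throughout;
coefficient magnitudes (thresholds of order 1–3) correspond to that choice.
The IC corpus is always recomputed from the loaded annotation set, so the
scale adapts to corpus size (max IC = ln corpus size).

Only `is_a` edges enter ancestor queries; `part_of` and other relationship
types are ignored. Obsolete terms are retained and flagged at parse time but
never participate in ancestor queries; annotations to them are remapped via
`replaced_by` when possible, otherwise dropped with a warning. Alternate
accessions resolve to primary ids at parse time.

### Representative profiles

A PS inherits annotations from several member diseases and is reduced to
one profile per ontology before comparison. For each original term `t` of
each member, `t` is matched against every other member's term set:

* the identical term, when the other member carries `t`;
* otherwise the *best match*: over the other member's terms `t'`, the
  closest common ancestor `cca(t, t')` (minimal summed hop distance, ties to
  higher IC then smallest id) whose IC is maximal; ties prefer the
  higher-IC counterpart, then smallest ids.

The matched terms are sorted by ascending IC and the middle element
(0-based index ⌊L/2⌋, i.e. the more specific of two middles for even L)
becomes the representative of `t` — M representative terms for M original
terms, each an ancestor-or-self of its original. A single-member PS keeps
its terms unchanged; a PS with no usable annotations in an ontology is
excluded from that ontology's network, which is why the five networks can
have different node counts.

The best-match rule is a deliberate design choice for the per-other-member
match. The alternative of pairing `t` with the other member's globally most
informative term regardless of `t` was implemented and rejected: the
counterpart is then almost always unrelated to `t`, the shared ancestor
collapses to near the root, and all profiles flatten to uninformative terms
(verified on synthetic cohorts, where within-group and between-group
coefficients become indistinguishable). By IC monotonicity the identical
term always wins the best match, so the two branches above are consistent.

Biological profiles treat each member disease as the unit, annotated with
the union of its gene products' GO terms per sub-ontology.

### Coefficients and networks

For profiles A and B the pairwise matrix `M_ij = IC(mica(a_i, b_j))` is
assembled (`mica` = most informative common ancestor, IC ties to the
smallest id) and summarised by the best-match average

    w = (Σ_i max_j M_ij + Σ_j max_i M_ij) / (rows + cols),

the average of all row and column maxima pooled together. The alternative
reading — the mean of the row-wise mean and the column-wise mean, which
differs on rectangular matrices — is available as `scheme="two-mean"`; the
pooled reading is the default. `w` is symmetric, non-negative, bounded by
the corpus's maximum IC, and exactly 0 for profiles sharing only the root.

Networks: CSN from HPO profiles, BSN-BP/CC/MF from the GO sub-ontologies,
all complete at threshold 0 (the assembler enforces n(n−1)/2 edges). The
general BSN takes the per-pair maximum over the three sub-ontology networks
(ties resolved BP > CC > MF) and records the winning sub-ontology per edge,
from which per-sub-ontology contribution fractions are reported.

Thresholding is strict (`w > t` survives) and drops isolated nodes, so edge
sets are nested and the component count is non-decreasing in the threshold.
Topology metrics are unweighted: `k_i` = degree; `C_i = 2e_i/(k_i(k_i−1))`
with `C_i = 0` for degree < 2, included in ⟨C⟩; ⟨l⟩ averages shortest-path
lengths over connected pairs only, so it remains defined after
fragmentation; density = 2E/(n(n−1)). The node-retention rule walks the
sorted distinct weights and returns the smallest threshold whose retained
node fraction first reaches the target (default 0.20).

### Clustering and quadrants

The all-pairs coefficients form a symmetric m×m matrix; the diagonal is
each PS's self-coefficient (BMA of its profile against itself — the mean IC
of its profile terms), the natural Resnik-consistent choice, which matters
because the row norms enter the uncentered correlation. Rows are compared
with the uncentered Pearson distance `1 − Σx_i y_i/√(Σx_i² Σy_i²)` and
clustered by average linkage (UPGMA, scipy implementation, verified against
a naive O(m³) recomputation in the tests); the tree is cut to a requested
cluster count (default 8; no principled cut rule is imposed). In pipeline
runs the clustered objects are the PS retained at the retention threshold,
each represented by its full similarity-profile row.

Quadrants partition the PS pairs having both a clinical and a biological
coefficient: II both ≥ cutoff, III biological only, IV clinical only,
I both below. The cutoff default is 2.0 with `≥` on the high side.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
rooted random DAGs (300 terms, depth cap 10, a broad top level of ~12 root
children, 25% of terms with a second parent for genuine DAG-ness); PS of
2–4 diseases; 1–2 causal gene products per disease; 4–6 HPO and 3–6 GO
annotations per entity. 24 PS fall into 8 planted groups. Each group owns,
per ontology, a pool of 5 terms sampled leaf-biased from an anchor term's
subtree; anchors are chosen with mutually disjoint subtrees so groups do not
leak similarity through shared ancestry, and background (non-planted)
annotations are drawn from outside all anchor subtrees, which keeps the
pool terms informative (their IC reflects only the owning group's usage).
Members of a group draw 95% of their annotations from the group pool
(within-group overlap), groups share 10% of their pools through a common
pool (between-group overlap), and each annotation is resampled uniformly at
random with probability 0.05 (noise). Group "modes" plant clinical and
biological similarity independently (both / clin / bio / neither), so all
four quadrants can be populated on purpose; biological pools are planted in
one dominant GO sub-ontology per group, cycling BP/CC/MF, which the ground
truth records. These conditions give within-group coefficients of roughly
1.5–2.4 nats against a between-group background of ~0.3–0.5, comparable to
the coefficient scale of real PS cohorts.

What the generator does **not** emulate: the size and depth heterogeneity of
real HPO/GO (tens of thousands of terms), annotation-propagation artifacts
of curated corpora, evidence-code structure, locus heterogeneity statistics,
or realistic DO class mixtures within a series (each synthetic group has one
DO class). Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted structure, not that real OMIM snapshots will
show any particular network topology.

## Numerical and determinism choices

* All tie-breaks are deterministic: lexicographically smallest id for MICA
  IC ties; higher IC then smallest id for closest-ancestor distance ties;
  BP > CC > MF for merge ties; smallest ids in quadrant listings.
* All randomness flows through `numpy.random.default_rng(seed)` with
  integer-indexed sampling, so cohorts and pipeline artifacts are
  byte-reproducible for a fixed seed (asserted by checksum in the tests).
* Degenerate inputs: empty annotation corpora, header-only GAFs, missing
  pairs in a supposedly complete coefficient set, zero-norm similarity rows
  and empty matrices raise immediately with stage context in pipeline runs.
* Pipeline problem sizes default to 24-PS cohorts; every stage is pure in
  its inputs plus the seed, and inter-stage artifacts are plain TSV.

## Known limitations

* The representative-term reduction is one deterministic reading of the
  intra-PS sharing procedure; other pairing orders are conceivable and would
  change coefficient magnitudes slightly.
* Planted-group recovery by clustering (ARI = 1 at zero noise) is typical
  but not guaranteed for every random cohort: two groups whose anchors lie
  near each other can entangle through the uncentered correlation of their
  full similarity-profile rows even when their pairwise coefficients
  separate cleanly.
* ⟨C⟩ and ⟨l⟩ follow one fixed convention (degree-<2 nodes count as C=0;
  connected pairs only); other tools round or define these differently at
  the third decimal.
* Real-data node/edge counts depend on the OMIM/HPO/GO/DO release used and
  are not treated as reproducible quantities.
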