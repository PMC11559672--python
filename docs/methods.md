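# Methods

## Copy-number calling

Input is a per-sample table of aberration intervals (one row per segment:
chromosome, 1-based inclusive start/end, mean log2 tumor/reference ratio,
supporting probe count), the simplified dialect of vendor
aberration-interval reports. Internally all coordinates are 0-based
half-open; conversion happens only at the file boundary.

A segment is a **gain** when mean log2 > `gain_threshold` (default +0.25),
a **loss** when mean log2 < `loss_threshold` (default −0.25), and
**filtered** when its probe count does not *exceed* `min_probes` (default
3, i.e. at least 4 probes are required). All comparisons are strict, so a
segment sitting exactly on a threshold is neutral; this makes boundary
behavior auditable and classification a pure, idempotent function of
(mean log2, probe count, thresholds). The number of "calls" for a sample
is the count of gain/loss segments.

Calls are projected onto cytobands with the any-overlap rule (≥ 1 base):
the band is the unit at which recurrence is assessed, and the most
inclusive overlap rule is the simplest to audit. When one band carries
both a gain and a loss — in one sample or across samples — both records
are kept and the band is flagged discordant rather than excluded.
Recurrence selection defaults to bands altered in at least 2 samples of a
condition (`min_samples=2`); requiring presence in all samples is a
parameter away.

## Gene sets

Genes are mapped through the altered cytobands (not the raw segments) by
default, because the band is the selection unit upstream; segment-level
mapping is available (`build_gene_set_from_segments`) for finer work.
Gains and losses are pooled into a single gene set per sample/condition,
producing one network per sample and condition. Non-protein-coding
entries are excluded by default (any biotype other than `protein_coding`
is normalized to `other` at load time). Every selected gene keeps its
(cytoband, direction) provenance.

## Interaction filtering and network induction

The edge table follows the STRING protein-links-full layout: two node
identifiers plus one integer score per evidence channel on a 0–1000 scale
(0.4 ≡ 400). Six channels are selected by default — coexpression,
experiments, database, and their homology-transferred variants; the
neighborhood/fusion/cooccurrence and textmining channels never qualify an
edge unless explicitly selected.

An edge is retained when **any** selected channel reaches the cutoff
(`mode="any"`). Requiring the cutoff in **every** selected channel
simultaneously (`mode="all"`) is implemented as a switch, but as a default
it would discard nearly all edges of any realistic evidence table, since
the channels are sparse and largely disjoint; "any" matches how evidence
filters behave in practice.

The subnetwork induced on a gene set is simplified (self-loops removed,
duplicate and reciprocal records merged into one undirected edge) and
restricted to its largest connected component; a size tie is broken by the
component containing the lexicographically smallest symbol, so induction
is deterministic. Nodes left without edges are dropped with their
components.

## Centralities and the HBS class

Three per-node scores are computed on the simplified main component:

- **degree** — incident edge count;
- **betweenness** — Brandes single-source dependency accumulation on the
  unweighted graph, reported unnormalized over *unordered* source–target
  pairs with endpoints excluded. The convention matters: normalization
  differs across libraries and would shift the mean used for
  classification below.
- **eigenvector** — principal eigenvector of the adjacency matrix by
  power iteration, scaled so the largest entry equals 1. The iteration
  runs on A + I, which has the same principal eigenvector as A for a
  connected nonnegative matrix but suppresses the ±λ oscillation of
  bipartite graphs; convergence is declared when successive
  max-normalized iterates differ by less than 1e-10 in the infinity norm,
  with a hard cap of 1000 iterations (failure raises an error carrying
  the iteration count). Max-normalization (rather than 2-norm) is chosen
  so the top node always scores 1; classification is invariant to the
  choice since rescaling scales the mean identically.

A node is a **hub** when its degree is *strictly* greater than the
arithmetic mean degree over the network's nodes; likewise **bottleneck**
(betweenness) and **switch** (eigenvector). **HBS** is the conjunction.
Strictness makes every vertex-transitive graph yield zero labels — a
clean, testable degenerate case — and means regular subnetworks never
produce spurious regulators.

## Comparison reports

Within a condition, all pairwise intersections and the full k-way common
set of the per-sample HBS sets are reported; across conditions, the
per-sample pre∩post sets and the global intersection over all sets.
Member lists are always emitted sorted, and reports are invariant under
permutation of the input sets. Node identity is the bare gene symbol; an
alias map must be applied at interaction-loading time if the edge file
uses other identifiers.

## Over-representation

Annotations are closed under the ancestor relation of the term DAG before
testing (true-path rule; idempotent). For each term with at least one
annotated universe gene, the p-value is the one-sided hypergeometric upper
tail — identical to the one-sided Fisher exact test on the 2×2 table; the
sidedness is fixed here because over-representation is the question being
asked. Terms with no annotated universe gene are never tested, and the
Benjamini–Hochberg family size is the number of tested terms. The default
universe is every gene with at least one propagated annotation,
overridable. Results are ordered by (q, p, term ID) so ties resolve
deterministically. A blocklist of generic terms (matched by ID or exact
name) can be removed from reports, with the removal count returned.

topGO-style elim/weight decorrelation is deliberately not implemented:
only the classic Fisher test is specified by the procedure this package
operationalizes, and decorrelated p-values would not be independently
verifiable.

Note on re-adjustment: applying BH to already-adjusted q-values can only
raise them, so re-running BH shrinks (never grows) the significance set;
it preserves it exactly when significant p-values are well separated from
the cutoff. The tests assert this true form.

## Synthetic data

The generators emulate the study conditions end to end with planted
ground truth. All randomness flows through numpy's PCG64
(`numpy.random.default_rng`), with independent substreams derived by
`SeedSequence.spawn`; the generator name is recorded in every truth JSON
and emitted files are byte-stable per (parameters, seed).

- **Genome** — 2 chromosomes × 8 contiguous cytobands (0.8–1.2 Mb), 15
  genes per band (2–50 kb, uniform placement), 10% non-coding. Sized so
  the full pipeline runs in seconds while leaving ~215 coding genes, enough
  for non-trivial networks.
- **CNA profiles** — 3 samples × {pre, post}. Six planted bands per
  condition, half shared across all samples (occasionally with a flipped
  direction in one sample, exercising discordance flagging); planted
  segments get mean log2 ~ N(±0.5, 0.05) and 5–30 probes, background
  segments N(0, 0.05), plus two large-amplitude segments with ≤ 3 probes
  that must be removed by the probe filter. The generator refuses to run
  unless `log2_effect > gain_threshold + 3·noise_sd`, so planted calls
  survive thresholding by construction (at the defaults the miscall
  probability per segment is Φ(−5) ≈ 3·10⁻⁷), which is what makes the
  ≥ 95% recovery assertion a property of the construction rather than
  luck.
- **Interaction network** — 1200 edges over the coding genes, grown by
  preferential attachment (weight = degree + 1) with the weight of each of
  the 5 planted regulators multiplied by `attachment_bias` (default 25).
  The regulators start as a clique and absorb most attachments, so the
  degree distribution is heavy-tailed with the planted nodes at the top.
  Plain unbiased preferential attachment would *not* make HBS recovery
  precise: in a scale-free graph roughly a fifth of nodes sit above the
  mean on all three centralities, so the HBS set would dilute the planted
  nodes many-fold. The strong bias concentrates shortest paths on the
  regulators — background nodes mostly attach *to* regulators and
  therefore mediate few shortest paths — so above-mean betweenness
  isolates the planted nodes and the three-way conjunction recovers them
  cleanly. Channel scores: 90% of edges pass the 400 cutoff in 1–3
  selected channels; the rest stay below it everywhere; unselected
  channels carry sparse noise.
- **Ontology** — a 50-term random tree of depth 4. The planted term sits
  at depth 3 and is kept a *leaf*: were it internal, its descendants'
  background annotations would propagate into it and inflate its
  annotated count, diluting the planted signal. It directly annotates all
  12 planted genes; every non-root term additionally annotates each gene
  with probability 0.08. Two shallow terms carry deliberately generic
  names so blocklist filtering can be exercised.
- **End-to-end fixture** — the pieces are coordinated: two "core"
  cytobands are gained in every sample and condition, the planted
  regulators are coding genes of those core bands (so every induced
  network contains them and no network is degenerate), and the planted
  enrichment set extends the regulators with further core-band genes.

What the generators do **not** emulate: probe-level intensities and
segmentation, FFPE artifacts, tumor heterogeneity and clonal evolution,
identifier-mapping noise between protein and gene namespaces, and the
annotation biases of real GO. Passing tests therefore demonstrate the
correctness and determinism of the pipeline's logic under its stated
assumptions, not the biological fidelity of any particular cohort.

## Problem sizes and numerical choices

The test suite validates betweenness against exhaustive shortest-path
enumeration on every non-isomorphic connected graph with up to 7 nodes
and 200 random connected graphs with up to 12 nodes, and eigenvector
centrality against dense eigendecomposition to 1e-8 after identical
normalization. Hypergeometric p-values are checked against exact rational
arithmetic for every table with universe size ≤ 30. Stochastic recovery
properties run over seeds 1–20 at the default generator settings. The
small fixture (≈ 215 coding genes, 1200 edges, 50 terms) keeps the whole
suite and the acceptance script within a couple of minutes on one core.

Known limitations: centralities are unweighted and undirected by design;
no community detection or semantic-similarity reduction of redundant
terms; the statistical significance of HBS overlap sizes is not assessed
(raw counts are reported, as in the procedure this package
operationalizes).
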