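# Methods

## Scope and model

`ppinet` treats a knockdown expression profile as a perturbation of an
undirected protein–protein interaction (PPI) network. The interactome is a
simple graph of gene symbols; all directionality, edge confidence and
isoform detail are out of scope. Analysis always starts from a *cleaned*
network: self-interactions removed, duplicate records collapsed (with a
count in the log), and degree-0 nodes dropped. Cleaning is idempotent and
every downstream construction returns cleaned networks whose edges are a
subset of the parent's.

## Differential expression calls

Fold changes use a single signed linear convention: −2.6 means a 2.6-fold
decrease. Ratio-style inputs (0.38) are converted to −1/0.38 on read when
the `ratio_style` flag is set. The DEG threshold is |FC| ≥ 2 with an
*inclusive* boundary — the common reading of a "2-fold change" cutoff —
and regulation is assigned by sign. Rows with missing fold changes are
skipped with a warning rather than failing the run, since array exports
routinely contain unquantified probes.

## Subnetwork constructions

*First-neighbor*: the induced subgraph on the seed genes plus their direct
partners. Induced (select-then-extract) semantics keep neighbor–neighbor
edges, matching the interactive-graph-tool workflow this reimplements; an
`incident_only` flag gives the stricter seed-incident variant. Seeding with
every node recovers the cleaned parent, and the construction is monotone in
the seed set.

*Axis*: from a center protein, retain exactly the simple-path templates
`center–x–d` and `center–x–d–y` with `d` a DEG and `x`, `y` unrestricted,
plus direct `center–d` edges. This is the literal formalization of a
"seed – neighbors – DEGs – neighbors" axis; direct DEG neighbors are kept
without a further `–y` extension, which is one consistent choice where the
informal description is silent. The template depth is fixed at these
patterns rather than exposed as a free parameter, because the brute-force
oracle used in tests enumerates exactly these.

*Internal*: the induced subgraph on the DEG set itself, singletons removed;
its connected-component census reports "k-DEG interactions" (a 3-node
component is one three-DEG interaction).

Seed symbols absent from the parent are reported as a warning, never an
error — in real profiles only a fraction of DEGs map into a curated
interactome.

## Topology

The power-law fit is a simple least-squares regression of log10(count) on
log10(degree) over the observed degree census, reported as `y = βxᵃ` with
the R² of the log-log regression. This is the descriptive convention of
interactive network-analysis tools, *not* a maximum-likelihood heavy-tail
estimate; zero-count degrees are naturally absent (log undefined), and the
fit refuses fewer than two distinct degrees. The "correlation" column is
the Pearson correlation of observed vs fitted counts on the original
scale — one of several conventions in circulation, so the report row
carries a `correlation_definition` field naming it. On an exact power law
the fitted and observed counts coincide and the correlation is defined as
1 (the sample correlation is otherwise degenerate there).

Scalar parameters on n ≥ 3 nodes: density `2E/(n(n−1))`; mean local
clustering with degree < 2 nodes contributing 0; Freeman degree
centralization `[n/(n−2)]·[max_k/(n−1) − density]`. All three lie in [0, 1]
on simple graphs.

## Subcellular layers

Eight ordered layers run from the extracellular space to the nucleus:
Secreted, Secreted/Membrane, Membrane, Cytoskeleton/Cytoplasm, Cytoplasm,
Cytoplasm/Nucleus, Nucleus, Downstream genes. Location keywords are first
canonicalized through a shipped synonym dictionary (e.g. "Cell membrane" →
Membrane); the combination rules are, in order: no recognized keyword →
Downstream genes; Secreted+Membrane → Secreted/Membrane; any set containing
Cytoskeleton → Cytoskeleton/Cytoplasm; Cytoplasm+Nucleus →
Cytoplasm/Nucleus; a single keyword → its home layer; any remaining
conflict (e.g. Membrane+Nucleus) → the most-upstream matching layer,
logged. No authoritative rule set exists for composite localizations; this
one is deterministic, order-independent and reproduces the named composite
layers. The layered layout fixes y at the (negated) layer index and spreads
nodes within a band at distinct integer-offset x positions, with the
within-band order drawn from a seeded generator.

## Shortest paths and the plausibility filter

All minimum-length simple paths between two proteins are enumerated from
the BFS predecessor DAG (via networkx) and returned in lexicographic order;
an exhaustive depth-bounded DFS oracle in the test suite confirms
completeness on all tested graphs. The default plausibility filter encodes
"signalling flows from cytoplasm to nucleus": a path passes when its
intermediate layer indices are non-decreasing and the last intermediate
sits in a nucleus-capable layer (Cytoplasm/Nucleus or Nucleus). This is one
formalization of a qualitative argument, so the rule object is fully
configurable (monotonicity toggle, terminal-layer set, or an arbitrary
predicate); a permissive rule is the identity. Single-edge paths pass
vacuously.

## Random walk with restart

`p_{t+1} = (1−r)Wp_t + rp_0`, `W` the column-normalized adjacency
(`W[i,j] = 1/deg(j)` for neighbors), `p_0` uniform over the seed set (the
standard multi-seed generalization of a single-seed walk). Defaults:
`r = 0.7`, L1 tolerance `10⁻¹⁰`, iteration cap 10⁴. Mass is conserved at
every step and convergence is geometric with ratio ≤ 1−r, so the default
tolerance is reached in well under 100 iterations; `r = 1` returns the seed
vector exactly without iterating. The iterative solution is cross-checked
in tests against the closed form `p = r(I−(1−r)W)⁻¹p_0`. On a disconnected
network the walk stays in the seeds' component; other components receive
probability 0 and appear as `-inf` log scores binned `unreachable`.

Scoring: DEGs (seeds excluded — they are reported separately with bin A)
are ranked descending by steady-state probability with lexicographic
tie-breaks. Log10 scores fall into half-open decade bins `(−k−1, −k]`
lettered from B at k = 2; the published binning notation ("−2.0 ~ −2.99")
leaves gaps such as (−3.0, −2.99) that the half-open convention closes. A
non-seed score above −2 has no letter under that scheme and is clamped to
B.

## Enrichment and the term map

Overrepresentation uses the right-tailed hypergeometric test
`P(X ≥ k | N, K, n)` with Benjamini–Hochberg adjustment — the standard
choice where no specific test is mandated — with each term intersected
with the universe first. The default universe is the analyzed network's
genes intersected with the annotation collection; report-all is the default
significance policy and the output records the test and correction used.
Term–term similarity is Cohen's kappa of the two binary membership vectors
over the universe; identical sets score exactly 1, and edges join pairs
with kappa ≥ 0.3. Groups are connected components — the simplest
formalization of a linked annotation map; iterative group-merging
heuristics of interactive tools are deliberately out of scope — and each
group's leading term minimizes adjusted p (ties: larger overlap, then term
id).

## Synthetic data

The generator emulates the *structure* the analysis assumes, not the
biology: a Barabási–Albert preferential-attachment graph (connected,
scale-free; defaults n = 900, m = 3, giving fits in the R² ≳ 0.8 regime
typical of DEG subnetworks cut from a curated interactome) stands in for
the parent database; 199 up- and 45 down-regulated genes are planted with
fold-change magnitudes log-uniform in [2, 8], matching a 244-DEG knockdown
census, while null genes draw strictly inside (1/2, 2) so threshold
recovery is exact; layer labels are drawn from a categorical distribution
over the 8 layers with keywords chosen to invert cleanly through the
assignment rules; and one annotation term is planted with 4× the null
expected overlap against a designated query. What the generator does *not*
reproduce: degree-correlated expression changes, correlated multi-compartment
localizations, the GO DAG's term nesting, or measurement noise on
fold changes — so green tests demonstrate algorithmic correctness and
recovery of planted structure, not performance on real arrays. The toy
fixture network (14 proteins, 21 interactions between a seed protein and a
target transcription factor, with synthetic but plausible layer labels) is
the only in-package dataset.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded from
user-visible seeds (generators salt a base seed per output so the network
and the profile are independently reproducible). Tabular outputs print
floats at 6 significant digits; the pipeline writes a provenance record
(parameters + SHA-256 input checksums, no timestamps) and identically
seeded runs are byte-identical. Desk-scale test sizes (random graphs of
12–50 nodes for oracle comparisons, 250–900-node synthetic networks for
recovery checks) were chosen so the brute-force oracles stay exact and the
full suite runs in seconds.

## Known limitations

- The plausibility filter is a heuristic; it does not recover a unique
  "most likely" path subset, and no ground truth exists for one.
- The power-law fit is descriptive; it should not be read as a statistical
  test of scale-freeness.
- Localization keyword mapping covers the five canonical compartments plus
  common synonyms; organelle-level detail (mitochondrion, ER, Golgi) maps
  to Downstream genes unless the synonym table is extended.
- Published node/edge counts for database-derived subnetworks depend on the
  interactome release and are not reproduced here.
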