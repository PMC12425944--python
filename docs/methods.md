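# Methods

This note documents the models and procedures implemented in `kgmine`, the
parameters that matter, the synthetic data used to validate them, and the
design choices made where more than one reasonable option existed.

## Assertion mining

A knowledge assertion is a subject–predicate–object triple with statistical
attributes (p-value, adjusted p-value and its correction method, effect
size and metric, sample size, statistical test) and provenance (publication
and table identifiers). Assertions are mined from supplementary tables by a
declarative transform engine: each table is paired with one YAML config
listing, **in execution order**, its value operations and row operations.
The config is the only place human judgement enters; running it is
deterministic, and identical inputs produce byte-identical output.

Supported value operations: `exponentiate(base)` (the cell is assumed to
hold log_base(p); a separate `negate` op composes with it for −log10
columns, keeping each op atomic), `regex_extract(pattern, group)`,
`text_clean(rules)` with an extensible rule set (underscore→space,
whitespace collapse, case folding, taxon-rank-prefix stripping such as
`g__`), and `arithmetic(expr)`, a unary expression in `x` evaluated in a
restricted namespace. Nulls propagate; a numeric op applied to a text cell
yields null with a counted warning rather than an error. Row operations
(`filter`, `cutoff`, `drop_nulls`, `drop_duplicates` with first-occurrence
wins) only remove rows, preserve survivor order, and record
rows-in/rows-out in a drop ledger, so retained + dropped always equals
input.

Two cutoff semantics coexist deliberately: the generic `cutoff(column,
max)` row op keeps cells ≤ max (the natural reading of "maximum"), while
the final governing-p filter applied by `run_config` is strict `<` so that
the invariant "every emitted assertion has governing p < cutoff" holds
exactly. The governing p-value is the adjusted p when a column is mapped
for it, else the raw p; when neither is mapped (tables that report only
correlation directions) no p filter applies. The default cutoff of 0.1
keeps both significant and suggestive assertions in the graph; significance
itself is a separate Boolean flag, strict `<` at α = 0.05 on the governing
p (so an adjusted p of exactly 0.05, or the suggestive 0.0664/0.075 values
in the packaged case studies, are flagged non-significant), and null when
no p-value exists.

## Normalization and the graph model

Labels resolve to CURIEs through a local, deterministic resolver table
(case-folded label → CURIE, canonical name, source database, with optional
Biolink category hints to break homonyms such as a gene symbol colliding
with a taxon name). Normalization is total: every assertion either becomes
an edge (with the resolver's canonical name on the node and the mapping
databases recorded as edge attributes) or a drop-ledger record with a
reason; emitted + dropped = input by construction. CURIE prefixes are
validated only syntactically — no external registry lookup — so everything
runs offline.

The graph is a multigraph: parallel edges for the same triple from
different tables are preserved, and "unique edges" is a *view* computed
over canonical keys — endpoints sorted lexicographically for symmetric
predicates (`associated_with`, `correlated_with`), kept as-is for directed
ones (`affects`, `treats`) — never a destructive merge. KGX TSV output is
byte-stable (nodes sorted by CURIE, edges in insertion order, nulls as
empty fields) and write∘read is the identity.

## Edge scoring network

The scorer is a centralized semantic unifier: graphs mined from dozens of
methodologically different studies carry statistics with incomparable
meanings, and a single positive score per edge makes them usable as graph
weights. Eleven features feed the model — four numeric (p-value, adjusted
p, sample size, effect size), five categorical (FDR-corrected ∈
{true,false,unknown}, statistical test, NLP type, subject and object
mapping database), two free-text (notes, supplementary caption). The
prose enumeration of the feature groups is ambiguous about how it reaches
eleven; this package counts significance as two features (raw and adjusted
p) and the mapping database as two (subject and object side).

Preprocessing: numeric features are z-scored against training statistics
(zero-variance features get sd := 1; nulls impute to the training mean and
hence encode to exactly 0), categoricals are label-encoded with index 0
reserved for values unseen at fit time, and free text is embedded by
deterministic feature hashing of word unigrams (md5-based index and sign,
ℓ2-normalized, 64 dimensions; the empty string embeds to the zero vector).
The embedder is a two-method contract (`dim`, `embed`), so a transformer
pooler output (e.g. 768-dimensional) can be dropped in; the hashing default
keeps every encoding reproducible bit-for-bit with no model download.
Whether categorical codes should be one-hot rather than raw integers is
not determined by the design being followed; raw codes are used, matching
plain label encoding.

Architecture: input (4 + 5 + 2·64 = 137) → 256 → 64 → 1, LeakyReLU
(slope 0.01) after the first two layers, dropout 0.2 between the two
largest layers (training only), Softplus on the output so every score is
strictly positive and finite. The hidden widths are a standard funnel for
this input size. Training minimizes Huber/SmoothL1 loss with transition
β = 1 using a hand-written full-batch Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8); defaults are learning rate 1e-3, 200 epochs, seed 42 —
full-batch is stable at the few-hundred-record scale this model is meant
for. Labels are unconstrained non-negative reals (a 0–100 scale in the
synthetic rubric); training is bit-reproducible under a fixed seed on a
fixed platform, and inference (dropout off) is deterministic.

The architecture's capacity is checked by overfitting 20 distinct records;
the fit is measured by the Huber loss of the *inference* pass (dropout
disabled), since the in-loop loss includes dropout noise that no amount of
fitting removes.

## Centrality analysis

Edge scores are affinities. The weighted directed view adds each symmetric
edge in both directions and each directed edge once; parallel
same-direction contributions sum (repeated independent evidence strengthens
a tie). Path-based betweenness converts affinities to distances d = 1/w —
a stronger tie is a shorter hop — and is reported unnormalized; spectral
measures use affinities directly.

- **Betweenness**: shortest-path betweenness on the weighted digraph
  (networkx backend), unnormalized, ordered node pairs.
- **Eigenvector**: leading eigenvector of Aᵀ (incoming influence) by
  power iteration on Aᵀ + I — the +I shift preserves eigenvectors while
  breaking the oscillation that periodic graphs (e.g. even cycles) induce —
  max-normalized. A nonnegative adjacency is nilpotent exactly when its
  digraph is acyclic; that case (λ_max = 0) is detected up front and
  reported as a failure for the spectral measures.
- **Katz**: x = αAᵀx + β solved by fixed-point iteration with
  α = 0.8/λ_max and β_i the eigenvector-centrality score of node i.
  "α at 80% of the eigenvalue" is read as 80% of the convergence bound
  1/λ_max: the literal 0.8·λ_max exceeds the bound whenever λ_max > 1.25
  and the iteration would diverge, so that reading is rejected on
  convergence grounds.
- **PageRank**: damping 0.85, weight-proportional transitions (networkx
  backend); scores sum to 1.

Convergence tolerance is 1e-10 with a 10,000-iteration cap for all
iterative methods. Tests verify all four against independent oracles on
random strongly connected weighted digraphs of ≤ 5 nodes: exhaustive
simple-path enumeration for betweenness, dense `numpy.linalg.eig` for the
eigenvector, and direct linear solves for Katz and PageRank, at 1e-8
absolute agreement. The random family threads a spanning cycle through
every draw so the graphs are strongly connected and the spectral measures
well-posed.

Per-disease taxon ranking builds the subgraph induced on a disease and its
direct `biolink:OrganismTaxon` neighbors. Taxon–taxon edges are kept by
default — in a pure star every taxon has betweenness 0, which would make
betweenness vacuous — with a star-only variant behind a flag. For each of
the four methods the maximal-scoring taxon (never the disease) is selected;
numerically indistinguishable ties break to the lexicographically smaller
CURIE.

Per-publication summaries report node, total-edge, and unique-edge counts
against the theoretical bounds for the unique count given n nodes:
n(n−1)/2 (fully connected simple graph), n−1 (connected, clique-free), and
n/2 (no connectivity requirement). Totals may legitimately exceed the
maximum (parallel evidence), and unique counts may fall below n−1
(disconnected per-publication subgraphs). The metagraph aggregates node
counts per Biolink class and edge counts per (subject class, predicate,
object class), canonicalizing symmetric-predicate arcs by lexicographic
class order; class counts sum to the node count and arc counts to the edge
count by construction.

## Synthetic data

`SyntheticSpec` emulates one supplementary association table: p-values
drawn from a mixture (fraction `f_sig` = 0.5 from Uniform(0, 0.05), rest
from Uniform(0.05, 1) — so the 0.1 cutoff and the significance flag both
have work to do), effect sizes Normal(0, 0.5) with 10% nulls, 10%
duplicated rows, labels stored in underscore style to exercise text
cleaning, p-values stored as log10 to exercise exponentiation, and 10% of
taxon labels (20% in the conservation checks) deliberately absent from the
resolver to exercise drop-on-failure. Expected output is computed by an
independent straightforward row-walk that shares no code with the
transform engine, enabling exact end-to-end equality checks. Default size
is 50 rows — small enough that every fixture builds in well under a
second, large enough for all code paths to fire.

The synthetic training rubric stands in for manual edge scoring:
100·(1 − governing p) + 10·[FDR-corrected] + Normal(0, 2), clipped at 0,
over records with unique feature combinations. It links the label to
significance, so a model trained on it should (and does, in the tests)
produce higher mean scores for significant than non-significant edges and
recover held-out labels with Spearman ≥ 0.8 on a 300/100 split.

What the synthetic data does *not* emulate: real supplementary tables'
multi-row headers, merged cells, footnote markers, inconsistent rounding,
or genuinely adversarial formatting; real manual scoring rubrics (the
synthetic one is a smooth function of two features — real expert scores
need not be); and corpus-scale graphs (tens of thousands of edges across
dozens of publications). Passing tests therefore demonstrate correctness
of the mechanics and the stated statistical properties under clean
conditions, not robustness to arbitrary real-world tables.

## Case-study bundles

Two packaged bundles transcribe worked examples from the microbiome
literature: the helminthiasis/NAFLD edge set (a helminth–microbiota
association study and a Mendelian-randomization study; six edges) and the
ten *Alistipes* edges (three short-chain fatty acids, tryptophan,
3-formylindole, five inflammation-related mouse genes). Only values
printed in the source narratives are transcribed: adjusted p-values
printed as upper bounds ("<0.0218") are stored as the bound with a
qualifier note; one value printed as "~0" is stored as 1e-12 (p must lie
in (0, 1]) with a note; the five gene edges carry correlation-direction
notes and no numerics, because the narrative prints only the directions.
Resolver CURIEs beyond the two printed MONDO disease identifiers are
illustrative local-resolver content.

## Numerical and degenerate-input choices

- Cell typing precedence is boolean > number > text; a column becomes
  numeric when ≥ 95% of its non-null cells parse. Header rows are always
  explicit (default 0), never sniffed. Encoding is UTF-8 with BOM
  tolerance. Ragged rows pad with nulls and log a warning.
- A null attribute and an absent one are the same thing; edges normalize
  their attribute maps accordingly, which is what makes KGX round-trips
  exact.
- Score histograms use bin width 5 by default; the multimodality indicator
  counts nonzero bins ≥ both neighbors (plateau bins each count, making
  the indicator coarse but monotone under the two-cluster patterns it is
  meant to flag).
- The resolver rejects conflicting duplicate entries at load time rather
  than letting later rows win.

## Known limitations

- Single header row only; two-row headers must be pre-flattened.
- The transform DSL is unary per op; multi-column arithmetic requires
  composing ops through intermediate columns.
- The predicate registry ships the four predicates used by the packaged
  content and is config-extensible; symmetry of any further predicate must
  be declared by the user.
- Betweenness on large dense graphs inherits networkx's cost profile;
  the spectral methods build dense adjacency matrices and are intended
  for subgraph-scale analyses (the per-disease subgraphs are tiny), not
  million-node graphs.
- Training is CPU, full-batch, and intended for hundreds of records;
  there is no mini-batching or hyperparameter search.
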