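# Methods

## Input model

An analysis run operates on four RDF components, conventionally three Turtle
files plus a report: an **ontology** (lightweight RDFS — classes and
`rdfs:subClassOf`), **instance data** (individuals typed via `rdf:type`),
**SHACL shapes** (node shapes targeting classes via `sh:targetClass`,
property shapes attached via `sh:property`), and a **validation report**
(`sh:ValidationReport` with one `sh:result` per violation).  Component
membership is recorded by source file and never inferred from vocabulary:
shapes and ontology terms may legally share namespaces and files, so
vocabulary-based tagging would be ambiguous.  No RDFS/OWL entailment is
applied anywhere — all counts and checks operate on asserted triples only,
which is also what makes the *Missing* bracket (below) meaningful.

Literal identity throughout is lexical: `(value, datatype, language)`.  Two
literals group together iff these three coincide, so no datatype arithmetic
can change a grouping between runs.

## Violation records and grouping

Each top-level `sh:result` becomes one record: focus node, source shape
(the property shape — its IRI is the constraint identity users see), optional
path and value, message, severity (default `sh:Violation`), and constraint
component.  Records are ordered by (compacted focus node, source shape,
value), making every downstream structure order-deterministic.  Nested
`sh:detail` results are not expanded into records; their messages are folded
into the owning record's message as opaque text.  With several
`sh:resultMessage` literals, the lexicographically first (language-tag,
text) pair is chosen — an arbitrary but stable convention.

Two records are **equivalent** when they share (source shape, message,
reported value).  Messages are whitespace-normalized before keying; values
compare as compacted term text; records without a value share the reserved
marker `∅`, so all minimum-count violations of one shape fall into one
group.  A group is summarized by its exemplar — the member with the
lexicographically smallest compacted focus node, a tie-break chosen once so
exports never flicker — and its size `m`; against a selection of focus nodes
the group label is `n/m` with `n` the selected members.

## Class tree

The `rdfs:subClassOf` statements form a forest (a cycle is an input error
and is reported as such).  A class with several superclasses is attached
under its lexicographically first parent and cross-listed by name on the
node, keeping the structure a tree as a hierarchy view requires.  Per class,
`m` counts distinct violating focus nodes whose *direct* asserted type is
that class — no subclass rollup, because a rollup is recoverable by
summation while the reverse is not; a `subtree_total` is exported alongside.
A focus node with k asserted types contributes to k counters.  Classes that
occur as instance types but are undeclared in the ontology are exposed in a
separate *Missing* bracket — in practice these are exactly the schema gaps
worth fixing.

## Path graph

The node-link structure contains ontology classes, node shapes, property
shapes, violation groups, and offending values.  The **essential path** is
class → node shape (`sh:targetClass`) → property shape (`sh:property`) →
violation group → value (`sh:value`); all other edges (subclass links,
`rdf:type` edges of offending values) are context.  Counts accumulate along
the essential path: a property shape's count is the sum of its group sizes,
a node shape's the sum over its property shapes, a class's the sum over its
node shapes; edges carry both endpoint counts (the contract a tapered
rendering would need).  A property shape shared by several node shapes would
contribute its full count to each owner — class totals can then overlap;
the fixtures contain no such sharing.

Instance terms appear **only** when they are the `sh:value` of at least one
result; this restriction is what keeps the graph bounded by the report, not
by the (potentially huge) instance data.  Offending values additionally get
their asserted `rdf:type` edges — the *absence* of such an edge back to the
expected class is the classic root-cause signature.  Groups whose source
shape cannot be found in the shapes component attach to a synthetic
"unresolved shapes" root rather than disappearing.  Group node ids are
short SHA-256 hashes of the key text, stable across exports.  Violation-path
expansion is essential-path reachability: forward from a class, backward
(reversed essential edges) from any other node, so the class↔violation
drill-down works in both directions.  Hiding nodes is presentational — the
induced subgraph keeps its counts.

## Focus table

Rows are the distinct violating focus nodes; data columns are the instance
predicates with at least one violating focus node as subject (`rdf:type` is
always included); cells hold object-term sets; one boolean indicator column
per violated property shape is appended.  Predicates whose only subjects
never violate are excluded — the table is a filtered join, and including
them would only widen it.  Column kinds: indicators are `boolean`; a column
with any multi-valued cell is `set`; a column whose every non-empty cell is
a single numeric literal (numeric XSD datatype, or a plain literal parsing
as a float) is `numeric`; everything else is `categorical`.  Row grouping
partitions rows by indicator pattern; per-column value histograms cap at 50
distinct values with the remainder bucketed as `other` (an unbounded-
cardinality guard).  CSV export renders multi-valued cells as sorted,
`|`-joined term texts, so exports diff deterministically; blank cells and
wide tables are accepted as-is, with column projection instead of
imputation.

## Projection

Feature sets: **violations** — the 0/1 indicator block, which separates
focus nodes purely by which constraints they violate; **full** — the
indicator block plus a one-hot column per (categorical/set column, value)
(absent value = all zeros, multi-valued cells set several positions) and a
z-scored column per numeric column (missing entries imputed at the column
mean).  The one-hot/z-score encoding is this package's declared convention
for mixed RDF features.  The embedding is UMAP with `n_components=2`,
`n_neighbors = min(15, rows − 1)`, `min_dist = 0.1`, and a fixed
`random_state` (default 42) — standard UMAP practice, all configurable.  A
fixed seed disables UMAP's parallel path, trading speed for bitwise
reproducibility within one software environment; across environments only
distance-based properties are meaningful, so quality is asserted via the
silhouette coefficient and the within-/between-pattern mean distance ratio,
never via absolute coordinates.

## Fixtures and the mini-validator

The guiding fixture is a deterministic Tolkien-themed KG built to exhibit
three realistic failure anatomies at desk scale: (i) a cohort-wide missing
property — 5 Hobbit characters have no `hasAncestry` and no suitable
ancestry object exists at all; (ii) plainly missing entries — 2 of the 7
other characters lack `hasHome`; (iii) a cascade — Middle-earth is never
typed `lotr:Continent`, so all 3 regions violate their class constraint,
which makes all 3 locations fail `sh:node` conformance, which invalidates
every character's home.  Defaults (5/7/2/3/3) are the canonical counts and
produce 23 records over 18 focus nodes in 9 groups with 4 distinct
violation patterns; the 5 homed non-Hobbit characters split 3 → Minas
Tirith, 2 → Edoras, fixed so the derived group sizes {3, 2} are stable
oracles.  Character names beyond the canonical ones are generated
deterministically; counts, not names, are contractual.  A parametric
generator reproduces the cascade anatomy at arbitrary depth and violation
rate for property testing.

The bundled validator implements standard SHACL semantics for the subset
the fixtures use: targets are `sh:targetClass` over asserted types;
`sh:minCount` emits one value-less result when a path has too few values;
`sh:class` emits one result per value lacking the required asserted type;
`sh:node` emits one result per value not conforming to the referenced node
shape, where conformance checks the value against the inner shape's
property shapes recursively and ignores the inner shape's own target
declarations.  Conformance is memoized per (node, shape); the `sh:node`
graph must be acyclic (checked up front).  Any other SHACL constraint
component is rejected with an error naming it rather than silently ignored.
Every fixture shape carries an explicit `sh:message`, so group keys never
depend on message synthesis.  The test suite cross-checks the validator's
(focus, shape, value) sets on every fixture against a second,
independently written validator that traverses rdflib graphs directly.

What the fixtures do *not* emulate: real reports' scale (thousands of focus
nodes), hash-like node IDs with human-readable labels, multi-typed
instances, shared property shapes, and the long tail of SHACL-Core
components.  Passing tests therefore demonstrate the correctness of the
analysis semantics, not performance or coverage of full SHACL.

## Problem sizes and numerical conventions

The suite and the acceptance script run entirely on generated inputs: the
guiding fixture (18 focus nodes), the minimal two-character bundle, and
parametric bundles of up to a few dozen instances — sizes at which every
expected count can be enumerated by hand and cross-checked by the
independent validator, while the whole pipeline (including one seeded UMAP
fit) completes in seconds.  Randomness enters only through the parametric
generator's chain sampling and the UMAP seed; both are driven by explicit
seeds.  Degenerate inputs are defined, not special-cased: an empty report
yields empty groups/tables and an all-zero path graph; an empty ontology an
empty forest; embedding requires at least two rows and a neighborhood
smaller than the row count, and rejects anything else with a parameter
error.

## Known limitations

* Only Turtle (and its N-Triples subset) input; no JSON-LD/RDF-XML.
* No RDFS/OWL inference; analyses reflect asserted triples only.
* The validator covers `sh:minCount`/`sh:class`/`sh:node` with
  `sh:targetClass` targets — it exists to make the pipeline hermetic, not to
  replace a full SHACL engine in production.
* UMAP coordinates are reproducible only within one software environment;
  cross-environment comparisons must use the distance-based diagnostics.
* "Same shape" in the grouping key means the property shape; if a property
  shape were reused by several node shapes, their violations would share
  groups (and class counts in the path graph could overlap).
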