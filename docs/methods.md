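# Methods

## Scope and model

This package implements the Matrix and Analysis Metadata Standards
(MAMS) as an executable artifact: an in-memory schema, packaged
vocabularies, a parser/serializer for the list-like JSON/YAML layout, a
rule-based validator, and lineage queries over the provenance DAG. It
deliberately performs no single-cell computation and never opens the
matrix payload files that `filepath`/`accessor` values point at — those
values are opaque strings.

The schema is a *field bag*, not a closed record type. Only `id` (or
`record_id` for REC) and `dataset_id` are required at construction; every
descriptive field is optional, because the standard's goal is that any
stored matrix *can* be annotated, not that every matrix must be fully
annotated. Unknown keys are preserved verbatim as extras at every layer
(entry, document, serialization) — metadata round-trips losslessly even
through tools that do not understand it.

Field-registry choices where the standard leaves room:

- `record_id` applies to all eight classes: it is the REC entry's own id
  and the linking field on every other class.
- `parent_id` applies to FOM and, as an optional extension, to ONG/FNG —
  a neighborhood graph is computed *from* a matrix and workflow diagrams
  draw that arrow, so the lineage can represent it. `parent_relationship`
  remains FOM-only, and the relationship-arity checks are scoped to FOMs
  so a conformant graph entry never warns.
- Compound-ID fields on OID/FID are named `is_compound` (boolean) and
  `delimiter` (string, required iff compound) — minimal and
  self-describing.
- Description twins are first-class registry fields for `processing`,
  `analyte`, `modality`, `obs_subset` and `feature_subset`; other
  `*_description` keys are accepted as extras.
- `record_runtime_start`/`end` are stored verbatim and parsed as
  ISO-8601 only for the end-after-start check; durations accept ISO-8601
  strings or plain seconds.

## Vocabularies

Vocabularies ship as flat TSV tables (token, description, parent,
aliases, provenance) so users can extend them without code changes.
Token lookup is normalized — lower-case with whitespace/hyphen/underscore
separators removed — so "log normalized" and "lognormalized" resolve to
the same term; the string as written in a document is preserved.

All vocabularies are open. The provenance column marks three tiers:
`builtin` (terms the standard enumerates), `inferred` (parents deduced
from description wording: lograw→raw, logcounts→counts,
logintensities→intensities), and `provisional` (term sets this package
assembles from prose where the standard enumerates none:
`feature_subset` = full/detected/variable/selected, plus suggestion-only
`obs_unit`, `data_type`, `representation`). `modality` deliberately has
no vocabulary at all — it is a broader integration axis (cross-species,
cross-technology) where any token is meaningful. Validation enforces only
`processing`, `analyte`, `obs_subset`, `feature_subset`,
`parent_relationship` and `metric_type`; the suggestion-only sets are for
lookup and documentation. `decontaminated`, `corrected` and `centered`
are left parentless: no parent is stated and none is clearly implied.

## Serialization

Canonical layout: `{dataset_id: {class_section: {matrix_id: {field:
value}}}}` with lower-case class sections. The entry's mapping key *is*
its id; an explicit `id` field must match (mismatch is a structural
error). Reading is tolerant — a single-dataset shorthand with class
sections at the top level is accepted, with `dataset_id` injected —
while writing is strict and deterministic: datasets, sections and ids
sorted, fields in registry order, extras sorted, JSON with 2-space
indent, YAML in block style. Serializing twice is byte-identical, which
keeps downstream diffs stable.

Two parser details matter for correctness: duplicate mapping keys
(including duplicate matrix ids) are rejected at load time in both
formats, and the YAML loader leaves ISO timestamps as plain strings so
JSON and YAML parse to equal documents. Any mapping-valued top-level key
is read as a dataset (a misspelled class section inside it is an error);
only non-mapping top-level values are preserved as document extras,
which keeps parse∘serialize total.

## Validation

Fourteen rules with stable ids; problems are reported, never raised.
Defaults follow the standard's open-vocabulary stance
(`vocab_strictness=warn`, provenance links optional, filesystem checks
off). A custom term accompanied by its description twin is conformant at
any strictness. Severity classes: dangling references (REF001), parent
cycles (GRAPH001), inverted runtimes (REC001), compound-ID
inconsistencies (CID001) and blank ids (ID001) are errors; misplaced
fields, relationship-arity mismatches and unknown terms warn; unknown
fields and obs_subset-ordering notes are informational. The
obs_subset containment chain (full ⊇ filtered ⊇ detected ⊇ nonartifact ⊇
clean) cannot be verified from metadata alone — MAMS carries no
observation lists — so a subset child declaring a broader term than its
parent is only an info-level note. References are resolved within one
dataset; a cross-dataset `parent_id` is therefore a dangling-reference
error, matching the per-dataset scope of id uniqueness. Reports are
sorted by (location, rule, message) so identical inputs yield identical
reports regardless of entry insertion order.

## Lineage and queries

The lineage graph contains FOM/ONG/FNG nodes and the parent→child edges
of their `parent_id` declarations; construction refuses documents with
structural defects (carrying the validation issues). OBS/FEA annotation
entries are not ranked nodes — they attach to FOMs through the
`obs`/`fea` linking fields. Ancestry and topological listings use
lexicographic tie-breaks among incomparable nodes, so output is
deterministic. Selection criteria are conjunctive; hierarchical matching
widens a constraint to all descendant terms via the vocabulary
hierarchy. Multi-valued `analyte`/`modality` match if any element
matches. The document diff is a symmetric field-level change-set; an
empty change-set is the package's definition of semantic equality and is
the oracle behind every round-trip test.

## Fixtures

The five curated use-case documents are seedless and byte-stable, with
golden copies packaged under `mams/data/examples/`. Entry counts and ids
are this package's choices; the workflow shapes follow the curated
analysis use cases (droplet scRNA-seq, CITE-seq-style multimodal,
multi-sample integration, biological re-analysis of a cell-type subset,
multiplexed imaging). Two fixture-design choices extend coverage so that
every builtin `processing`/`analyte`/`obs_subset`/`parent_relationship`
term appears somewhere: the imaging use case includes imaging
mass-spectrometry lipid/metabolite matrices, and the biological-subset
use case includes a mitochondrial-variant allele-frequency matrix
(`analyte=dna`, `processing=raw`). Provenance records use neutral
placeholder names (`example_tool`, `0.1.0`). The biological-subset
fixture intentionally uses a custom `obs_subset` term ("tcell") with its
description twin, exercising the described-custom-term path under strict
validation.

`random_document(seed)` emits structurally valid random documents for
property testing: parents are drawn only from earlier matrices (a DAG by
construction), references are sampled from existing ids, and the same
seed reproduces the same document. It emulates document *structure* —
not biological plausibility — so round-trip and validation properties
shown on it say nothing about the scientific coherence of real metadata.

## Verification sizes and numerical choices

The test suite and `scripts/acceptance.py` use 500 seeded random
documents for round-trip checks, 200 random DAGs of up to 50 nodes
(checked against brute-force DFS reachability), and one targeted
corruption per validation rule applied to the strictly clean scRNA-seq
fixture; the whole suite runs in well under a minute on one CPU. Cycle
detection delegates to networkx `simple_cycles`; timestamp comparison is
skipped when exactly one side carries a timezone (incomparable by
design). There is no floating-point numerics in the package; determinism
comes entirely from sorted emission orders and seeded generators.

## Known limitations

- MAMS terms are not mapped onto external ontology IRIs (OBO/EFO).
- No schema migration between profile versions; `spec_version` is
  recorded and defaulted, nothing more.
- Whether an embedding FOM's parent must be a reduction FOM is not
  enforced — tSNE-from-scaled-data workflows exist.
- `accessor` strings are never executed and `filepath` targets are only
  stat-checked under the opt-in policy flag.
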