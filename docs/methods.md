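# Methods

## The expression model

EST counts are treated as draws from the underlying transcript
population of each cDNA library.  All records sharing a normalized
tissue label form a *tissue pool*, all records sharing a stage label a
*stage pool*, and the joint labels a *(tissue, stage) cell pool*.  For
a gene with `n` ESTs in a pool of `N` total ESTs, abundance is

```
TPM = 1e6 · n / N
```

computed in exact floating arithmetic with no rounding.  Marginal TPM
values (tissue-pool and stage-pool denominators) are the two classical
normalizations; the cell-level value uses the joint pool as
denominator, which is the only choice that makes cells mutually
comparable and that degenerates to the marginals when one axis is
collapsed.  Two consequences are load-bearing and tested:

- **Partition identity.** If every EST of a pool belongs to exactly one
  gene, the per-gene TPM values of that pool sum to exactly 1e6 (up to
  float summation error); with unassigned ESTs the sum is ≤ 1e6.
- **No-data semantics.** A pool with `N = 0` has *no* TPM value —
  absence of a library is not zero expression.  Requesting TPM of an
  empty pool is an error, never 0.

Cells whose pool is smaller than `pool_min` (default 30 ESTs) are
flagged low-confidence rather than suppressed: EST sampling depth
limits the resolution of any count-based estimate, and hiding shallow
cells would silently bias breadth statistics.

## Metadata normalization

Library metadata in public EST collections is free text from many
submitters.  Normalization is exact matching after canonicalization
(lowercase, trim, collapse whitespace and underscores) against
per-axis controlled vocabularies shipped as editable YAML
(28 *B. mori* tissues, 31 stages, 4 sexes, 10 strains, each with
synonyms).  There is deliberately no fuzzy matching: every mapping is
auditable and deterministic.  Unmapped or empty values become the
`uncharacterized` category — a value, not an error — while genuinely
uninformative but real labels ("whole body", "uncharacterized tissue")
remain their own canonical categories.  FASTA defline extraction is an
ordered-regex rule engine (covering `/key="value"` and `key: value`
dialects) with an optional library-id lookup table, because defline
conventions differ per submitting center.

The space-delimited flat format ("one EST per line") writes internal
whitespace as underscores; an empty field followed by a non-empty one
is written as `-` and read back as empty, keeping positional parsing
sound.  A literal `-` metadata value is therefore not representable in
this format (the FASTA path carries it fine).

## Specificity calling

Each gene's call derives from two per-axis statistics over its profile:

- `dominance` — the largest share of the gene's ESTs in a single
  canonical tissue (or stage); 1.0 for perfectly exclusive expression.
- `breadth` — the fraction of *qualifying* pools (pool total ≥
  `pool_min`) in which the gene has ≥ 1 EST; an unsampled tissue
  cannot count against ubiquity.

Decision order (deterministic): support < `min_support` (default 3) →
`insufficient_data`; tissue dominance ≥ `d` → `tissue_specific`; stage
dominance ≥ `d` → `stage_specific`; tissue breadth ≥ `b` (default
0.80) → `ubiquitous`; else `mixed`.  Tissue precedes stage by design —
EST libraries confound the two axes, and both dominances are recorded
in the output so the tie is auditable.  The `uncharacterized` category
never serves as a specificity target and never enters breadth: ESTs
without labels contribute support (evidence the gene is expressed) but
not localization evidence.

The default dominance threshold is `d = 0.95`, a strict reading of
"exclusive" appropriate for clean, curated labels; it reproduces the
three anchor patterns (a broadly detected housekeeping-like gene →
ubiquitous; a middle-silk-gland-exclusive gene → tissue_specific; a
pupa-exclusive gene → stage_specific) exactly.  The class-recovery
experiment in `estprofile.experiments` instead runs at `d = 0.8`: under
independent label corruption at rate ε, the expected dominance of a
perfectly specific gene is ≈ 1 − ε, so any threshold above 1 − ε is
unattainable in expectation at realistic EST depth regardless of the
caller — the operating point must sit below the label-retention rate
while staying far above the best non-specific dominance (~1/3 for the
designed mixed genes).  This is a property of the dominance statistic,
chosen by analysis before the experiment, not a tuned value; both
thresholds are exposed as parameters.

## BLAST annotation and GO rollup

The annotation path consumes standard 12-column BLASTx tabular output
(the search itself runs out of process, keeping the pipeline hermetic).
Hits are filtered at an *inclusive* e-value cutoff (≤ 1e-10 by
default; "cutoff" conventionally includes the boundary, and the choice
is documented so it is auditable).  "Most meaningful match" is made
precise as: minimum e-value, ties broken by maximum bit score, then by
lexicographically smallest subject accession — fully deterministic.

GO terms reached through the best hit are rolled up to a fixed level,
where a term's level is the shortest `is_a` distance from its namespace
root (root = level 1); only `is_a` edges are traversed (`part_of` and
regulatory edges are out of scope, and the level parameter makes the
convention revisable).  Counts are of *distinct* ESTs per rollup term,
so an EST whose terms share an ancestor is counted once; percentages
are relative to the dataset's annotated-EST count, hence need not sum
to 100.  At level 1 the summary reduces to the namespace roots, each
counting every EST that maps into its namespace.  The multi-dataset
plot is a grouped bar chart per namespace with a log-scaled percentage
axis.  OBO parsing is delegated to `obonet` (obsolete terms excluded,
acyclicity over `is_a` verified); ancestor traversal and the rollup are
implemented here and tested against a construction-time transitive
closure.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of a large public silkworm
EST collection: 28/31/4/10 category axes with heavy-tailed frequencies
peaking at ovary (14.9%), wing disk (14.6%) and silk gland (12.4%);
5th-instar day 3 at 31.2%, the 5th-instar-to-spinning mixture at 16.8%,
4th-instar day 2 at 9.2%; the Dazao strain at 85.3% and mixed sex at
49.3%.  Accession duplication (default 5%) and per-field missing
metadata (default 2%) emulate dbEST redundancy and incomplete
submissions; deflines are emitted in three dialects (slash key-value,
colon key-value, library-id-only with a lookup sidecar).  Expression
classes are generated by construction: tissue-specific genes put 30
ESTs in one tissue, stage-specific genes 30 ESTs in one stage with
tissues cycled, ubiquitous genes 2 ESTs in every tissue, mixed genes 9
ESTs over a 3×3 tissue-stage block; label noise independently replaces
a record's labels with uniform draws.  One root seed feeds fixed
per-generator substreams, so regeneration is byte-identical.

Not emulated: nucleotide-level sequencing error (sequences are
decorative for parser tests), chimeric clones, correlated library
biases, real GO topology (the synthetic DAG is layered with occasional
extra parents), and real BLAST score statistics.  Passing tests
therefore demonstrate correctness of counting, normalization, calling
and rollup logic under known truth — not robustness to every artifact
of real dbEST submissions.

## Numerical and procedural choices

- Duplicate accessions: first occurrence kept, count logged
  (order-stable, deterministic); removal is accession-level, with
  sequence-level redundancy noted as a possible extension.
- Profile TSVs are written with 17 significant digits so TPM values
  re-ingest bit-exactly; the flat cell table fully determines the
  profile (marginals are recoverable by summation because every record
  carries a normalized label on both axes).
- Hotspot (`argmax_cell`) breaks ties by count, then by cell label.
- Figure axis order follows vocabulary file order — biological, not
  alphabetical — so developmental stages read in temporal order.
- Pipeline outputs are staged in a temporary directory and moved into
  place only on success; the manifest records each file's sha-256, and
  two runs on identical inputs produce identical manifests (all
  randomness lives in the generator, none in analysis stages).
- Validation problem sizes: tally oracles at 20,000 records, class
  recovery at 500 genes, best-hit oracle at 500 queries, GO checks on a
  ~250-term DAG with 100 enrichment replicates — large enough for the
  statistical checks to be meaningful while keeping the whole suite
  fast enough to run on every change.

## Known limitations

- Counting assumes a deduplicated corpus and one (possibly compound)
  tissue label per EST; mixed-tissue libraries count once under their
  compound term rather than once per constituent tissue.
- Cluster tables are taken as ground truth; no de novo clustering or
  assembly is performed, and accessions missing from the corpus are
  reported, never silently dropped.
- No differential-expression statistics are computed between pools, and
  no GO enrichment test (Fisher/hypergeometric) — the GO summary is
  descriptive category percentages only.
- EST-based profiles underestimate genes with few sequenced clones;
  the low-confidence flag marks shallow pools but cannot correct them.
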