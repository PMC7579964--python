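# Methods

## The counting model

A read-based functional profile treats each sequenced read as one unit of
observed abundance. After alignment against a protein database, read *r*
in sample *s* has a set of hits H(r); refinement reduces H(r) to a
retained gene set G(r), and the gene profile is

    abundance(g, s) = Σ_{r in s : g ∈ G(r)} 1 / |G(r)|.

Because each read distributes exactly one unit, per-sample totals equal
the number of refined reads — the central invariant the test suite checks
at 1e-9 × reads in floating point. Aggregation to higher functional levels
applies the same even-split rule through a many-to-many mapping: a source
feature with m targets sends value/m to each, so the invariant survives
the gene → KO and KO → module/pathway steps.

## Hit refinement semantics

Refinement is a fixed sequence: E-value cutoff → per-gene HSP collapse →
strategy → optional top-percentage band.

- **E-value cutoff** (default 0.001, inclusive: `evalue <= cutoff`
  survives; `inf` disables). Applied before anything else, so an
  insignificant hit can never reach the ranking stage. A read whose every
  hit fails the cutoff is dropped from the stream entirely.
- **HSP collapse.** A read can produce several local alignments against
  one gene. Only the best-scoring one represents the (read, gene) pair,
  so a gene can never absorb more than one share of a read's mass. Ties
  within a gene break by lower E-value, then input order — a deterministic
  but inconsequential choice, since only the surviving score matters
  downstream.
- **Ranking.** Bit score descending. Bit scores are independent of
  database size, unlike E-values, which makes retained sets comparable
  across databases. E-value ascending refines the *ordering* among
  bit-score ties but never excludes a bit-score-tied gene.
- **best**: keep every gene at the read's maximum bit score. Ties are
  genuinely common in practice (short reads against UniRef90 clusters),
  which is why the fractional-counting rule exists at all.
- **best_n**: keep the n top-scoring genes; if a tie straddles rank n,
  every gene at the boundary score is kept. The alternative — dropping an
  arbitrary subset of tied genes — would make results depend on input
  order. Consequently the result may exceed n.
- **top_percentage p**: keep hits with bit score ≥ (1 − p/100) × max.
  Applied after the strategy; p = 0 degenerates to best-match, p = 100 is
  a no-op. Under `best` the band can never remove anything (all survivors
  share the maximum); under `best_n` it can prune low-ranked genes.

Refinement is idempotent and only ever *selects* hits — no field is
rewritten — which the property tests assert directly.

## Aggregation and unmapped mass

Both aggregation steps default to the even split described above, which
keeps total abundance conserved and therefore testable. A `copy` mode
(full value to every target, non-conserving) is provided because naive
KEGG-style summaries often count a KO fully in each pathway that contains
it; the two modes are documented alternatives, not a claim that either is
the only defensible choice. Sources absent from a mapping go to a reserved
`UNMAPPED` feature by default (`collect`); with `drop` their mass is
discarded but reported per sample in the step summary, so either way the
mass balance is auditable. `UNMAPPED` mass at the KO level is carried
through to module/pathway level unchanged rather than re-aggregated. The
reserved id may not appear as a mapping target.

Paired-end handling: each mate is an independent read contributing its own
unit, so a pair with both mates mapping contributes 2.0. Read sets
(forward / reverse / singleton) are refined and counted separately, then
summed per sample. Relative-abundance normalization, when enabled, is
applied to the KO profile before module/pathway aggregation; since
aggregation is linear, module and pathway columns then also sum to 1 per
sample (up to collected unmapped mass).

## Summary statistics

Mean base quality is the mean over **all bases** of the Phred score (total
quality / total bases), not the mean of per-read means; the two differ
whenever read lengths vary. Phred+33 encoding is assumed (modern
Illumina); Phred+64 is not supported. Mean read length is the mean over
reads of sequence length. The master table outer-joins the per-step tables
on sample id with columns namespaced `step.statistic`; cells for samples a
step never saw are left empty.

## The resumable driver

Output paths encode parameters: a step's folder is named
`step.key_value.key_value...` with keys sorted, values spelled exactly as
in the configuration file. Nesting mirrors the dependency chain
(`filter.*/aggregate.*/normalize.*/`), so changing a parameter relocates
that stage's outputs *and* every downstream stage's outputs, while
unaffected branches (FASTQ statistics, pre-filter alignment statistics)
keep their files.

Planning is demand-driven, walking backwards from the final outputs
(KO/module/pathway profiles and the master table): a step is scheduled
only when a file somebody needs is missing. This has two consequences that
a naive "run if my own output is missing" rule would get wrong. First, a
re-run after a successful run schedules nothing even though deletable
intermediates (refined alignment tables, per-sample gene profiles) were
removed — nothing demands them. Second, changing one parameter schedules
exactly the dependency closure of the affected step, because only those
encoded paths moved. Existing files are trusted by name — resume detection
uses no timestamps or checksums, so manually edited outputs are taken at
face value (a documented limitation).

Samples are isolated: per-sample steps run inside a failure boundary, a
failing sample's partial outputs are removed, and cross-sample stages run
only when every sample succeeded — a merged profile is never silently
built from a subset. The CLI exits 0 on success, 1 when some samples
failed (completed samples' outputs remain valid and a repaired re-run
processes only the failed ones), 2 on configuration errors.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of real inputs, not their content:
BLAST-tabular alignments in which each read's best hit points to its true
source gene, bit-score ties planted at an exact-equality rate
(`tie_rate`, default 0.2, tie width 2), strictly sub-best decoy hits
(`decoy_rate` 0.3, 1–3 decoys with scores 0.5–30 bits below the best, any
E-value), true-hit E-values drawn as 10^U(−40, −5) so they always pass the
0.001 default cutoff, and bit scores on a 0.1 grid so tie detection needs
no tolerance. The default catalog — 120 genes, 40 KOs, 10 modules, 6
pathways, 30% of genes on two KOs, 10% unmapped, a quarter of KOs in two
modules/pathways — is small enough for a test suite yet exercises every
splitting and unmapped-mass rule; the default cohort is 4 samples × 5,000
reads.

Ground-truth profiles are computed by a second, independent implementation
of the even-split arithmetic inside the generator, over the realised
per-read retained sets, so end-to-end comparisons are genuine two-route
checks. One stream of a seeded NumPy generator backs each output file,
with substreams keyed by (seed, stable file label); outputs are
byte-identical across invocations and adding samples does not perturb
existing ones.

What passing these tests does **not** show: the generator plants no
sequencing errors, no reads that fail to align, no compositional structure
across samples, no relationship between E-value and bit score, and no
realistic database redundancy. Agreement on fixtures demonstrates that the
bookkeeping — refinement logic, fractional mass, aggregation, resume —
is correct, not that any biological conclusion drawn from real data would
be.

## Numerical choices

- Fractional shares are kept in binary floating point without rounding;
  with tie width 2 and mapping multiplicities ≤ 2 all shares are dyadic,
  which is why noiseless recovery tests can assert exact equality.
- Profile TSVs serialize floats with 12 significant digits so that
  write → read round-trips values well within the 1e-9 tolerances used
  throughout; alignment tables serialize floats via shortest-round-trip
  `repr`, making parse → write → parse a byte-level fixed point.
- Conservation and equality tolerances scale with the number of reads
  (1e-9 × reads) to track additive float error.
- Degenerate inputs: empty alignment files yield empty streams, an empty
  FASTQ reports count 0 with means omitted, a zero-total sample is a
  normalization error naming the sample, and duplicate read ids in one
  counting stream are rejected as double counting.

## Known limitations

- No length normalization (RPK-style), copy-number correction or
  evidence-weighted pathway aggregation; profiles are read counts (or
  relative abundances of read counts).
- Phred+64 FASTQ, SAM/BAM input and weighted (non-even) splitting are
  unsupported.
- The unsorted alignment reader buffers the whole file in memory; use
  `assume_sorted` for large sorted inputs.
- Resume trusts file names and existence only; corrupt but present
  outputs are not detected.
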