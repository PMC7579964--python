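# readfunc

Read-based functional annotation of shotgun metagenomes: the post-alignment
core of a metagenomic annotation workflow, as a tested Python library and a
resumable `readfunc` command-line tool.

Shotgun metagenomic sequencing yields reads drawn from every genome in a
microbial community. To estimate which *functions* the community encodes, a
common read-based strategy aligns each read against a protein database such
as UniRef90 (e.g. with DIAMOND), refines each read's matches to a retained
gene set, counts reads into gene abundances, and rolls those up through
KEGG's functional hierarchy — genes → orthology groups (KOs) → modules and
pathways. `readfunc` implements everything downstream of the aligner:

- **Hit refinement.** For each read, hits above an E-value cutoff
  (default 0.001, inclusive) are discarded, multiple local alignments
  against one gene collapse to the best-scoring one, and a strategy keeps
  either the top-scoring gene with *all* bit-score ties (**best match**,
  the high-specificity default) or the top *N* genes with boundary ties
  retained (**best N matches**), optionally restricted to hits scoring
  within a percentage of the read's maximum. Bit score is the ranking
  metric because it is independent of database size.
- **Fractional counting.** Each refined read contributes unit mass: a read
  retained to k genes adds 1/k to each, so a sample's gene-abundance total
  equals its number of counted reads. Forward, reverse and singleton read
  sets are counted separately and summed; each mate of a pair is an
  independent read.
- **Functional aggregation.** Gene abundances are summed into KO
  abundances and KO abundances into module and pathway abundances through
  many-to-many mapping tables. A feature with m targets contributes
  value/m to each (mass-conserving even split; a non-conserving `copy`
  mode is available). Features absent from a mapping are collected under a
  reserved `UNMAPPED` feature by default, so no abundance disappears
  silently. Profiles can optionally be rescaled to relative abundances.
- **Summary statistics.** Every step emits a per-sample table (reads
  counted, mean read length, mean base quality, matches before/after
  refinement, unique features per level, unmapped mass); the driver joins
  them into one master table.
- **Resumable driver.** `readfunc run` chains the stages from a YAML
  configuration. Output folder names encode every parameter that can
  change a step's output (`filter.evalue_cutoff_0.001.strategy_best/...`),
  so re-running with an unchanged configuration recomputes nothing, and
  changing one parameter re-executes exactly that step's dependency
  closure. Samples are processed independently: one malformed sample never
  invalidates the others.
- **Synthetic fixtures.** A seeded generator fabricates gene catalogs,
  DIAMOND-style alignment tables with planted ties and decoys, and FASTQ
  files — together with ground-truth profiles computed by independent
  arithmetic — so the whole pipeline is testable without any database
  downloads.

Running the aligner itself, host filtering, quality trimming, copy-number
correction (MUSiCC) and evidence-weighted pathway aggregation (EMPANADA)
are out of scope.

## Worked example

Five alignments of three reads, in standard 12-column BLAST tabular
format (`outfmt 6`):

```python
from readfunc import (
    FilterConfig, refine_hits, count_gene_abundances, read_alignment_table,
)

lines = [
    "read1\tgeneA\t98.0\t50\t1\t0\t1\t50\t10\t59\t1e-30\t95.0",
    "read1\tgeneB\t92.0\t50\t4\t0\t1\t50\t3\t52\t1e-25\t88.0",
    "read2\tgeneA\t97.0\t48\t1\t0\t1\t48\t5\t52\t1e-28\t90.5",
    "read2\tgeneC\t97.0\t48\t1\t0\t1\t48\t7\t54\t1e-27\t90.5",
    "read3\tgeneB\t90.0\t45\t5\t1\t1\t45\t2\t46\t0.5\t40.0",
]
open("sample1.blast6.tab", "w").write("\n".join(lines) + "\n")

refined, summary = refine_hits(
    read_alignment_table("sample1.blast6.tab"),
    FilterConfig(strategy="best", evalue_cutoff=0.001),
    sample_id="sample1",
)
profile = count_gene_abundances(refined, "sample1")
print(summary.to_frame())
print(profile.to_frame())
```

prints

```
         reads_in  reads_out  matches_post_filter
sample
sample1         3          2                    3

       sample1
gene
geneA      1.5
geneC      0.5
```

read3's only hit (E-value 0.5) fails the 0.001 cutoff, so the read is
discarded (`reads_out` 2). read1 keeps geneA alone (95.0 beats 88.0) and
contributes 1.0; read2 is tied between geneA and geneC at bit score 90.5,
so each gene receives 0.5 — and note that three matches remain because the
tie keeps both genes. The profile total (2.0) equals the number of counted
reads.

The same refinement from the shell:

```bash
readfunc filter --input sample1.blast6.tab --output refined.tab \
    --strategy best --evalue-cutoff 0.001 --sample sample1
readfunc count --input refined.tab --sample sample1 --output gene_profile.tab
readfunc aggregate --profile gene_profile.tab --mapping gene_to_ko.tab \
    --source-level gene --target-level ortholog --output ko_profile.tab
```

A full multi-sample run with resume support reads a YAML config:

```yaml
samples:
  S01: {alignments: alignments/S01.blast6.tab, fastq: fastq/S01.fastq}
  S02: {alignments: alignments/S02.blast6.tab, fastq: fastq/S02.fastq}
mappings:
  gene_to_ortholog: catalog/gene_to_ortholog.tab
  ortholog_to_module: catalog/ortholog_to_module.tab
  ortholog_to_pathway: catalog/ortholog_to_pathway.tab
filter: {strategy: best, evalue_cutoff: 0.001}
aggregation: {split: even, unmapped: collect}
output_dir: out
```

```bash
readfunc run --config config.yaml
```

and leaves KO-, module- and pathway-level profiles plus
`summary.master.tab` under a parameter-encoded output tree. `readfunc
simulate --seed 7 --out fixture/` generates a complete synthetic dataset
(with its ground-truth profiles) to experiment on.

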