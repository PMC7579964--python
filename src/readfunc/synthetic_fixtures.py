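"""Seeded synthetic inputs with known ground truth.

Real inputs to a read-based annotation pipeline are protein-database
alignments of millions of shotgun reads plus gene→KO and KO→module/pathway
mapping tables derived from UniRef90 and KEGG — none of which can ship
with a test suite.  This module fabricates structurally faithful stand-ins:
a gene catalog with ortholog/module/pathway structure, per-sample BLAST
tabular alignment files in which every simulated read's best hit points to
its true source gene (optionally tied across genes, optionally shadowed by
strictly lower-scoring decoy hits), and FASTQ files with tallied length
and quality statistics.

The ground-truth profiles are computed by this module's own even-split
arithmetic over the simulated reads — a second, independent implementation
of the counting and aggregation rules — so end-to-end tests compare the
pipeline against a genuine oracle rather than against itself.

Everything is deterministic under a fixed seed: each output file draws
from a substream derived from the seed and a stable text label, so adding
samples or files never perturbs existing ones.  Simulated bit scores live
on a 0.1 grid and tied scores are bit-identical floats, so tie detection
needs no tolerance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import AlignmentHit, ReadHitGroup, write_alignment_table
from .functional_aggregation import UNMAPPED_ID, FeatureMapping, write_mapping_table


class FixtureError(ValueError):
    """Infeasible fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a small but non-trivial community: 120 genes mapped
    onto 40 KOs, 10 modules and 6 pathways, four samples of 5,000 aligned
    reads each, a 20% chance that a read's best score is tied across two
    genes and a 30% chance of extra sub-best decoy hits — enough structure
    to exercise every refinement and aggregation rule.
    """

    seed: int = 0
    n_genes: int = 120
    n_orthologs: int = 40
    n_modules: int = 10
    n_pathways: int = 6
    multi_ortholog_fraction: float = 0.3
    unmapped_gene_fraction: float = 0.1
    n_samples: int = 4
    reads_per_sample: int = 5000
    tie_rate: float = 0.2
    decoy_rate: float = 0.3
    evalue_exponent_range: tuple[float, float] = (-40.0, -5.0)
    bitscore_range: tuple[float, float] = (60.0, 240.0)

    def __post_init__(self) -> None:
        for name in (
            "multi_ortholog_fraction",
            "unmapped_gene_fraction",
            "tie_rate",
            "decoy_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_genes", "n_orthologs", "n_modules", "n_pathways",
            "n_samples", "reads_per_sample",
        ):
            if getattr(self, name) < 1:
                raise FixtureError(f"{name} must be >= 1")
        n_mapped = self.n_genes - round(self.unmapped_gene_fraction * self.n_genes)
        if n_mapped < self.n_orthologs:
            raise FixtureError(
                f"only {n_mapped} mapped genes cannot reach all "
                f"{self.n_orthologs} orthologs"
            )
        if self.n_orthologs < self.n_modules or self.n_orthologs < self.n_pathways:
            raise FixtureError(
                "need at least as many orthologs as modules and pathways"
            )


def _rng(seed: int, label: str) -> np.random.Generator:
    """Substream for one labelled output, stable under spec changes."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


@dataclass
class Catalog:
    """Synthetic gene catalog with its functional structure."""

    gene_to_ortholog: FeatureMapping
    ortholog_to_module: FeatureMapping
    ortholog_to_pathway: FeatureMapping
    genes: tuple[str, ...]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_to_ortholog": out_dir / "gene_to_ortholog.tab",
            "ortholog_to_module": out_dir / "ortholog_to_module.tab",
            "ortholog_to_pathway": out_dir / "ortholog_to_pathway.tab",
        }
        write_mapping_table(self.gene_to_ortholog, paths["gene_to_ortholog"])
        write_mapping_table(self.ortholog_to_module, paths["ortholog_to_module"])
        write_mapping_table(self.ortholog_to_pathway, paths["ortholog_to_pathway"])
        return paths


@dataclass
class GroundTruth:
    """What the pipeline should recover from a simulated dataset.

    ``gene_counts`` holds the number of reads generated from each gene;
    the expected profiles apply the even-split rules to the *realised*
    per-read retained sets (ties included), computed here with arithmetic
    independent of the pipeline modules.
    """

    gene_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    gene_profile: dict[tuple[str, str], float] = field(default_factory=dict)
    ortholog_profile: dict[tuple[str, str], float] = field(default_factory=dict)
    module_profile: dict[tuple[str, str], float] = field(default_factory=dict)
    pathway_profile: dict[tuple[str, str], float] = field(default_factory=dict)


def generate_catalog(spec: FixtureSpec) -> Catalog:
    """Build the gene→KO, KO→module and KO→pathway mapping tables.

    Exactly ``round(unmapped_gene_fraction * n_genes)`` genes are left out
    of the gene→ortholog mapping and exactly
    ``round(multi_ortholog_fraction * n_genes)`` mapped genes point to two
    orthologs; every ortholog is reachable from at least one gene, every
    module and pathway from at least one ortholog.  A quarter of orthologs
    belong to two modules and two pathways, exercising the downstream
    splitting rule.  Deterministic for a fixed seed.
    """
    rng = _rng(spec.seed, "catalog")
    genes = tuple(f"g{i:05d}" for i in range(spec.n_genes))
    orthologs = [f"K{i:05d}" for i in range(spec.n_orthologs)]
    modules = [f"M{i:04d}" for i in range(spec.n_modules)]
    pathways = [f"path{i:04d}" for i in range(spec.n_pathways)]

    n_unmapped = round(spec.unmapped_gene_fraction * spec.n_genes)
    n_multi = round(spec.multi_ortholog_fraction * spec.n_genes)
    mapped = list(rng.permutation(spec.n_genes))
    unmapped_idx = set(mapped[:n_unmapped])
    mapped_idx = [i for i in mapped if i not in unmapped_idx]
    if n_multi > len(mapped_idx):
        raise FixtureError(
            f"{n_multi} multi-mapped genes requested but only "
            f"{len(mapped_idx)} genes are mapped"
        )

    g2o: dict[str, tuple[str, ...]] = {}
    # first n_orthologs mapped genes anchor one ortholog each (reachability)
    for rank, gi in enumerate(mapped_idx):
        if rank < spec.n_orthologs:
            primary = orthologs[rank]
        else:
            primary = orthologs[rng.integers(spec.n_orthologs)]
        g2o[genes[gi]] = (primary,)
    multi_genes = rng.choice(
        [genes[i] for i in mapped_idx], size=n_multi, replace=False
    )
    for gene in multi_genes:
        primary = g2o[gene][0]
        others = [k for k in orthologs if k != primary]
        extra = others[rng.integers(len(others))]
        g2o[gene] = (primary, extra)

    def _ortholog_map(targets: list[str], label: str) -> dict[str, tuple[str, ...]]:
        sub = _rng(spec.seed, f"catalog.{label}")
        out: dict[str, tuple[str, ...]] = {}
        for rank, ko in enumerate(orthologs):
            if rank < len(targets):
                primary = targets[rank]
            else:
                primary = targets[sub.integers(len(targets))]
            if len(targets) > 1 and sub.random() < 0.25:
                others = [t for t in targets if t != primary]
                extra = others[sub.integers(len(others))]
                out[ko] = (primary, extra)
            else:
                out[ko] = (primary,)
        return out

    # sort g2o by gene id for stable file output
    g2o = {g: g2o[g] for g in sorted(g2o)}
    return Catalog(
        gene_to_ortholog=FeatureMapping("gene", "ortholog", g2o),
        ortholog_to_module=FeatureMapping(
            "ortholog", "module", _ortholog_map(modules, "modules")
        ),
        ortholog_to_pathway=FeatureMapping(
            "ortholog", "pathway", _ortholog_map(pathways, "pathways")
        ),
        genes=genes,
    )


def _distribute(
    profile: dict[tuple[str, str], float],
    mapping: FeatureMapping,
) -> dict[tuple[str, str], float]:
    """Independent even-split aggregation used only for ground truth."""
    out: dict[tuple[str, str], float] = {}
    for (feature, sample), value in profile.items():
        if feature == UNMAPPED_ID:
            targets: tuple[str, ...] = (UNMAPPED_ID,)
        else:
            targets = mapping.pairs.get(feature, (UNMAPPED_ID,))
        share = value / len(targets)
        for t in targets:
            key = (t, sample)
            out[key] = out.get(key, 0.0) + share
    return out


def generate_alignments(
    spec: FixtureSpec, catalog: Catalog, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Simulate per-sample DIAMOND-style alignment tables with ground truth.

    Every read draws a true source gene uniformly from the catalog.  Its
    best hit points to that gene; with probability ``tie_rate`` a second
    gene shares the identical best bit score, and with probability
    ``decoy_rate`` one to three decoy hits with strictly lower bit scores
    (and arbitrary E-values) are appended.  True hits always pass the
    default 0.001 E-value cutoff.  The returned :class:`GroundTruth` holds
    realised read counts per gene and the expected profiles at all four
    levels, computed by this module's own arithmetic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()
    paths: dict[str, Path] = {}
    lo_exp, hi_exp = spec.evalue_exponent_range
    lo_bs, hi_bs = spec.bitscore_range

    for si in range(spec.n_samples):
        sample = f"S{si + 1:02d}"
        rng = _rng(spec.seed, f"alignments.{sample}")
        groups: list[ReadHitGroup] = []
        for ri in range(spec.reads_per_sample):
            read_id = f"{sample}.r{ri:06d}"
            true_gi = int(rng.integers(spec.n_genes))
            true_gene = catalog.genes[true_gi]
            key = (true_gene, sample)
            truth.gene_counts[key] = truth.gene_counts.get(key, 0) + 1

            best_score = round(float(rng.uniform(lo_bs, hi_bs)), 1)
            retained = [true_gene]
            if rng.random() < spec.tie_rate:
                partner_gi = int(rng.integers(spec.n_genes - 1))
                if partner_gi >= true_gi:
                    partner_gi += 1
                retained.append(catalog.genes[partner_gi])
            hits = []
            for gene in retained:
                evalue = 10.0 ** float(rng.uniform(lo_exp, hi_exp))
                hits.append(_make_hit(read_id, gene, best_score, evalue, rng))
            if rng.random() < spec.decoy_rate:
                for _ in range(int(rng.integers(1, 4))):
                    decoy_gene = catalog.genes[int(rng.integers(spec.n_genes))]
                    delta = round(float(rng.uniform(0.5, 30.0)), 1)
                    decoy_score = round(best_score - delta, 1)
                    decoy_evalue = 10.0 ** float(rng.uniform(-30.0, 1.0))
                    hits.append(
                        _make_hit(read_id, decoy_gene, decoy_score,
                                  decoy_evalue, rng)
                    )
            groups.append(ReadHitGroup(read_id, tuple(hits)))

            share = 1.0 / len(retained)
            for gene in retained:
                gkey = (gene, sample)
                truth.gene_profile[gkey] = (
                    truth.gene_profile.get(gkey, 0.0) + share
                )
        path = out_dir / f"{sample}.blast6.tab"
        write_alignment_table(groups, path)
        paths[sample] = path

    truth.ortholog_profile = _distribute(
        truth.gene_profile, catalog.gene_to_ortholog
    )
    truth.module_profile = _distribute(
        truth.ortholog_profile, catalog.ortholog_to_module
    )
    truth.pathway_profile = _distribute(
        truth.ortholog_profile, catalog.ortholog_to_pathway
    )
    return paths, truth


def _make_hit(
    read_id: str,
    gene: str,
    bit_score: float,
    evalue: float,
    rng: np.random.Generator,
) -> AlignmentHit:
    length = int(rng.integers(30, 101))
    pident = round(float(rng.uniform(60.0, 100.0)), 1)
    qstart = int(rng.integers(1, 20))
    sstart = int(rng.integers(1, 200))
    return AlignmentHit(
        query_id=read_id,
        subject_id=gene,
        percent_identity=pident,
        alignment_length=length,
        mismatches=int(rng.integers(0, 10)),
        gap_opens=int(rng.integers(0, 3)),
        query_start=qstart,
        query_end=qstart + length - 1,
        subject_start=sstart,
        subject_end=sstart + length - 1,
        evalue=evalue,
        bit_score=bit_score,
    )


def generate_fastq(
    path: str | Path,
    n_reads: int,
    seed: int = 0,
    length_range: tuple[int, int] = (80, 120),
    quality_range: tuple[int, int] = (20, 40),
) -> dict[str, float | int]:
    """Write a Phred+33 FASTQ file and return generator-side tallies.

    Lengths and per-base qualities are drawn uniformly over the inclusive
    ranges given; the returned dict holds the exact ``read_count`` and the
    ``mean_read_length`` / ``mean_base_quality`` computed from the very
    bases written, for comparison against a scanner.
    """
    path = Path(path)
    rng = _rng(seed, f"fastq.{path.name}")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    total_bases = 0
    total_quality = 0
    with open(path, "w") as fh:
        for i in range(n_reads):
            lo, hi = length_range
            length = int(rng.integers(lo, hi + 1))
            seq = bytes(rng.choice(bases, size=length)).decode("ascii")
            qlo, qhi = quality_range
            quals = rng.integers(qlo, qhi + 1, size=length)
            qual = "".join(chr(33 + int(q)) for q in quals)
            total_bases += length
            total_quality += int(quals.sum())
            fh.write(f"@read{i:06d}\n{seq}\n+\n{qual}\n")
    stats: dict[str, float | int] = {"read_count": n_reads}
    if n_reads > 0:
        stats["mean_read_length"] = total_bases / n_reads
        stats["mean_base_quality"] = total_quality / total_bases
    return stats


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path, with_fastq: bool = True
) -> dict:
    """Write a complete synthetic dataset under ``out_dir``.

    Returns a manifest-style dict with catalog paths, per-sample alignment
    paths, optional per-sample FASTQ paths with their expected statistics,
    and the :class:`GroundTruth`.
    """
    out_dir = Path(out_dir)
    catalog = generate_catalog(spec)
    catalog_paths = catalog.write(out_dir / "catalog")
    alignment_paths, truth = generate_alignments(
        spec, catalog, out_dir / "alignments"
    )
    fastq: dict[str, dict] = {}
    if with_fastq:
        fastq_dir = out_dir / "fastq"
        fastq_dir.mkdir(parents=True, exist_ok=True)
        for sample in alignment_paths:
            fq_path = fastq_dir / f"{sample}.fastq"
            expected = generate_fastq(
                fq_path, n_reads=spec.reads_per_sample, seed=spec.seed
            )
            fastq[sample] = {"path": fq_path, "expected": expected}
    return {
        "catalog": catalog,
        "catalog_paths": catalog_paths,
        "alignments": alignment_paths,
        "fastq": fastq,
        "ground_truth": truth,
    }
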