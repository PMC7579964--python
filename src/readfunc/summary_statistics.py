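"""Per-step, per-sample summary tables and the master table joining them.

Every pipeline stage emits a small named-statistics table (reads counted,
reads discarded, matches remaining, unique features, ...), one row per
sample.  At the end of a run these step tables are outer-joined into a
single master table whose columns are namespaced ``step.statistic``, so a
user can audit the whole run at a glance.

Mean base quality is averaged over *bases* (total Phred score over all
bases divided by total base count), not over per-read means; FASTQ quality
strings are assumed Phred+33.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # avoid an import cycle; hit_filtering imports StepSummary
    from .abundance_profiling import AbundanceProfile
    from .alignment_io import ReadHitGroup

PHRED_OFFSET = 33

StatRow = dict[str, float | int]


class SummaryError(ValueError):
    """Inconsistent or malformed summary input."""


@dataclass
class StepSummary:
    """Named per-sample statistics emitted by one pipeline step."""

    step_name: str
    rows: dict[str, StatRow] = field(default_factory=dict)

    def add_row(self, sample_id: str, stats: Mapping[str, float | int]) -> None:
        if sample_id in self.rows:
            raise SummaryError(
                f"duplicate sample {sample_id!r} in step {self.step_name!r}"
            )
        self.rows[sample_id] = dict(stats)

    def to_frame(self) -> pd.DataFrame:
        """Rows as a DataFrame indexed by sample id."""
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "sample"
        return df

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        return path

    @classmethod
    def read(cls, path: str | Path, step_name: str | None = None) -> "StepSummary":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="sample")
        name = step_name if step_name is not None else path.stem
        return cls(
            step_name=name,
            rows={str(s): row.dropna().to_dict() for s, row in df.iterrows()},
        )


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def fastq_summary(path: str | Path, sample_id: str) -> StepSummary:
    """Read count, mean read length and mean base quality of one FASTQ file.

    Quality is Phred+33.  Mean length is the mean over reads of sequence
    length; mean quality is the mean over *all bases* of the Phred score.
    An empty file reports count 0 and omits the means.  A record whose
    quality string length differs from its sequence length is an error
    naming the record number.
    """
    n_reads = 0
    total_bases = 0
    total_quality = 0
    with _open_maybe_gzip(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            n_reads += 1
            if len(qual) != len(seq):
                raise SummaryError(
                    f"{path}: record {n_reads} ({title.split()[0]}): quality "
                    f"string length {len(qual)} != sequence length {len(seq)}"
                )
            total_bases += len(seq)
            total_quality += sum(qual.encode("ascii")) - PHRED_OFFSET * len(qual)
    stats: StatRow = {"read_count": n_reads}
    if n_reads > 0:
        stats["mean_read_length"] = total_bases / n_reads
        stats["mean_base_quality"] = total_quality / total_bases
    summary = StepSummary(step_name="fastq_stats")
    summary.add_row(sample_id, stats)
    return summary


def filtering_summary(reads_in: int, reads_out: int, sample_id: str) -> StepSummary:
    """Reads discarded by a filtering step, as count and percentage."""
    if reads_out > reads_in:
        raise SummaryError(
            f"sample {sample_id!r}: reads out ({reads_out}) exceeds reads in "
            f"({reads_in}); input files likely mismatched"
        )
    discarded = reads_in - reads_out
    pct = 100.0 * discarded / reads_in if reads_in > 0 else 0.0
    summary = StepSummary(step_name="read_filtering")
    summary.add_row(
        sample_id,
        {
            "reads_in": reads_in,
            "reads_out": reads_out,
            "reads_discarded": discarded,
            "percent_discarded": pct,
        },
    )
    return summary


def alignment_summary(
    groups: Iterable["ReadHitGroup"], sample_id: str
) -> StepSummary:
    """Aligned-read, total-match and unique-gene counts for one sample."""
    reads = 0
    matches = 0
    genes: set[str] = set()
    for group in groups:
        reads += 1
        matches += len(group)
        genes.update(h.subject_id for h in group)
    summary = StepSummary(step_name="alignment")
    summary.add_row(
        sample_id,
        {
            "reads_aligned": reads,
            "total_matches": matches,
            "unique_genes": len(genes),
        },
    )
    return summary


def post_filter_summary(
    groups: Iterable["ReadHitGroup"], sample_id: str
) -> StepSummary:
    """Matches and reads remaining after hit refinement."""
    reads = 0
    matches = 0
    for group in groups:
        reads += 1
        matches += len(group)
    summary = StepSummary(step_name="post_filter")
    summary.add_row(
        sample_id, {"reads_surviving": reads, "matches_post_filter": matches}
    )
    return summary


def profile_summary(
    profile: "AbundanceProfile", step_name: str = "profile"
) -> StepSummary:
    """Per-sample count of present features and total abundance."""
    summary = StepSummary(step_name=step_name)
    for sample in profile.sample_ids:
        column = profile.sample_values(sample)
        summary.add_row(
            sample,
            {
                "unique_features": len(column),
                "total_abundance": sum(column.values()),
            },
        )
    return summary


def merge_summaries(summaries: Iterable[StepSummary]) -> pd.DataFrame:
    """Outer-join step summaries into one master table.

    One row per sample; columns are ``{step_name}.{statistic}`` in input
    (pipeline-stage) order, statistics alphabetical within a step; samples
    absent from a step get empty cells.  Duplicate step names are an error.
    """
    frames: list[pd.DataFrame] = []
    seen: set[str] = set()
    for s in summaries:
        if s.step_name in seen:
            raise SummaryError(f"duplicate step name {s.step_name!r}")
        seen.add(s.step_name)
        df = s.to_frame()
        df = df[sorted(df.columns)]
        df.columns = [f"{s.step_name}.{c}" for c in df.columns]
        frames.append(df)
    if not frames:
        out = pd.DataFrame()
        out.index.name = "sample"
        return out
    master = pd.concat(frames, axis=1, join="outer")
    master = master.sort_index()
    master.index.name = "sample"
    return master


def write_master_table(master: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    master.to_csv(path, sep="\t")
    return path
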