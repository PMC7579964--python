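"""Streaming reader/writer for 12-column BLAST tabular alignment files.

This is the format DIAMOND emits with ``--outfmt 6`` (and BLAST+ with
``-outfmt 6``): one local alignment per line, twelve tab-separated columns
(qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend, sstart,
send, evalue, bitscore).  Hits are surfaced grouped by query read, which is
the unit every downstream refinement step operates on.

Coordinates are kept exactly as parsed (1-based inclusive, BLAST
convention); reversed intervals from reverse-frame hits are never
normalised, because downstream counting never touches coordinates.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Canonical BLAST outfmt-6 column names, in file order.
BLAST6_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bit_score",
)

_INT_FIELDS = {
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
}
_FLOAT_FIELDS = {"percent_identity", "evalue", "bit_score"}


class AlignmentParseError(ValueError):
    """Malformed row in a BLAST tabular file (carries file, line, column)."""


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """One row of BLAST-tabular output: a (read, gene) local alignment.

    ``query_start``/``query_end`` may be reversed for reverse-frame hits;
    they are stored verbatim.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError(
                f"alignment_length must be >= 1, got {self.alignment_length}"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if self.query_start < 1 or self.query_end < 1:
            raise ValueError("query coordinates are 1-based and must be >= 1")


@dataclass(frozen=True, slots=True)
class ReadHitGroup:
    """All hits of one query read, in encounter order."""

    query_id: str
    hits: tuple[AlignmentHit, ...]

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError("ReadHitGroup must contain at least one hit")
        for h in self.hits:
            if h.query_id != self.query_id:
                raise ValueError(
                    f"hit query_id {h.query_id!r} does not match group "
                    f"{self.query_id!r}"
                )

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[AlignmentHit]:
        return iter(self.hits)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_hit_line(line: str, *, path: str = "<str>", lineno: int = 0) -> AlignmentHit:
    """Parse one outfmt-6 data line into an :class:`AlignmentHit`.

    Extra columns beyond the standard twelve are tolerated (DIAMOND can
    append columns); fewer than twelve, or an unparseable numeric field,
    raise :class:`AlignmentParseError` naming file, line and column.
    """
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise AlignmentParseError(
            f"{path}:{lineno}: expected >= 12 tab-separated columns, "
            f"got {len(parts)}"
        )
    if len(parts) > 12:
        logger.warning(
            "%s:%d: %d extra columns beyond the 12 standard BLAST fields "
            "ignored", path, lineno, len(parts) - 12
        )
    values: dict[str, object] = {}
    for i, name in enumerate(BLAST6_COLUMNS):
        raw = parts[i]
        try:
            if name in _INT_FIELDS:
                values[name] = int(raw)
            elif name in _FLOAT_FIELDS:
                values[name] = float(raw)
            else:
                values[name] = raw
        except ValueError as exc:
            raise AlignmentParseError(
                f"{path}:{lineno}: column {i + 1} ({name}): "
                f"cannot parse {raw!r}"
            ) from exc
    try:
        return AlignmentHit(**values)  # type: ignore[arg-type]
    except ValueError as exc:
        raise AlignmentParseError(f"{path}:{lineno}: {exc}") from exc


def _iter_hits(path: str | Path) -> Iterator[AlignmentHit]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#"):  # some BLAST dialects emit headers
                continue
            yield parse_hit_line(line, path=str(path), lineno=lineno)


def read_alignment_table(
    path: str | Path, assume_sorted: bool = False
) -> Iterator[ReadHitGroup]:
    """Stream a BLAST tabular file as one :class:`ReadHitGroup` per read.

    With ``assume_sorted``, rows sharing a query_id must be contiguous and
    groups are yielded as soon as the query changes (constant memory).
    Otherwise the whole file is buffered so that every yielded group is
    complete even when a read's rows are interleaved; groups then come out
    in order of first appearance.  ``.gz`` paths are decompressed
    transparently.  An empty file yields an empty stream.
    """
    if assume_sorted:
        current_id: str | None = None
        buf: list[AlignmentHit] = []
        for hit in _iter_hits(path):
            if current_id is None:
                current_id = hit.query_id
            elif hit.query_id != current_id:
                yield ReadHitGroup(current_id, tuple(buf))
                current_id = hit.query_id
                buf = []
            buf.append(hit)
        if current_id is not None:
            yield ReadHitGroup(current_id, tuple(buf))
    else:
        groups: dict[str, list[AlignmentHit]] = {}
        for hit in _iter_hits(path):
            groups.setdefault(hit.query_id, []).append(hit)
        for qid, hits in groups.items():
            yield ReadHitGroup(qid, tuple(hits))


def format_hit_line(hit: AlignmentHit) -> str:
    """Serialise a hit back to a tab-separated line.

    Floats use ``repr`` (shortest round-tripping decimal), so parse → write
    → parse is lossless and byte-stable.
    """
    out = []
    for f in fields(AlignmentHit):
        v = getattr(hit, f.name)
        out.append(repr(v) if isinstance(v, float) else str(v))
    return "\t".join(out)


def write_alignment_table(
    groups: Iterable[ReadHitGroup], path: str | Path
) -> Path:
    """Write groups to ``path`` in outfmt-6; returns the path written."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for group in groups:
            for hit in group:
                fh.write(format_hit_line(hit))
                fh.write("\n")
    return path
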