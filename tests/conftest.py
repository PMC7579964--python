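from __future__ import annotations

import random

import pytest

from readfunc.alignment_io import AlignmentHit, ReadHitGroup


def make_hit(
    qid: str = "r1",
    sid: str = "g1",
    bit_score: float = 95.0,
    evalue: float = 1e-20,
    **overrides,
) -> AlignmentHit:
    """A syntactically valid hit with the score fields under test."""
    fields = dict(
        query_id=qid,
        subject_id=sid,
        percent_identity=97.0,
        alignment_length=50,
        mismatches=1,
        gap_opens=0,
        query_start=1,
        query_end=50,
        subject_start=10,
        subject_end=59,
        evalue=evalue,
        bit_score=bit_score,
    )
    fields.update(overrides)
    return AlignmentHit(**fields)


def make_group(qid: str, *gene_scores: tuple[str, float], evalue: float = 1e-20):
    return ReadHitGroup(
        qid, tuple(make_hit(qid, g, s, evalue) for g, s in gene_scores)
    )


def random_hits(
    rng: random.Random,
    n_hits: int,
    n_reads: int,
    n_genes: int = 12,
    score_grid: float = 0.5,
) -> list[tuple[str, str, float, float]]:
    """Random (qid, gene, bit_score, evalue) tuples; gridded scores make
    ties common, and evalues straddle the default 0.001 cutoff."""
    rows = []
    for _ in range(n_hits):
        qid = f"r{rng.randrange(n_reads)}"
        gene = f"g{rng.randrange(n_genes)}"
        score = round(rng.uniform(40, 100) / score_grid) * score_grid
        evalue = 10.0 ** rng.uniform(-30, 0)
        rows.append((qid, gene, score, evalue))
    return rows


def tuples_to_groups(rows: list[tuple[str, str, float, float]]):
    by_read: dict[str, list[AlignmentHit]] = {}
    for qid, gene, score, evalue in rows:
        by_read.setdefault(qid, []).append(make_hit(qid, gene, score, evalue))
    return [ReadHitGroup(q, tuple(hs)) for q, hs in by_read.items()]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
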