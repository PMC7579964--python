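"""Per-read refinement of alignment hits to the retained gene set.

A shotgun read typically aligns to many database genes.  Before counting,
each read's hit list is refined: an E-value cutoff discards insignificant
hits, multiple local alignments (HSPs) of the read against one gene
collapse to the best-scoring one, and a retention strategy keeps either the
single best-scoring gene (with all bit-score ties — the high-specificity
default) or the top N genes, optionally widened to every gene scoring
within a percentage of the read's maximum.

Bit score is the ranking metric throughout because it is independent of
database size; E-value only refines ordering among bit-score ties and never
excludes a tied gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .alignment_io import AlignmentHit, ReadHitGroup
from .summary_statistics import StepSummary

#: E-value above which hits are discarded by default.
DEFAULT_EVALUE_CUTOFF = 1e-3


class FilterConfigError(ValueError):
    """Invalid hit-refinement configuration."""


@dataclass(frozen=True)
class FilterConfig:
    """Hit-refinement strategy and its parameters.

    Parameters
    ----------
    strategy:
        ``"best"`` keeps the top-scoring gene per read (all bit-score ties
        kept); ``"best_n"`` keeps the ``n`` top-scoring genes, retaining
        every gene tied at the boundary score.
    n:
        Number of genes for ``best_n``; required for that strategy.
    evalue_cutoff:
        Hits with E-value strictly above this are discarded before any
        strategy is applied (comparison is inclusive: ``evalue <= cutoff``
        survives).  ``math.inf`` disables the cutoff.
    top_percentage:
        If set, after the strategy runs, additionally keep every collapsed
        hit whose bit score is within this percentage of the read's maximum
        (0 reduces to best-match; 100 keeps everything that passed the
        E-value cutoff).
    """

    strategy: str = "best"
    n: int | None = None
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    top_percentage: float | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("best", "best_n"):
            raise FilterConfigError(
                f"unknown strategy {self.strategy!r}; expected 'best' or 'best_n'"
            )
        if self.strategy == "best_n":
            if self.n is None or self.n < 1:
                raise FilterConfigError(
                    "strategy 'best_n' requires n >= 1, got "
                    f"{self.n!r}"
                )
        if self.evalue_cutoff < 0:
            raise FilterConfigError(
                f"evalue_cutoff must be >= 0, got {self.evalue_cutoff}"
            )
        if self.top_percentage is not None and not (
            0 <= self.top_percentage <= 100
        ):
            raise FilterConfigError(
                f"top_percentage must be in [0, 100], got {self.top_percentage}"
            )


def filter_by_evalue(
    group: ReadHitGroup, cutoff: float
) -> ReadHitGroup | None:
    """Keep hits with ``evalue <= cutoff``; ``None`` if none survive."""
    kept = tuple(h for h in group if h.evalue <= cutoff)
    if not kept:
        return None
    return ReadHitGroup(group.query_id, kept)


def _rank_key(indexed_hit: tuple[int, AlignmentHit]) -> tuple[float, float, int]:
    i, h = indexed_hit
    # descending bit score, then ascending evalue, then file order
    return (-h.bit_score, h.evalue, i)


def collapse_to_best_hsp_per_gene(group: ReadHitGroup) -> ReadHitGroup:
    """Keep one hit per gene — the best-scoring HSP — sorted by score.

    Ties within a gene break by lower E-value then earlier file position,
    so the result is deterministic.  Output order is descending bit score
    (E-value ascending, then file order, among equals), the order every
    strategy below assumes.
    """
    best: dict[str, tuple[int, AlignmentHit]] = {}
    for i, hit in enumerate(group):
        prev = best.get(hit.subject_id)
        if prev is None or _rank_key((i, hit)) < _rank_key(prev):
            best[hit.subject_id] = (i, hit)
    ordered = sorted(best.values(), key=_rank_key)
    return ReadHitGroup(group.query_id, tuple(h for _, h in ordered))


def select_best_matches(group: ReadHitGroup) -> ReadHitGroup:
    """Keep every hit whose bit score equals the read's maximum.

    All ties are kept; the operation is idempotent.  Expects one hit per
    gene (after :func:`collapse_to_best_hsp_per_gene`).
    """
    top = max(h.bit_score for h in group)
    return ReadHitGroup(
        group.query_id, tuple(h for h in group if h.bit_score == top)
    )


def select_best_n_matches(group: ReadHitGroup, n: int) -> ReadHitGroup:
    """Keep the ``n`` top-scoring genes, plus every gene tied at rank ``n``.

    A bit-score tie straddling the cutoff rank retains all genes at the
    boundary score, so no gene is dropped arbitrarily and the result can
    exceed ``n``.  ``n`` at least the gene count is the identity.
    """
    if n < 1:
        raise FilterConfigError(f"n must be >= 1, got {n}")
    collapsed = collapse_to_best_hsp_per_gene(group)
    if len(collapsed) <= n:
        return collapsed
    boundary = collapsed.hits[n - 1].bit_score
    kept = tuple(h for h in collapsed if h.bit_score >= boundary)
    return ReadHitGroup(group.query_id, kept)


def filter_by_top_percentage(group: ReadHitGroup, p: float) -> ReadHitGroup:
    """Keep hits scoring within ``p`` percent of the read's best bit score.

    The threshold is ``(1 - p/100) * max_score``; ``p=0`` reduces to
    best-match, ``p=100`` keeps everything.
    """
    if not 0 <= p <= 100:
        raise FilterConfigError(f"top_percentage must be in [0, 100], got {p}")
    top = max(h.bit_score for h in group)
    threshold = (1.0 - p / 100.0) * top
    return ReadHitGroup(
        group.query_id, tuple(h for h in group if h.bit_score >= threshold)
    )


def refine_group(
    group: ReadHitGroup, config: FilterConfig
) -> ReadHitGroup | None:
    """Apply the full refinement chain to one read; ``None`` if it empties.

    Order: E-value cutoff → per-gene HSP collapse → strategy (best /
    best_n) → optional top-percentage band applied to the strategy output.
    Under ``best`` the percentage band is a no-op (survivors already share
    the maximum score); under ``best_n`` it can prune low-ranked genes that
    fall outside the band.
    """
    surviving = filter_by_evalue(group, config.evalue_cutoff)
    if surviving is None:
        return None
    collapsed = collapse_to_best_hsp_per_gene(surviving)
    if config.strategy == "best":
        selected = select_best_matches(collapsed)
    else:
        selected = select_best_n_matches(collapsed, config.n)  # type: ignore[arg-type]
    if config.top_percentage is not None:
        selected = filter_by_top_percentage(selected, config.top_percentage)
    return selected


def refine_hits(
    groups: Iterable[ReadHitGroup],
    config: FilterConfig,
    sample_id: str = "sample",
) -> tuple[list[ReadHitGroup], StepSummary]:
    """Refine a stream of read groups; also report per-sample statistics.

    Returns the surviving groups (reads whose every hit fails the E-value
    cutoff are dropped) and a :class:`StepSummary` with reads in, reads
    surviving, and total matches remaining.  Deterministic for fixed input
    and config.
    """
    refined: list[ReadHitGroup] = []
    reads_in = 0
    matches_out = 0
    for group in groups:
        reads_in += 1
        out = refine_group(group, config)
        if out is not None:
            refined.append(out)
            matches_out += len(out)
    summary = StepSummary(
        step_name="filter",
        rows={
            sample_id: {
                "reads_in": reads_in,
                "reads_out": len(refined),
                "matches_post_filter": matches_out,
            }
        },
    )
    return refined, summary
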