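"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths: plain dict/loop
arithmetic over (read, gene, score) tuples, so agreement with the package
is a genuine two-route check rather than a tautology.
"""

from __future__ import annotations


def brute_refine(
    hits: list[tuple[str, str, float, float]],
    strategy: str = "best",
    n: int | None = None,
    evalue_cutoff: float = 0.001,
    top_percentage: float | None = None,
) -> dict[str, set[str]]:
    """Reference hit refinement: read id -> retained gene set.

    ``hits`` are (query_id, subject_id, bit_score, evalue) tuples.
    """
    by_read: dict[str, list[tuple[str, float, float]]] = {}
    for qid, sid, score, evalue in hits:
        by_read.setdefault(qid, []).append((sid, score, evalue))

    retained: dict[str, set[str]] = {}
    for qid, rows in by_read.items():
        rows = [r for r in rows if r[2] <= evalue_cutoff]
        if not rows:
            continue
        # best HSP per gene
        per_gene: dict[str, float] = {}
        for sid, score, _ in rows:
            if sid not in per_gene or score > per_gene[sid]:
                per_gene[sid] = score
        top = max(per_gene.values())
        if strategy == "best":
            kept = {g for g, s in per_gene.items() if s == top}
        elif strategy == "best_n":
            assert n is not None and n >= 1
            scores = sorted(per_gene.values(), reverse=True)
            if len(scores) <= n:
                kept = set(per_gene)
            else:
                boundary = scores[n - 1]
                kept = {g for g, s in per_gene.items() if s >= boundary}
        else:
            raise ValueError(strategy)
        if top_percentage is not None:
            kept_max = max(per_gene[g] for g in kept)
            threshold = (1.0 - top_percentage / 100.0) * kept_max
            kept = {g for g in kept if per_gene[g] >= threshold}
        retained[qid] = kept
    return retained


def brute_count(retained: dict[str, set[str]]) -> dict[str, float]:
    """Reference fractional counting: gene -> abundance."""
    out: dict[str, float] = {}
    for genes in retained.values():
        share = 1.0 / len(genes)
        for g in genes:
            out[g] = out.get(g, 0.0) + share
    return out


def brute_aggregate(
    column: dict[str, float],
    mapping: dict[str, tuple[str, ...]],
    mode: str = "collect",
    split: str = "even",
) -> tuple[dict[str, float], float]:
    """Reference aggregation of one sample column; returns (result,
    unmapped mass seen)."""
    out: dict[str, float] = {}
    unmapped = 0.0
    for feature, value in column.items():
        targets = mapping.get(feature)
        if targets is None:
            unmapped += value
            if mode == "collect":
                out["UNMAPPED"] = out.get("UNMAPPED", 0.0) + value
            continue
        share = value / len(targets) if split == "even" else value
        for t in targets:
            out[t] = out.get(t, 0.0) + share
    return out, unmapped
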