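"""Aggregation of abundance profiles up many-to-many feature mappings.

Gene abundances are summed into functional-ortholog (KO) abundances, and
ortholog abundances into module and pathway abundances.  A source feature
associated with m targets has its abundance distributed evenly — value/m to
each target — so total abundance is conserved through every aggregation
step ("even" split, the default).  A non-conserving "copy" split, where
every target receives the full source value (naive KEGG-style summation),
is available for comparability with tools that count a KO fully in each of
its pathways.

Sources absent from the mapping either accumulate under the reserved
``UNMAPPED`` feature (default) or are dropped with their mass reported, so
no abundance ever disappears silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .abundance_profiling import AbundanceProfile, ProfileError
from .summary_statistics import StepSummary

logger = logging.getLogger(__name__)

#: Reserved feature id collecting abundance of unmapped source features.
UNMAPPED_ID = "UNMAPPED"

SPLIT_MODES = ("even", "copy")


class MappingError(ValueError):
    """Malformed or inconsistent feature mapping."""


@dataclass(frozen=True)
class UnmappedPolicy:
    """What to do with source features absent from the mapping.

    ``collect`` routes their abundance to the reserved ``UNMAPPED``
    feature; ``drop`` discards it and reports the dropped mass in the step
    summary.
    """

    mode: str = "collect"

    def __post_init__(self) -> None:
        if self.mode not in ("collect", "drop"):
            raise MappingError(
                f"unmapped mode must be 'collect' or 'drop', got {self.mode!r}"
            )


@dataclass
class FeatureMapping:
    """Many-to-many map from source features to target features."""

    source_level: str
    target_level: str
    pairs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for source, targets in self.pairs.items():
            if not targets:
                raise MappingError(f"source {source!r} maps to no targets")
            if len(set(targets)) != len(targets):
                raise MappingError(
                    f"duplicate (source, target) pair for source {source!r}"
                )

    def targets(self, source: str) -> tuple[str, ...] | None:
        return self.pairs.get(source)

    @property
    def n_sources(self) -> int:
        return len(self.pairs)

    @property
    def n_targets(self) -> int:
        return len({t for ts in self.pairs.values() for t in ts})


def read_mapping_table(
    path: str | Path, source_level: str, target_level: str
) -> FeatureMapping:
    """Read a two-column (source, target) TSV into a :class:`FeatureMapping`.

    A source may repeat across lines (many-to-many); exact duplicate pairs
    are kept once with a warning.  ``#`` comment lines are skipped.  A line
    without exactly two columns is a parse error naming the line.
    """
    path = Path(path)
    pairs: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise MappingError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            source, target = parts
            bucket = pairs.setdefault(source, [])
            if target in bucket:
                logger.warning(
                    "%s:%d: duplicate pair (%s, %s) kept once",
                    path, lineno, source, target,
                )
            else:
                bucket.append(target)
    mapping = FeatureMapping(
        source_level=source_level,
        target_level=target_level,
        pairs={s: tuple(ts) for s, ts in pairs.items()},
    )
    logger.info(
        "%s: %d sources -> %d targets", path, mapping.n_sources,
        mapping.n_targets,
    )
    return mapping


def write_mapping_table(mapping: FeatureMapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for source, targets in mapping.pairs.items():
            for target in targets:
                fh.write(f"{source}\t{target}\n")
    return path


def aggregate(
    profile: AbundanceProfile,
    mapping: FeatureMapping,
    policy: UnmappedPolicy = UnmappedPolicy(),
    split: str = "even",
) -> tuple[AbundanceProfile, StepSummary]:
    """Aggregate a profile from the mapping's source level to its target level.

    Under the default even split a source with m targets contributes
    value/m to each, conserving per-sample totals; under ``copy`` each
    target receives the full value.  Returns the aggregated profile and a
    step summary reporting, per sample, the unmapped mass (collected or
    dropped).
    """
    if split not in SPLIT_MODES:
        raise MappingError(f"split must be one of {SPLIT_MODES}, got {split!r}")
    if profile.feature_level != mapping.source_level:
        raise ProfileError(
            f"profile is at level {profile.feature_level!r} but mapping "
            f"expects {mapping.source_level!r}"
        )
    for source, targets in mapping.pairs.items():
        if UNMAPPED_ID in targets:
            raise MappingError(
                f"mapping contains the reserved target {UNMAPPED_ID!r} "
                f"(source {source!r})"
            )
    out = AbundanceProfile(feature_level=mapping.target_level)
    unmapped_mass: dict[str, float] = {}
    for (feature, sample), value in profile.values.items():
        targets = mapping.targets(feature)
        if targets is None:
            unmapped_mass[sample] = unmapped_mass.get(sample, 0.0) + value
            if policy.mode == "collect":
                out.add(UNMAPPED_ID, sample, value)
            continue
        share = value / len(targets) if split == "even" else value
        for target in targets:
            out.add(target, sample, share)
    summary = StepSummary(step_name=f"aggregate_{mapping.target_level}")
    for sample in profile.sample_ids:
        mass = unmapped_mass.get(sample, 0.0)
        summary.add_row(
            sample,
            {
                "unmapped_mass": mass if policy.mode == "collect" else 0.0,
                "dropped_mass": mass if policy.mode == "drop" else 0.0,
                "unique_features": len(out.sample_values(sample)),
            },
        )
    return out, summary


def aggregate_chain(
    gene_profile: AbundanceProfile,
    gene_to_ortholog: FeatureMapping,
    ortholog_to_module: FeatureMapping,
    ortholog_to_pathway: FeatureMapping,
    policy: UnmappedPolicy = UnmappedPolicy(),
    split: str = "even",
) -> tuple[AbundanceProfile, AbundanceProfile, AbundanceProfile]:
    """Gene profile → (ortholog, module, pathway) profiles.

    The ortholog profile is computed once, then aggregated independently to
    modules and to pathways.  The reserved ``UNMAPPED`` ortholog (if any)
    is carried through to module/pathway level as unmapped mass, not
    re-aggregated.
    """
    ortholog, _ = aggregate(gene_profile, gene_to_ortholog, policy, split)
    module, _ = aggregate(ortholog, ortholog_to_module, policy, split)
    pathway, _ = aggregate(ortholog, ortholog_to_pathway, policy, split)
    return ortholog, module, pathway
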