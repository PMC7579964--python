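"""Fractional gene-abundance counting and profile assembly.

Each refined read contributes one unit of abundance.  A read retained to a
single gene adds 1.0 to that gene; a read retained to k genes (bit-score
ties, or a best-N set) adds 1/k to each, so per-sample totals always equal
the number of counted reads.  Forward, reverse and singleton read sets of
a paired-end sample are counted separately and summed — each mate is an
independent read, so a pair whose mates both map contributes 2.0.

Profiles are sparse: structural zeros are absent, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .alignment_io import ReadHitGroup

#: Feature levels a profile can live at, in aggregation order.
FEATURE_LEVELS = ("gene", "ortholog", "module", "pathway")


class ProfileError(ValueError):
    """Inconsistent profile construction or combination."""


@dataclass
class AbundanceProfile:
    """Sparse feature × sample matrix of non-negative abundances.

    ``values`` maps ``(feature_id, sample_id)`` to a strictly positive
    abundance; absent cells are zero.  ``feature_level`` labels what the
    features are (gene, ortholog, module or pathway) and guards against
    combining profiles from different levels.
    """

    feature_level: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_level not in FEATURE_LEVELS:
            raise ProfileError(
                f"unknown feature level {self.feature_level!r}; "
                f"expected one of {FEATURE_LEVELS}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        seen = dict.fromkeys(f for f, _ in self.values)
        return list(seen)

    @property
    def sample_ids(self) -> list[str]:
        seen = dict.fromkeys(s for _, s in self.values)
        return list(seen)

    def get(self, feature: str, sample: str) -> float:
        return self.values.get((feature, sample), 0.0)

    def sample_values(self, sample: str) -> dict[str, float]:
        """Non-zero cells of one sample's column, feature → abundance."""
        return {f: v for (f, s), v in self.values.items() if s == sample}

    def sample_total(self, sample: str) -> float:
        return sum(v for (_, s), v in self.values.items() if s == sample)

    def total(self) -> float:
        return sum(self.values.values())

    def add(self, feature: str, sample: str, amount: float) -> None:
        """Accumulate ``amount`` into a cell (cells never go negative)."""
        if amount < 0:
            raise ProfileError("abundance increments must be non-negative")
        if amount == 0:
            return
        key = (feature, sample)
        self.values[key] = self.values.get(key, 0.0) + amount

    # -- pandas bridge -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame (features × samples), zeros filled in."""
        df = pd.DataFrame(
            0.0,
            index=sorted(self.feature_ids),
            columns=sorted(self.sample_ids),
        )
        for (f, s), v in self.values.items():
            df.at[f, s] = v
        df.index.name = self.feature_level
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_level: str) -> "AbundanceProfile":
        values = {
            (str(f), str(s)): float(v)
            for f, row in df.iterrows()
            for s, v in row.items()
            if v != 0
        }
        return cls(feature_level=feature_level, values=values)


def count_gene_abundances(
    groups: Iterable[ReadHitGroup], sample_id: str
) -> AbundanceProfile:
    """Turn refined read groups into a single-sample gene profile.

    Each read's unit mass is split evenly (1/k) over its k retained genes,
    so the profile total equals the number of contributing reads.  Seeing
    the same query_id twice is an error — it would count a read twice.
    """
    profile = AbundanceProfile(feature_level="gene")
    seen: set[str] = set()
    for group in groups:
        if group.query_id in seen:
            raise ProfileError(
                f"read {group.query_id!r} appears more than once in the "
                f"refined stream for sample {sample_id!r}"
            )
        seen.add(group.query_id)
        share = 1.0 / len(group)
        for hit in group:
            profile.add(hit.subject_id, sample_id, share)
    return profile


def sum_profiles(profiles: Iterable[AbundanceProfile]) -> AbundanceProfile:
    """Cell-wise sum of profiles at one feature level.

    Used to combine forward/reverse/singleton read-set profiles of one
    sample; overlapping cells add.  Commutative and associative.
    """
    profiles = list(profiles)
    if not profiles:
        raise ProfileError("cannot sum an empty collection of profiles")
    level = profiles[0].feature_level
    out = AbundanceProfile(feature_level=level)
    for p in profiles:
        if p.feature_level != level:
            raise ProfileError(
                f"cannot sum profiles at levels {level!r} and "
                f"{p.feature_level!r}"
            )
        for (f, s), v in p.values.items():
            out.add(f, s, v)
    return out


def merge_samples(profiles: Iterable[AbundanceProfile]) -> AbundanceProfile:
    """Assemble single-sample profiles into one multi-sample table.

    Sample ids must be pairwise disjoint; each sample's column in the
    result is identical to its input profile.
    """
    profiles = list(profiles)
    if not profiles:
        raise ProfileError("cannot merge an empty collection of profiles")
    level = profiles[0].feature_level
    out = AbundanceProfile(feature_level=level)
    seen_samples: set[str] = set()
    for p in profiles:
        if p.feature_level != level:
            raise ProfileError("mixed feature levels in merge_samples")
        overlap = seen_samples.intersection(p.sample_ids)
        if overlap:
            raise ProfileError(
                f"duplicate sample id(s) in merge_samples: {sorted(overlap)}"
            )
        seen_samples.update(p.sample_ids)
        for (f, s), v in p.values.items():
            out.add(f, s, v)
    return out


def normalize_relative(profile: AbundanceProfile) -> AbundanceProfile:
    """Rescale each sample's column to sum to 1 (relative abundances).

    The zero structure is preserved.  A sample with zero total cannot be
    normalised and is an error naming the sample.
    """
    totals: dict[str, float] = {}
    for (_, s), v in profile.values.items():
        totals[s] = totals.get(s, 0.0) + v
    for s in profile.sample_ids:
        if totals.get(s, 0.0) <= 0:
            raise ProfileError(f"sample {s!r} has zero total abundance")
    values = {
        (f, s): v / totals[s] for (f, s), v in profile.values.items()
    }
    return AbundanceProfile(feature_level=profile.feature_level, values=values)


def write_profile(
    profile: AbundanceProfile, path: str | Path, float_format: str = "%.12g"
) -> Path:
    """Write a profile as TSV: feature id column, one column per sample.

    Twelve significant digits by default so that write → read reproduces
    every value well within 1e-9 relative error; pass a coarser
    ``float_format`` for human-facing exports.
    """
    path = Path(path)
    profile.to_frame().to_csv(path, sep="\t", float_format=float_format)
    return path


def read_profile(path: str | Path, feature_level: str) -> AbundanceProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.astype(float)
    except ValueError as exc:
        raise ProfileError(f"{path}: cannot parse profile table: {exc}") from exc
    return AbundanceProfile.from_frame(df, feature_level)
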