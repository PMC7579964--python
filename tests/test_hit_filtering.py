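import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readfunc.alignment_io import ReadHitGroup
from readfunc.hit_filtering import (
    DEFAULT_EVALUE_CUTOFF,
    FilterConfig,
    FilterConfigError,
    collapse_to_best_hsp_per_gene,
    filter_by_evalue,
    filter_by_top_percentage,
    refine_group,
    refine_hits,
    select_best_matches,
    select_best_n_matches,
)

from .conftest import make_group, make_hit, random_hits, tuples_to_groups
from .oracles import brute_refine


def genes_of(group):
    return {h.subject_id for h in group}


class TestEvalueFilter:
    def test_default_cutoff_drops_insignificant_hit(self):
        group = ReadHitGroup(
            "r1",
            (make_hit("r1", "g1", evalue=1e-5), make_hit("r1", "g2", evalue=0.5)),
        )
        out = filter_by_evalue(group, DEFAULT_EVALUE_CUTOFF)
        assert genes_of(out) == {"g1"}

    def test_disabled_cutoff_is_identity(self):
        group = make_group("r1", ("g1", 50.0), ("g2", 40.0))
        assert filter_by_evalue(group, math.inf) is not None
        assert filter_by_evalue(group, math.inf).hits == group.hits

    def test_cutoff_is_inclusive(self):
        group = ReadHitGroup("r1", (make_hit("r1", "g1", evalue=0.01),))
        assert filter_by_evalue(group, 0.01) is not None

    def test_emptied_group_becomes_none(self):
        group = ReadHitGroup("r1", (make_hit("r1", "g1", evalue=0.5),))
        assert filter_by_evalue(group, 0.001) is None

    def test_matches_brute_force_scan(self, rng):
        hits = [make_hit("r1", f"g{i}", evalue=10.0 ** rng.uniform(-6, 0))
                for i in range(20)]
        group = ReadHitGroup("r1", tuple(hits))
        out = filter_by_evalue(group, 0.01)
        expected = tuple(h for h in hits if h.evalue <= 0.01)
        assert out.hits == expected


class TestHspCollapse:
    def test_max_of_two_hsps(self):
        group = make_group("r1", ("g1", 80.0), ("g1", 60.0))
        out = collapse_to_best_hsp_per_gene(group)
        assert [(h.subject_id, h.bit_score) for h in out] == [("g1", 80.0)]

    def test_distinct_genes_only_sorted(self):
        group = make_group("r1", ("g1", 50.0), ("g2", 70.0))
        out = collapse_to_best_hsp_per_gene(group)
        assert [h.subject_id for h in out] == ["g2", "g1"]

    def test_matches_brute_force_group_by_max(self, rng):
        rows = [(f"g{rng.randrange(4)}", round(rng.uniform(40, 90), 1))
                for _ in range(15)]
        group = make_group("r1", *rows)
        out = collapse_to_best_hsp_per_gene(group)
        expected = {}
        for g, s in rows:
            expected[g] = max(expected.get(g, -1.0), s)
        assert {h.subject_id: h.bit_score for h in out} == expected


class TestBestMatch:
    def test_singleton(self):
        group = make_group("r1", ("g1", 95.0))
        assert genes_of(select_best_matches(group)) == {"g1"}

    def test_all_ties_kept(self):
        group = make_group("r1", ("g1", 50.0), ("g2", 50.0), ("g3", 40.0))
        assert genes_of(select_best_matches(group)) == {"g1", "g2"}

    def test_matches_brute_force_argmax(self, rng):
        rows = [(f"g{i}", round(rng.uniform(40, 90), 1)) for i in range(25)]
        group = collapse_to_best_hsp_per_gene(make_group("r1", *rows))
        top = max(s for _, s in rows)
        assert genes_of(select_best_matches(group)) == {
            g for g, s in rows if s == top
        }


class TestBestN:
    def test_n_exceeding_gene_count_is_identity(self):
        group = make_group("r1", ("g1", 50.0), ("g2", 40.0))
        assert genes_of(select_best_n_matches(group, 5)) == {"g1", "g2"}

    def test_boundary_tie_keeps_all_tied_genes(self):
        group = make_group(
            "r1", ("g1", 90.0), ("g2", 80.0), ("g3", 80.0), ("g4", 70.0)
        )
        assert genes_of(select_best_n_matches(group, 2)) == {"g1", "g2", "g3"}

    def test_no_boundary_tie(self):
        group = make_group("r1", ("g1", 90.0), ("g2", 80.0), ("g3", 70.0))
        assert genes_of(select_best_n_matches(group, 2)) == {"g1", "g2"}

    def test_invalid_n(self):
        group = make_group("r1", ("g1", 90.0))
        with pytest.raises(FilterConfigError):
            select_best_n_matches(group, 0)


class TestTopPercentage:
    def test_p0_equals_best_match(self):
        group = make_group("r1", ("g1", 50.0), ("g2", 50.0), ("g3", 40.0))
        assert genes_of(filter_by_top_percentage(group, 0.0)) == {"g1", "g2"}

    def test_p100_is_identity(self):
        group = make_group("r1", ("g1", 50.0), ("g2", 1.0))
        assert genes_of(filter_by_top_percentage(group, 100.0)) == {"g1", "g2"}

    def test_threshold_formula(self):
        # p=10 of max 100 keeps scores >= 90
        group = make_group("r1", ("g1", 100.0), ("g2", 91.0), ("g3", 89.0))
        assert genes_of(filter_by_top_percentage(group, 10.0)) == {"g1", "g2"}

    def test_out_of_range_p(self):
        group = make_group("r1", ("g1", 50.0))
        with pytest.raises(FilterConfigError):
            filter_by_top_percentage(group, 101.0)


class TestFilterConfig:
    def test_shipped_defaults(self):
        cfg = FilterConfig()
        assert cfg.strategy == "best"
        assert cfg.evalue_cutoff == 0.001

    def test_best_n_requires_n(self):
        with pytest.raises(FilterConfigError):
            FilterConfig(strategy="best_n")

    def test_unknown_strategy(self):
        with pytest.raises(FilterConfigError):
            FilterConfig(strategy="worst")


CONFIGS = [
    FilterConfig(strategy="best"),
    FilterConfig(strategy="best_n", n=1),
    FilterConfig(strategy="best_n", n=2),
    FilterConfig(strategy="best_n", n=3),
    FilterConfig(strategy="best", top_percentage=0.0),
    FilterConfig(strategy="best_n", n=3, top_percentage=10.0),
    FilterConfig(strategy="best_n", n=3, top_percentage=100.0),
]


class TestRefine:
    def test_minimal_pass_through(self):
        group = make_group("r1", ("g1", 95.0))
        refined, summary = refine_hits([group], FilterConfig())
        assert refined == [group]
        row = summary.rows["sample"]
        assert (row["reads_in"], row["reads_out"], row["matches_post_filter"]) == (1, 1, 1)

    @pytest.mark.parametrize("config", CONFIGS, ids=lambda c: repr(c))
    def test_equals_brute_force_oracle(self, rng, config):
        rows = random_hits(rng, n_hits=200, n_reads=40)
        refined, _ = refine_hits(tuples_to_groups(rows), config)
        got = {g.query_id: genes_of(g) for g in refined}
        expected = brute_refine(
            rows,
            strategy=config.strategy,
            n=config.n,
            evalue_cutoff=config.evalue_cutoff,
            top_percentage=config.top_percentage,
        )
        assert got == expected

    @pytest.mark.parametrize("config", CONFIGS, ids=lambda c: repr(c))
    def test_idempotent(self, rng, config):
        groups = tuples_to_groups(random_hits(rng, n_hits=120, n_reads=25))
        once, _ = refine_hits(groups, config)
        twice, _ = refine_hits(once, config)
        assert [g.hits for g in twice] == [g.hits for g in once]

    def test_retained_hits_are_subset_of_input(self, rng):
        groups = tuples_to_groups(random_hits(rng, n_hits=150, n_reads=30))
        all_hits = {h for g in groups for h in g}
        refined, _ = refine_hits(groups, FilterConfig(strategy="best_n", n=2))
        assert all(h in all_hits for g in refined for h in g)

    def test_best_dominance(self, rng):
        groups = tuples_to_groups(random_hits(rng, n_hits=150, n_reads=30))
        refined, _ = refine_hits(groups, FilterConfig())
        for g in refined:
            top = max(h.bit_score for h in g)
            assert all(h.bit_score == top for h in g)

    def test_monotonicity_best_subset_of_best_n(self, rng):
        groups = tuples_to_groups(random_hits(rng, n_hits=200, n_reads=40))
        best, _ = refine_hits(groups, FilterConfig())
        prev = {g.query_id: genes_of(g) for g in best}
        for n in (1, 2, 4):
            bn, _ = refine_hits(groups, FilterConfig(strategy="best_n", n=n))
            cur = {g.query_id: genes_of(g) for g in bn}
            assert set(prev) == set(cur)
            for qid in prev:
                assert prev[qid] <= cur[qid]
            prev = cur

    def test_empty_stream(self):
        refined, summary = refine_hits([], FilterConfig())
        assert refined == []
        assert summary.rows["sample"]["reads_in"] == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    scores=st.lists(
        st.sampled_from([40.0, 50.0, 50.0, 60.0, 72.5, 90.0]),
        min_size=1,
        max_size=8,
    ),
    n=st.integers(min_value=1, max_value=4),
)
def test_best_n_result_properties(scores, n):
    """best_n keeps at least min(n, genes) genes, every kept score
    dominates every dropped score, and boundary ties are never split."""
    group = make_group("r1", *[(f"g{i}", s) for i, s in enumerate(scores)])
    out = select_best_n_matches(group, n)
    kept = {h.subject_id: h.bit_score for h in out}
    dropped = {f"g{i}": s for i, s in enumerate(scores) if f"g{i}" not in kept}
    assert len(kept) >= min(n, len(scores))
    if dropped:
        assert min(kept.values()) > max(dropped.values())
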