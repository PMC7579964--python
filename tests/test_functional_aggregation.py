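import random

import pytest

from readfunc.abundance_profiling import AbundanceProfile, ProfileError
from readfunc.functional_aggregation import (
    UNMAPPED_ID,
    FeatureMapping,
    MappingError,
    UnmappedPolicy,
    aggregate,
    aggregate_chain,
    read_mapping_table,
)

from .oracles import brute_aggregate


def random_mapping(rng, sources, targets, multi_rate=0.4):
    pairs = {}
    for s in sources:
        if rng.random() < 0.15:
            continue  # leave some sources unmapped
        k = 2 if rng.random() < multi_rate else 1
        pairs[s] = tuple(rng.sample(targets, k))
    return pairs


class TestMappingTable:
    def test_single_line(self, tmp_path):
        p = tmp_path / "m.tab"
        p.write_text("g1\tK00001\n")
        m = read_mapping_table(p, "gene", "ortholog")
        assert m.pairs == {"g1": ("K00001",)}

    def test_many_to_many(self, tmp_path):
        p = tmp_path / "m.tab"
        p.write_text("g1\tK1\ng1\tK2\ng2\tK1\n")
        m = read_mapping_table(p, "gene", "ortholog")
        assert m.pairs == {"g1": ("K1", "K2"), "g2": ("K1",)}

    def test_duplicates_kept_once_with_warning(self, tmp_path, caplog, rng):
        lines = []
        expected = {}
        for i in range(100):
            s, t = f"g{i % 30}", f"K{rng.randrange(10)}"
            lines.append(f"{s}\t{t}")
            expected.setdefault(s, [])
            if t not in expected[s]:
                expected[s].append(t)
        lines += lines[:10]  # 10% duplicate lines
        p = tmp_path / "m.tab"
        p.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            m = read_mapping_table(p, "gene", "ortholog")
        assert {s: set(ts) for s, ts in m.pairs.items()} == {
            s: set(ts) for s, ts in expected.items()
        }
        assert "duplicate pair" in caplog.text

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "m.tab"
        p.write_text("g1\tK1\ng2\n")
        with pytest.raises(MappingError, match="m.tab:2"):
            read_mapping_table(p, "gene", "ortholog")

    def test_comments_skipped(self, tmp_path):
        p = tmp_path / "m.tab"
        p.write_text("# gene\tko\ng1\tK1\n")
        assert read_mapping_table(p, "gene", "ortholog").pairs == {"g1": ("K1",)}


class TestAggregate:
    def test_even_split_across_two_orthologs(self):
        profile = AbundanceProfile("gene", {("g1", "s"): 1.0})
        mapping = FeatureMapping("gene", "ortholog", {"g1": ("K1", "K2")})
        out, _ = aggregate(profile, mapping)
        assert out.values == {("K1", "s"): 0.5, ("K2", "s"): 0.5}

    def test_identity_mapping_is_identity(self, rng):
        values = {(f"g{i}", "s"): rng.uniform(0.1, 5) for i in range(10)}
        profile = AbundanceProfile("gene", dict(values))
        mapping = FeatureMapping(
            "gene", "ortholog", {f"g{i}": (f"g{i}",) for i in range(10)}
        )
        out, _ = aggregate(profile, mapping)
        assert out.values == pytest.approx(values)

    @pytest.mark.parametrize("split", ["even", "copy"])
    def test_matches_brute_force_oracle(self, rng, split):
        genes = [f"g{i}" for i in range(30)]
        kos = [f"K{i}" for i in range(8)]
        pairs = random_mapping(rng, genes, kos)
        column = {g: rng.uniform(0.1, 10) for g in genes}
        profile = AbundanceProfile(
            "gene", {(g, "s"): v for g, v in column.items()}
        )
        mapping = FeatureMapping("gene", "ortholog", pairs)
        out, summary = aggregate(
            profile, mapping, UnmappedPolicy("collect"), split
        )
        expected, unmapped = brute_aggregate(column, pairs, "collect", split)
        assert {f: v for (f, _), v in out.values.items()} == pytest.approx(expected)
        assert summary.rows["s"]["unmapped_mass"] == pytest.approx(unmapped)

    def test_mass_conservation_collect(self, rng):
        genes = [f"g{i}" for i in range(40)]
        pairs = random_mapping(rng, genes, [f"K{i}" for i in range(6)])
        profile = AbundanceProfile(
            "gene", {(g, "s"): rng.uniform(0.1, 10) for g in genes}
        )
        mapping = FeatureMapping("gene", "ortholog", pairs)
        out, _ = aggregate(profile, mapping, UnmappedPolicy("collect"), "even")
        total = profile.sample_total("s")
        assert out.sample_total("s") == pytest.approx(total, abs=1e-9 * total)

    def test_drop_mode_accounts_for_dropped_mass(self, rng):
        genes = [f"g{i}" for i in range(40)]
        pairs = random_mapping(rng, genes, [f"K{i}" for i in range(6)])
        profile = AbundanceProfile(
            "gene", {(g, "s"): rng.uniform(0.1, 10) for g in genes}
        )
        mapping = FeatureMapping("gene", "ortholog", pairs)
        out, summary = aggregate(profile, mapping, UnmappedPolicy("drop"), "even")
        dropped = summary.rows["s"]["dropped_mass"]
        assert out.sample_total("s") + dropped == pytest.approx(
            profile.sample_total("s")
        )

    def test_linearity(self, rng):
        genes = [f"g{i}" for i in range(15)]
        pairs = random_mapping(rng, genes, ["K1", "K2", "K3"])
        mapping = FeatureMapping("gene", "ortholog", pairs)
        a = AbundanceProfile("gene", {(g, "s"): rng.uniform(0.1, 5) for g in genes})
        b = AbundanceProfile("gene", {(g, "s"): rng.uniform(0.1, 5) for g in genes})
        summed = AbundanceProfile(
            "gene", {k: a.values[k] + b.values[k] for k in a.values}
        )
        out_sum, _ = aggregate(summed, mapping)
        out_a, _ = aggregate(a, mapping)
        out_b, _ = aggregate(b, mapping)
        for key in out_sum.values:
            assert out_sum.values[key] == pytest.approx(
                out_a.values.get(key, 0.0) + out_b.values.get(key, 0.0)
            )

    def test_level_mismatch(self):
        profile = AbundanceProfile("ortholog", {("K1", "s"): 1.0})
        mapping = FeatureMapping("gene", "ortholog", {"g1": ("K1",)})
        with pytest.raises(ProfileError, match="level"):
            aggregate(profile, mapping)

    def test_reserved_target_rejected(self):
        profile = AbundanceProfile("gene", {("g1", "s"): 1.0})
        mapping = FeatureMapping("gene", "ortholog", {"g1": (UNMAPPED_ID,)})
        with pytest.raises(MappingError, match="reserved"):
            aggregate(profile, mapping)


class TestChain:
    def test_chain_of_identities(self):
        gene = AbundanceProfile("gene", {("g1", "s"): 2.0})
        g2o = FeatureMapping("gene", "ortholog", {"g1": ("K1",)})
        o2m = FeatureMapping("ortholog", "module", {"K1": ("M1",)})
        o2p = FeatureMapping("ortholog", "pathway", {"K1": ("P1",)})
        orth, mod, path = aggregate_chain(gene, g2o, o2m, o2p)
        assert orth.values == {("K1", "s"): 2.0}
        assert mod.values == {("M1", "s"): 2.0}
        assert path.values == {("P1", "s"): 2.0}

    def test_ko_in_two_pathways_splits_mass(self):
        gene = AbundanceProfile("gene", {("g1", "s"): 1.0})
        g2o = FeatureMapping("gene", "ortholog", {"g1": ("K1",)})
        o2m = FeatureMapping("ortholog", "module", {"K1": ("M1",)})
        o2p = FeatureMapping("ortholog", "pathway", {"K1": ("P1", "P2")})
        _, _, path = aggregate_chain(gene, g2o, o2m, o2p)
        assert path.values == {("P1", "s"): 0.5, ("P2", "s"): 0.5}

    def test_full_chain_matches_stepwise_oracle(self, rng):
        genes = [f"g{i}" for i in range(25)]
        kos = [f"K{i}" for i in range(8)]
        g2o_pairs = random_mapping(rng, genes, kos)
        o2m_pairs = random_mapping(rng, kos, ["M1", "M2", "M3"], multi_rate=0.3)
        o2p_pairs = random_mapping(rng, kos, ["P1", "P2"], multi_rate=0.3)
        column = {g: rng.uniform(0.1, 10) for g in genes}
        gene_profile = AbundanceProfile(
            "gene", {(g, "s"): v for g, v in column.items()}
        )
        orth, mod, path = aggregate_chain(
            gene_profile,
            FeatureMapping("gene", "ortholog", g2o_pairs),
            FeatureMapping("ortholog", "module", o2m_pairs),
            FeatureMapping("ortholog", "pathway", o2p_pairs),
        )
        e_orth, _ = brute_aggregate(column, g2o_pairs)
        # UNMAPPED carries through unchanged at the next levels
        e_mod, _ = brute_aggregate(
            {k: v for k, v in e_orth.items() if k != "UNMAPPED"}, o2m_pairs
        )
        e_path, _ = brute_aggregate(
            {k: v for k, v in e_orth.items() if k != "UNMAPPED"}, o2p_pairs
        )
        for label, got, exp in (
            ("ortholog", orth, e_orth),
            ("module", mod, e_mod),
            ("pathway", path, e_path),
        ):
            got_col = {f: v for (f, _), v in got.values.items()}
            if label != "ortholog" and "UNMAPPED" in e_orth:
                exp = dict(exp)
                exp["UNMAPPED"] = exp.get("UNMAPPED", 0.0) + e_orth["UNMAPPED"]
            assert got_col == pytest.approx(exp), label
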