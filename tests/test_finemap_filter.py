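import numpy as np
import pandas as pd
import pytest

from qtlcurator import finemap_filter as ff


def cs_frame(members: dict[str, list[str]], z=None, pip=None, trait_of=None):
    """Build a credible-set member table from {cs_id: [variant, ...]}."""
    rows = []
    for cs_id, variants in members.items():
        trait = trait_of[cs_id] if trait_of else cs_id.rsplit("_L", 1)[0]
        for k, v in enumerate(variants):
            rows.append(
                {
                    "molecular_trait_id": trait,
                    "molecular_trait_object_id": "geneA",
                    "cs_id": cs_id,
                    "variant": v,
                    "chromosome": "chr1",
                    "position": 100 + k,
                    "ref": "A",
                    "alt": "G",
                    "pip": (pip or {}).get(cs_id, [0.5] * len(variants))[k],
                    "z": (z or {}).get(cs_id, [5.0] * len(variants))[k],
                }
            )
    return pd.DataFrame(rows)


def components_fixpoint_oracle(members: dict[str, set[str]]) -> list[set[str]]:
    """Repeated pairwise merging until no two groups share a variant."""
    groups = [({cs}, set(vs)) for cs, vs in members.items()]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i][1] & groups[j][1]:
                    groups[i] = (
                        groups[i][0] | groups[j][0],
                        groups[i][1] | groups[j][1],
                    )
                    groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    return [g[0] for g in groups]


class TestFilterCredibleSets:
    def test_low_z_strict_boundary(self):
        cs = cs_frame(
            {"a_L1": ["v1", "v2"], "b_L1": ["v3"]},
            z={"a_L1": [2.1, -2.99], "b_L1": [3.0]},
        )
        surviving, discarded = ff.filter_credible_sets(cs)
        assert discarded["cs_id"].tolist() == ["a_L1"]
        assert discarded["reason"].tolist() == ["low_z"]
        assert set(surviving["cs_id"]) == {"b_L1"}

    def test_size_strict_boundary(self):
        cs = cs_frame(
            {
                "big_L1": [f"v{i}" for i in range(201)],
                "ok_L1": [f"w{i}" for i in range(200)],
            },
            z={"big_L1": [10.0] * 201, "ok_L1": [3.0] * 200},
        )
        surviving, discarded = ff.filter_credible_sets(cs)
        assert discarded["cs_id"].tolist() == ["big_L1"]
        assert discarded["reason"].tolist() == ["oversized"]
        assert set(surviving["cs_id"]) == {"ok_L1"}

    def test_both_reasons_recorded(self):
        cs = cs_frame(
            {"bad_L1": [f"v{i}" for i in range(201)]},
            z={"bad_L1": [1.0] * 201},
        )
        _, discarded = ff.filter_credible_sets(cs)
        assert discarded["reason"].iloc[0] == "low_z,oversized"


class TestBuildComponents:
    def test_shared_variant_joins(self):
        cs = cs_frame({"A_L1": ["v1", "v2"], "B_L1": ["v2", "v3"], "C_L1": ["v4"]})
        part = ff.build_components(cs, "geneA")
        sets = [set(c.cs_ids) for c in part.components]
        assert {"A_L1", "B_L1"} in sets and {"C_L1"} in sets

    def test_disjoint_sets_stay_singleton(self):
        cs = cs_frame({"A_L1": ["v1"], "B_L1": ["v2"], "C_L1": ["v3"]})
        part = ff.build_components(cs, "geneA")
        assert len(part.components) == 3

    def test_chain_closure_is_transitive(self):
        cs = cs_frame(
            {"A_L1": ["v1", "v2"], "B_L1": ["v2", "v3"], "C_L1": ["v3", "v4"]}
        )
        part = ff.build_components(cs, "geneA")
        assert len(part.components) == 1
        assert set(part.components[0].cs_ids) == {"A_L1", "B_L1", "C_L1"}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_fixpoint_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_cs = int(rng.integers(2, 50))
        universe = [f"v{i}" for i in range(60)]
        members = {
            f"cs{i}_L1": set(
                rng.choice(universe, size=rng.integers(1, 6), replace=False)
            )
            for i in range(n_cs)
        }
        cs = cs_frame({k: sorted(v) for k, v in members.items()})
        part = ff.build_components(cs, "geneA")
        ours = sorted(sorted(c.cs_ids) for c in part.components)
        oracle = sorted(sorted(g) for g in components_fixpoint_oracle(members))
        assert ours == oracle

    def test_row_order_invariance(self, rng):
        cs = cs_frame(
            {"A_L1": ["v1", "v2"], "B_L1": ["v2"], "C_L1": ["v5", "v6"]}
        )
        shuffled = cs.sample(frac=1, random_state=3).reset_index(drop=True)
        p1 = ff.build_components(cs, "g")
        p2 = ff.build_components(shuffled, "g")
        assert [c.cs_ids for c in p1.components] == [c.cs_ids for c in p2.components]


class TestSelectTags:
    def test_highest_pip_wins(self):
        cs = cs_frame(
            {"traitA_L1": ["v1"], "traitB_L1": ["v1"]},
            pip={"traitA_L1": [0.93], "traitB_L1": [0.88]},
        )
        part = ff.select_tags(ff.build_components(cs, "g"), cs)
        assert part.components[0].tag_trait == "traitA"

    def test_exact_tie_breaks_lexicographically(self):
        cs = cs_frame(
            {"zeta_L1": ["v1"], "alpha_L1": ["v1"]},
            pip={"zeta_L1": [0.9], "alpha_L1": [0.9]},
        )
        part = ff.select_tags(ff.build_components(cs, "g"), cs)
        assert part.components[0].tag_trait == "alpha"

    def test_singleton_component_tags_itself(self):
        cs = cs_frame({"only_L1": ["v9"]})
        part = ff.select_tags(ff.build_components(cs, "g"), cs)
        assert part.components[0].tag_trait == "only"

    def test_two_signals_of_one_trait_can_both_tag(self):
        cs = cs_frame(
            {"t1_L1": ["v1"], "t1_L2": ["v9"]},
            trait_of={"t1_L1": "t1", "t1_L2": "t1"},
        )
        part = ff.select_tags(ff.build_components(cs, "g"), cs)
        assert len(part.components) == 2
        assert all(c.tag_trait == "t1" for c in part.components)


def sumstats_for(traits, n_variants=1000):
    rows = []
    for t in traits:
        for i in range(n_variants):
            rows.append(
                {
                    "molecular_trait_id": t,
                    "molecular_trait_object_id": "geneA",
                    "variant": f"chr1_{100 + i}_A_G",
                    "chromosome": "chr1",
                    "position": 100 + i,
                    "ref": "A",
                    "alt": "G",
                    "maf": 0.3,
                    "beta": 0.0,
                    "se": 1.0,
                    "pvalue": 1.0,
                    "ac": 10,
                    "an": 100,
                }
            )
    return pd.DataFrame(rows)


class TestFilterSumstats:
    def test_reduction_arithmetic(self):
        traits = [f"t{i}" for i in range(20)]
        ss = sumstats_for(traits)
        cs = cs_frame({"t0_L1": ["v1"]})
        part = ff.select_tags(ff.build_components(cs, "geneA"), cs)
        out, report = ff.filter_sumstats(ss, part)
        assert report["reduction"] == pytest.approx(0.95)
        assert set(out["molecular_trait_id"]) == {"t0"}

    def test_every_trait_tagged_means_no_reduction(self):
        ss = sumstats_for(["a", "b"], n_variants=10)
        cs = cs_frame({"a_L1": ["v1"], "b_L1": ["v2"]})
        part = ff.select_tags(ff.build_components(cs, "geneA"), cs)
        _, report = ff.filter_sumstats(ss, part)
        assert report["reduction"] == 0.0

    def test_no_surviving_cs_drops_everything(self):
        ss = sumstats_for(["a"], n_variants=10)
        cs = cs_frame({"a_L1": ["v1"]}, z={"a_L1": [1.0]})  # fails z filter
        out, part, report = ff.prune_group(ss, cs, "geneA")
        assert len(out) == 0 and report["rows_out"] == 0

    def test_missing_tag_trait_is_error(self):
        ss = sumstats_for(["other"], n_variants=5)
        cs = cs_frame({"ghost_L1": ["v1"]})
        part = ff.select_tags(ff.build_components(cs, "geneA"), cs)
        with pytest.raises(KeyError, match="ghost"):
            ff.filter_sumstats(ss, part)

    def test_retained_traits_bounded_by_components(self):
        cs = cs_frame(
            {"a_L1": ["v1", "v2"], "b_L1": ["v2"], "c_L1": ["v7"]},
        )
        part = ff.select_tags(ff.build_components(cs, "geneA"), cs)
        assert len(part.tag_traits) <= len(part.components)


def test_end_to_end_reduction_on_correlated_group():
    """Twenty correlated traits sharing one signal keep a single tag trait."""
    from qtlcurator.cis import group_permutation
    from qtlcurator.simulate import (
        simulate_finemap_outputs,
        simulate_genotypes,
        simulate_trait_group,
    )

    dos = simulate_genotypes(300, 25, maf=0.3, ld_block_size=5, seed=21)
    tm, truth = simulate_trait_group(
        dos, causal_index=12, n_traits=20, lead_effect=1.0, decoy_effect=0.6,
        seed=22,
    )
    res = group_permutation(
        tm.values, list(tm.traits["trait_id"]), dos, n_perm=100, seed=23,
        group_id="geneA",
    )
    cs, _ = simulate_finemap_outputs(res.sumstats)
    filtered, part, report = ff.prune_group(
        res.sumstats.drop(columns="note"), cs, "geneA"
    )
    assert report["reduction"] >= 0.9
    assert truth.causal_variant in part.components[0].variants
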