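"""Closed-reference growth, de novo single linkage, pseudotaxon naming and
the nested partition invariants."""

import numpy as np
import pytest

from conftest import DictScorer, flat_cutoff_table
from mycocurate.assigner import AssignmentResult
from mycocurate.clusterer import (
    closed_reference_pass,
    denovo_single_linkage,
    name_pseudotaxon,
    nested_cluster,
)
from mycocurate.io_formats import RANKS, Lineage


def assignment(asv_id, *names):
    return AssignmentResult(asv_id=asv_id, lineage=Lineage.from_names(list(names)))


class TestClosedReference:
    def test_identity_joins_first_pass(self):
        scorer = DictScorer({("x", "core1"): 1.0})
        joined, residue = closed_reference_pass(
            ["x"], {"G": ["core1"]}, 0.95, None, scorer
        )
        assert joined == {"x": "G"} and residue == []

    def test_chain_joins_via_second_pass(self):
        """b is below cutoff to the seed but reaches it through a."""
        scorer = DictScorer(
            {("a", "core1"): 0.99, ("b", "a"): 0.99, ("b", "core1"): 0.90}
        )
        joined, residue = closed_reference_pass(
            ["a", "b"], {"G": ["core1"]}, 0.95, None, scorer
        )
        assert joined == {"a": "G", "b": "G"}
        assert residue == []

    def test_below_cutoff_remains_unassigned(self):
        scorer = DictScorer({("x", "core1"): 0.90})
        joined, residue = closed_reference_pass(
            ["x"], {"G": ["core1"]}, 0.95, None, scorer
        )
        assert joined == {} and residue == ["x"]

    def test_tie_goes_to_highest_score_then_larger_core(self):
        scorer = DictScorer(
            {
                ("x", "g1"): 0.97,
                ("x", "h1"): 0.99,
                ("y", "g1"): 0.97,
                ("y", "g2"): 0.97,
                ("y", "h1"): 0.97,
            }
        )
        cores = {"G": ["g1", "g2"], "H": ["h1"]}
        joined, _ = closed_reference_pass(["x", "y"], cores, 0.95, None, scorer)
        assert joined["x"] == "H"  # higher score wins
        assert joined["y"] == "G"  # equal scores: larger core wins

    def test_empty_cores_returns_all(self):
        joined, residue = closed_reference_pass(
            ["b", "a"], {}, 0.95, None, DictScorer({})
        )
        assert joined == {} and residue == ["a", "b"]


class TestDenovoSingleLinkage:
    def test_transitive_closure(self):
        scorer = DictScorer({("a", "b"): 0.99, ("b", "c"): 0.99, ("a", "c"): 0.90})
        comps = denovo_single_linkage(["c", "a", "b"], 0.95, None, scorer)
        assert comps == [["a", "b", "c"]]

    def test_all_below_cutoff_singletons(self):
        comps = denovo_single_linkage(["b", "a"], 0.95, None, DictScorer({}))
        assert comps == [["a"], ["b"]]

    def test_matches_brute_force_on_random_instances(self, rng):
        """Connected components vs an independent union-find oracle on 100
        random <=50-sequence instances."""

        def union_find_components(ids, edges):
            parent = {i: i for i in ids}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in edges:
                parent[find(a)] = find(b)
            groups = {}
            for i in ids:
                groups.setdefault(find(i), set()).add(i)
            return {frozenset(g) for g in groups.values()}

        for _ in range(100):
            n = int(rng.integers(2, 51))
            ids = [f"s{i:02d}" for i in range(n)]
            scores = {}
            edges = []
            cutoff = 0.95
            for i in range(n):
                for j in range(i + 1, n):
                    s = float(rng.uniform(0.85, 1.0))
                    scores[(ids[i], ids[j])] = s
                    if s >= cutoff:
                        edges.append((ids[i], ids[j]))
            comps = denovo_single_linkage(ids, cutoff, None, DictScorer(scores))
            assert {frozenset(c) for c in comps} == union_find_components(ids, edges)


class TestPseudotaxonNaming:
    def test_example_form(self):
        parent = Lineage.from_names(["Fungi", "Ascomycota"])
        assert (
            name_pseudotaxon("class", parent, 1234) == "pseudo_class_Ascomycota_1234"
        )

    def test_anchor_skips_pseudo_parents(self):
        parent = Lineage.from_names(
            ["Fungi", "Basidiomycota", "Agaricomycetes", "Agaricales",
             "pseudo_family_Agaricales_3", "pseudo_genus_Agaricales_7"]
        )
        assert name_pseudotaxon("species", parent, 2) == "pseudo_species_Agaricales_2"

    def test_serials_unique_within_run(self):
        from mycocurate.clusterer import PseudotaxonNamer

        namer = PseudotaxonNamer()
        serials = [namer.next_serial("species") for _ in range(5)]
        assert len(set(serials)) == 5


class TestNestedCluster:
    def cortinarioid(self, *tail):
        return ("Fungi", "Basidiomycota", "Agaricomycetes", "Agaricales",
                "Cortinariaceae", "Cortinarius", *tail)

    def test_shared_species_name_same_otu(self):
        assignments = {
            "a": assignment("a", *self.cortinarioid("Cortinarius_sp01")),
            "b": assignment("b", *self.cortinarioid("Cortinarius_sp01")),
        }
        _, otus = nested_cluster(
            ["a", "b"], assignments, flat_cutoff_table(0.9), DictScorer({})
        )
        assert len(otus) == 1
        assert sorted(otus[0].member_asv_ids) == ["a", "b"]
        assert not otus[0].lineage.pseudotaxon[6]

    def test_unidentified_pair_forms_pseudo_species_otu(self):
        assignments = {
            "a": assignment("a", *self.cortinarioid()),
            "b": assignment("b", *self.cortinarioid()),
        }
        table = flat_cutoff_table(0.9, per_rank={"species": 0.985})
        scorer = DictScorer({("a", "b"): 0.99})
        _, otus = nested_cluster(["a", "b"], assignments, table, scorer)
        assert len(otus) == 1
        name = otus[0].lineage.name_at("species")
        assert name.startswith("pseudo_species_Cortinarius_")
        assert otus[0].lineage.pseudotaxon[6]

    def test_genus_only_asv_below_cutoff_is_singleton_pseudo_species(self):
        assignments = {
            "a": assignment("a", *self.cortinarioid("Cortinarius_sp01")),
            "x": assignment("x", *self.cortinarioid()),
        }
        table = flat_cutoff_table(0.9, per_rank={"species": 0.985})
        scorer = DictScorer({("a", "x"): 0.95})  # congener but below cutoff
        _, otus = nested_cluster(["a", "x"], assignments, table, scorer)
        assert len(otus) == 2
        pseudo = next(o for o in otus if "x" in o.member_asv_ids)
        assert pseudo.lineage.name_at("species").startswith(
            "pseudo_species_Cortinarius_"
        )

    def test_partition_and_nesting_invariants(self, rng):
        ids = [f"a{i:02d}" for i in range(20)]
        assignments = {}
        for i, asv in enumerate(ids):
            if i < 8:
                assignments[asv] = assignment(
                    asv, *self.cortinarioid(f"Cortinarius_sp{i % 3:02d}")
                )
            elif i < 14:
                assignments[asv] = assignment(asv, *self.cortinarioid())
            else:
                assignments[asv] = assignment(asv)  # fully unidentified
        scores = {}
        for i in range(20):
            for j in range(i + 1, 20):
                scores[(ids[i], ids[j])] = float(rng.uniform(0.80, 1.0))
        table = flat_cutoff_table(0.9, per_rank={"species": 0.97})
        by_rank, otus = nested_cluster(
            ids, assignments, table, DictScorer(scores)
        )
        for rank in RANKS:
            members = [m for c in by_rank[rank] for m in c.member_asv_ids]
            assert sorted(members) == sorted(ids)  # partition, no overlap
        # nesting: every species cluster sits inside one genus cluster
        genus_of = {
            m: c.cluster_id for c in by_rank["genus"] for m in c.member_asv_ids
        }
        for c in by_rank["species"]:
            assert len({genus_of[m] for m in c.member_asv_ids}) == 1

    def test_order_invariance_with_stable_names(self, rng):
        ids = [f"a{i:02d}" for i in range(15)]
        assignments = {a: assignment(a, *self.cortinarioid()) for a in ids}
        scores = {}
        for i in range(15):
            for j in range(i + 1, 15):
                scores[(ids[i], ids[j])] = float(rng.uniform(0.90, 1.0))
        table = flat_cutoff_table(0.9, per_rank={"species": 0.97})
        scorer = DictScorer(scores)
        _, otus1 = nested_cluster(list(ids), assignments, table, scorer)
        shuffled = list(ids)
        np.random.default_rng(5).shuffle(shuffled)
        _, otus2 = nested_cluster(shuffled, assignments, table, scorer)
        key = lambda o: (o.lineage.names, tuple(o.member_asv_ids))
        assert sorted(map(key, otus1)) == sorted(map(key, otus2))

    def test_representative_is_most_abundant_member(self):
        assignments = {
            "a": assignment("a", *self.cortinarioid("Cortinarius_sp01")),
            "b": assignment("b", *self.cortinarioid("Cortinarius_sp01")),
        }
        _, otus = nested_cluster(
            ["a", "b"],
            assignments,
            flat_cutoff_table(0.9),
            DictScorer({}),
            totals={"a": 5, "b": 50},
        )
        assert otus[0].representative_asv_id == "b"
        assert otus[0].total_count == 55

    def test_nonfungal_root_segregated_and_droppable(self):
        assignments = {
            "f": assignment("f", *self.cortinarioid("Cortinarius_sp01")),
            "n": assignment("n"),  # unidentified at kingdom
        }
        table = flat_cutoff_table(0.9)
        _, keep = nested_cluster(["f", "n"], assignments, table, DictScorer({}))
        assert len(keep) == 2
        _, dropped = nested_cluster(
            ["f", "n"], assignments, table, DictScorer({}), drop_nonfungal_root=True
        )
        assert len(dropped) == 1 and dropped[0].member_asv_ids == ["f"]
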