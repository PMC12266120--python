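"""Collection overlap, frequency ranking, and hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact, hypergeom

from parabio_rescue.datatypes import DEGRecord, GeneSetCollection, ValidationError
from parabio_rescue.prioritize import (
    frequency_rank,
    hypergeom_enrich,
    overlap_with_collections,
)


def rec(gene, ct, lfc=1.0, contrast="Aged"):
    return DEGRecord(
        gene, ct, contrast, lfc, 0.001, 0.01, "up" if lfc > 0 else "down"
    )


class TestOverlap:
    def test_disjoint_sets_empty(self):
        coll = GeneSetCollection("c", {"s": ["x", "y"]})
        assert overlap_with_collections({"a", "b"}, [coll]) == {}

    def test_provenance_bookkeeping(self):
        colls = [
            GeneSetCollection("atlas", {"s1": ["g1", "g2"]}),
            GeneSetCollection("genage", {"s2": ["g1"]}),
            GeneSetCollection("cellage", {"s3": ["g9"]}),
        ]
        out = overlap_with_collections({"g1", "g3"}, colls)
        assert set(out) == {"g1"}
        assert sorted(out["g1"]) == [("atlas", "s1"), ("genage", "s2")]

    def test_empty_query_warns_not_errors(self):
        coll = GeneSetCollection("c", {"s": ["x"]})
        with pytest.warns(UserWarning):
            assert overlap_with_collections(set(), [coll]) == {}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        colls = []
        for c in range(5):
            sets = {
                f"s{c}_{k}": list(rng.choice(genes, size=rng.integers(1, 30)))
                for k in range(10)
            }
            colls.append(GeneSetCollection(f"coll{c}", sets))
        query = set(rng.choice(genes, size=60, replace=False))
        ours = overlap_with_collections(query, colls)
        # independent double-loop membership scan
        expected = {}
        for coll in colls:
            for set_name, members in coll.sets.items():
                for g in query:
                    if g in members:
                        expected.setdefault(g, set()).add((coll.name, set_name))
        assert {g: set(v) for g, v in ours.items()} == expected


class TestFrequencyRank:
    def test_counts_distinct_cell_types(self):
        tables = {f"T{i}": [rec("g1", f"T{i}")] for i in range(1, 6)}
        tables["T1"].append(rec("g1", "T1", contrast="Ahet"))  # same type twice
        for i in range(6, 12):
            tables[f"T{i}"] = []
        overlap = {"g1": [("atlas", "s")]}
        table = frequency_rank(overlap, tables)
        assert table["n_cell_types"].iloc[0] == 5

    def test_tie_break_deterministic(self):
        tables = {
            "T1": [rec("a", "T1", lfc=0.5), rec("b", "T1", lfc=2.0)],
            "T2": [rec("a", "T2", lfc=0.5), rec("b", "T2", lfc=2.0)],
        }
        overlap = {"a": [("c", "s")], "b": [("c", "s")]}
        t1 = frequency_rank(overlap, tables)
        t2 = frequency_rank(overlap, tables)
        assert list(t1["gene"]) == ["b", "a"]  # larger summed |log2FC| first
        assert t1.equals(t2)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            tables = {}
            for t in range(6):
                picked = rng.choice(genes, size=rng.integers(0, 20), replace=False)
                tables[f"T{t}"] = [rec(g, f"T{t}") for g in picked]
            overlap = {g: [("c", "s")] for g in rng.choice(genes, size=25, replace=False)}
            table = frequency_rank(overlap, tables).set_index("gene")
            for g in overlap:
                expected = sum(
                    any(r.gene == g for r in recs) for recs in tables.values()
                )
                if expected == 0:
                    assert g not in table.index
                else:
                    assert table.loc[g, "n_cell_types"] == expected

    def test_hub_gene_recovery(self, small_processed):
        # defaults plant the hub in every type's rescued program; it should
        # lead the candidate table
        from parabio_rescue.deg import find_all_degs
        from parabio_rescue.rescue import classify_cell_type, pr_gene_union

        cm, ann, truth = small_processed
        deg_map = find_all_degs(cm, ann, contrasts=["Aged", "Ahet"])
        types = sorted({ct for ct, _ in deg_map})
        cls = []
        for t in types:
            c = classify_cell_type(
                deg_map.get((t, "Aged"), []), deg_map.get((t, "Ahet"), []), []
            )
            c.cell_type = t
            cls.append(c)
        overlap = overlap_with_collections(
            pr_gene_union(cls), [truth.aging_collection()]
        )
        scope = {
            t: deg_map.get((t, "Aged"), []) + deg_map.get((t, "Ahet"), []) for t in types
        }
        table = frequency_rank(overlap, scope)
        assert table["gene"].iloc[0] == truth.hub_gene
        assert table["n_cell_types"].iloc[0] == len(types)


class TestHypergeom:
    def test_worked_case(self):
        # N=10, K=5, n=4, overlap 3: [C(5,3)C(5,1) + C(5,4)C(5,0)] / C(10,4)
        universe = {f"u{i}" for i in range(10)}
        ann_set = {f"u{i}" for i in range(5)}
        query = {"u0", "u1", "u2", "u5"}
        k, p = hypergeom_enrich(query, ann_set, universe)
        assert k == 3
        assert p == pytest.approx(55 / 210, abs=1e-12)

    def test_zero_overlap_p_one(self):
        universe = {f"u{i}" for i in range(10)}
        k, p = hypergeom_enrich({"u9"}, {"u0"}, universe)
        assert (k, p) == (0, 1.0)

    def test_degenerate_full_overlap(self):
        s = {f"u{i}" for i in range(6)}
        k, p = hypergeom_enrich(s, s, s)
        assert k == 6 and p == 1.0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="alien"):
            hypergeom_enrich({"alien"}, {"u0"}, {"u0", "u1"})

    def test_matches_scipy_and_fisher(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"u{i}" for i in range(N)}
            ann_set = {f"u{i}" for i in range(K)}
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k, p = hypergeom_enrich(query, ann_set, universe)
            assert p == pytest.approx(hypergeom.sf(k - 1, N, K, n), abs=1e-10)
            table = [[k, len(query) - k], [K - k, N - K - (n - k)]]
            assert p == pytest.approx(
                fisher_exact(table, alternative="greater")[1], abs=1e-10
            )
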