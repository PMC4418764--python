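from fractions import Fraction

import numpy as np
import pytest

from mirkey.enrichment import (
    CancerPathwaySet,
    GeneSetAnnotation,
    bh_adjust,
    enrich,
    genes_in_both,
    hypergeom_pvalue,
    read_gmt,
    screen_cancer_pathways,
    select_significant,
    write_gmt,
)

from oracles import bh_stepup, hypergeom_upper_tail_exact


def annotation(term_id, genes, category="GO", name=None):
    return GeneSetAnnotation(
        term_id=term_id,
        term_name=name or term_id,
        category=category,
        genes=frozenset(genes),
    )


class TestHypergeomPvalue:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(0, 5, 10, 100) == 1.0

    def test_exhaustive_draw_is_one(self):
        assert hypergeom_pvalue(4, 4, 10, 10) == 1.0

    def test_documented_enumeration_case(self):
        # C(4,3)C(6,2) + C(4,4)C(6,1) over C(10,5) = 66/252
        expected = Fraction(66, 252)
        assert hypergeom_upper_tail_exact(3, 4, 5, 10) == expected
        assert hypergeom_pvalue(3, 4, 5, 10) == pytest.approx(float(expected), rel=1e-12)

    def test_all_small_configurations_vs_enumeration(self):
        for N in range(13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(hypergeom_upper_tail_exact(k, K, n, N))
                        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                            expected, rel=1e-9, abs=1e-12
                        ), (k, K, n, N)

    def test_nonincreasing_in_k(self):
        previous = 1.1
        for k in range(0, 11):
            p = hypergeom_pvalue(k, 20, 10, 100)
            assert p <= previous + 1e-15
            previous = p

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 11, 5, 10)


class TestBHAdjust:
    def test_twenty_term_toys_vs_hand_stepup(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            p = list(rng.uniform(0, 1, size=20))
            expected_q, expected_reject = bh_stepup(p)
            got_q = bh_adjust(p)
            assert got_q == pytest.approx(expected_q, rel=1e-12)
            # rejection sets agree between q < alpha and the classic step-up
            got_reject = [q < 0.05 for q in got_q]
            # q <= alpha vs strict: handle boundary-free random draws
            assert got_reject == [bool(r) for r in expected_reject]

    def test_q_monotone_with_p_rank(self):
        rng = np.random.default_rng(23)
        p = sorted(rng.uniform(0, 1, size=50))
        q = bh_adjust(p)
        assert all(q1 <= q2 + 1e-15 for q1, q2 in zip(q, q[1:]))

    def test_empty(self):
        assert bh_adjust([]) == []


class TestEnrich:
    def test_query_equals_universe_all_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        annotations = [
            annotation("t1", list(universe)[:10]),
            annotation("t2", list(universe)[5:20]),
        ]
        results = enrich(universe, annotations, universe=universe)
        assert all(r.p == 1.0 for r in results)

    def test_planted_terms_recovered(self):
        from mirkey.synthetic_data import simulate_annotations

        universe = [f"g{i}" for i in range(2000)]
        query = universe[:40]
        hits = 0
        for seed in range(100):
            annotations, truth = simulate_annotations(
                n_terms=100,
                genes_per_term=50,
                enriched_terms={f"TERM{i:04d}": 0.8 for i in range(5)},
                rng_seed=seed,
                query_genes=query,
                universe_genes=universe,
            )
            results = enrich(query, annotations, universe=universe)
            top5 = {r.term_id for r in results[:5]}
            if top5 == {f"TERM{i:04d}" for i in range(5)}:
                hits += 1
        assert hits >= 95

    def test_pq_vector_vs_oracle_on_toy(self):
        rng = np.random.default_rng(31)
        universe = [f"g{i}" for i in range(60)]
        query = list(rng.choice(universe, size=15, replace=False))
        annotations = [
            annotation(f"t{i:02d}", rng.choice(universe, size=12, replace=False))
            for i in range(20)
        ]
        results = enrich(query, annotations, universe=universe)
        qset = set(query)
        tested = []
        for a in sorted(annotations, key=lambda a: a.term_id):
            k = len(a.genes & qset)
            if k >= 1:
                tested.append(
                    (a.term_id, float(hypergeom_upper_tail_exact(k, len(a.genes), 15, 60)))
                )
        expected_q, _ = bh_stepup([p for _, p in tested])
        expected = {t: (p, q) for (t, p), q in zip(tested, expected_q)}
        assert {r.term_id for r in results} == set(expected)
        for r in results:
            ep, eq = expected[r.term_id]
            assert r.p == pytest.approx(ep, rel=1e-9)
            assert r.q == pytest.approx(eq, rel=1e-9)

    def test_bh_applied_per_category(self):
        universe = [f"g{i}" for i in range(40)]
        go = [annotation("go1", universe[:8], "GO"), annotation("go2", universe[4:12], "GO")]
        kegg = [annotation("k1", universe[:8], "KEGG")]
        results = enrich(universe[:8], go + kegg, universe=universe)
        by_id = {r.term_id: r for r in results}
        # same raw p, but the GO branch adjusts over 2 tests and KEGG over 1
        assert by_id["go1"].p == by_id["k1"].p
        assert by_id["k1"].q == pytest.approx(by_id["k1"].p)
        expected_go_q, _ = bh_stepup([by_id["go1"].p, by_id["go2"].p])
        assert by_id["go1"].q == pytest.approx(expected_go_q[0])
        assert by_id["go2"].q == pytest.approx(expected_go_q[1])

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            enrich([], [annotation("t", ["a"])], universe={"a"})

    def test_query_outside_universe_lists_offenders(self):
        with pytest.raises(ValueError, match="zz"):
            enrich(["zz"], [annotation("t", ["a"])], universe={"a"})

    def test_type_i_error_band_under_null(self):
        rng = np.random.default_rng(47)
        universe = [f"g{i}" for i in range(400)]
        n_sig = n_terms_total = 0
        for _ in range(200):
            annotations = [
                annotation(f"t{i}", rng.choice(universe, size=20, replace=False))
                for i in range(15)
            ]
            query = list(rng.choice(universe, size=25, replace=False))
            results = enrich(query, annotations, universe=universe)
            n_sig += sum(r.q < 0.05 for r in results)
            n_terms_total += len(annotations)
        assert n_sig / n_terms_total <= 0.05 * 1.5


class TestSelectSignificant:
    def test_none_significant_top_view_survives(self):
        results = enrich(
            [f"g{i}" for i in range(30)],
            [annotation(f"t{i}", [f"g{j}" for j in range(30)]) for i in range(3)],
            universe=[f"g{i}" for i in range(30)],
        )
        sel = select_significant(results, alpha=0.05, top_k=2)
        assert sel.significant == ()
        assert len(sel.top) == 2

    def test_alpha_one_selects_all(self):
        results = enrich(
            ["g0"], [annotation("t", ["g0", "g1"])], universe=["g0", "g1", "g2"]
        )
        sel = select_significant(results, alpha=1.0)
        assert len(sel.significant) == len(results)

    def test_randomized_vs_filter_sort_oracle(self):
        from mirkey.enrichment import EnrichmentResult

        rng = np.random.default_rng(53)
        for _ in range(20):
            results = [
                EnrichmentResult(
                    term_id=f"t{i}", term_name="", category="GO",
                    k=1, K=2, n=3, N=10,
                    p=float(rng.uniform()), q=float(rng.uniform()),
                )
                for i in range(15)
            ]
            sel = select_significant(results, alpha=0.3, top_k=5)
            expected_sig = sorted(
                (r for r in results if r.q < 0.3), key=lambda r: (r.p, r.term_id)
            )
            expected_top = sorted(results, key=lambda r: (r.p, r.term_id))[:5]
            assert list(sel.significant) == expected_sig
            assert list(sel.top) == expected_top


class TestGenesInBoth:
    def test_disjoint_empty(self):
        assert genes_in_both([{"a", "b"}], [{"c"}]) == frozenset()

    def test_identical_idempotent(self):
        membership = [{"a", "b"}, {"b", "c"}]
        assert genes_in_both(membership, membership) == {"a", "b", "c"}

    def test_random_vs_set_oracle(self):
        rng = np.random.default_rng(61)
        pool = [f"g{i}" for i in range(50)]
        for _ in range(20):
            go = [set(rng.choice(pool, size=8, replace=False)) for _ in range(4)]
            kegg = [set(rng.choice(pool, size=8, replace=False)) for _ in range(3)]
            expected = set().union(*go) & set().union(*kegg)
            assert genes_in_both(go, kegg) == expected


class TestScreenCancerPathways:
    def test_table2_fixture_counts(self, table2):
        per_mirna = table2.target_lists()
        all_genes = {g for genes in per_mirna.values() for g in genes}
        annotations = [annotation("hsa05200", all_genes, "KEGG", "pathways in cancer")]
        screened = screen_cancer_pathways(
            all_genes, annotations, CancerPathwaySet(), per_mirna
        )
        assert {m: len(g) for m, g in screened.items()} == {
            "miR-199-5p": 53,
            "miR-22": 53,
            "miR-429": 51,
        }

    def test_empty_row_retained(self):
        annotations = [annotation("hsa05200", {"a"}, "KEGG")]
        screened = screen_cancer_pathways(
            {"a"}, annotations, CancerPathwaySet(), {"m1": [], "m2": ["a"]}
        )
        assert screened == {"m1": [], "m2": ["a"]}

    def test_random_three_way_intersection_oracle(self):
        rng = np.random.default_rng(67)
        pool = [f"g{i}" for i in range(40)]
        for _ in range(10):
            cancer = set(rng.choice(pool, size=15, replace=False))
            screen = set(rng.choice(pool, size=20, replace=False))
            targets = {
                f"m{i}": list(rng.choice(pool, size=10, replace=False)) for i in range(3)
            }
            annotations = [annotation("hsa05200", cancer, "KEGG")]
            got = screen_cancer_pathways(
                screen, annotations, CancerPathwaySet(), targets
            )
            for m, tg in targets.items():
                assert got[m] == sorted(set(tg) & screen & cancer)

    def test_unknown_cancer_id_rejected(self):
        with pytest.raises(ValueError):
            screen_cancer_pathways(
                {"a"},
                [annotation("k1", {"a"}, "KEGG")],
                CancerPathwaySet(term_ids=frozenset({"nope"})),
                {},
            )


class TestGmtRoundTrip:
    def test_write_read(self, tmp_path):
        annotations = [
            annotation("t1", {"B", "A"}, "GO", "first term"),
            annotation("t2", {"C"}, "GO", "second term"),
        ]
        path = tmp_path / "toy.gmt"
        write_gmt(annotations, path)
        back = read_gmt(path, "GO")
        assert [(a.term_id, a.term_name, a.genes) for a in back] == [
            ("t1", "first term", frozenset({"A", "B"})),
            ("t2", "second term", frozenset({"C"})),
        ]

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_two\tfields\n")
        with pytest.raises(ValueError):
            read_gmt(path, "GO")

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            annotation("t", [])
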