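from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtlinker.annotation_space import AnnotationSpace, GenericTermPolicy
from gtlinker.enrichment import GeneTermSet, QueryContext
from gtlinker.linker import (
    ElementVector,
    Metagroup,
    build_element_vectors,
    complete_cover,
    cosine_distance_matrix,
    cut_pre_metagroups,
    filter_generic_only,
    greedy_term_merge,
    link_elements,
    score_metagroups,
    ward_tree,
)
from oracles import bh_adjust_enum, ward_merges_enum
from conftest import make_element


def policy(space_id: str, generic: set[str]) -> GenericTermPolicy:
    return GenericTermPolicy(
        space_id=space_id,
        mean_ng=1.0,
        sigma_ng=0.0,
        n_factor=4.0,
        generic_terms=frozenset(generic),
    )


POLICIES = {"S": policy("S", {"gen1", "gen2"})}


class TestFilterGenericOnly:
    def test_all_generic_removed(self):
        e = make_element("E1", {"a"}, {"S::gen1", "S::gen2"}, 0.01)
        assert filter_generic_only([e], POLICIES) == []

    def test_mixed_retained_intact(self):
        e = make_element("E1", {"a"}, {"S::gen1", "S::t1"}, 0.01)
        out = filter_generic_only([e], POLICIES)
        assert out == [e]
        assert out[0].terms == {"S::gen1", "S::t1"}

    def test_empty_input(self):
        assert filter_generic_only([], POLICIES) == []

    def test_unknown_space_errors(self):
        e = make_element("E1", {"a"}, {"X::t1"}, 0.01)
        with pytest.raises(ValueError, match="unknown space"):
            filter_generic_only([e], POLICIES)

    def test_survivors_unchanged(self):
        elements = [
            make_element("E1", {"a"}, {"S::t1"}, 0.01),
            make_element("E2", {"b"}, {"S::gen1"}, 0.02),
            make_element("E3", {"c"}, {"S::t2", "S::gen2"}, 0.03),
        ]
        out = filter_generic_only(elements, POLICIES)
        assert out == [elements[0], elements[2]]


class TestBuildElementVectors:
    def test_literal_mode(self):
        ctx = QueryContext.from_genes(["g1", "g2", "g3", "g4"], 50)
        e = make_element("E1", {"g1", "g2"}, {"S::t"}, 0.01)
        (v,) = build_element_vectors([e], ctx, "literal")
        assert v.coords == pytest.approx([1, 1, 0, 0, 0.04])

    def test_off_mode(self):
        ctx = QueryContext.from_genes(["g1", "g2", "g3", "g4"], 50)
        e = make_element("E1", {"g1", "g2"}, {"S::t"}, 0.01)
        (v,) = build_element_vectors([e], ctx, "off")
        assert v.coords == pytest.approx([1, 1, 0, 0, 0])

    def test_full_query_coverage(self, query8):
        e = make_element("E1", set(query8.query_genes), {"S::t"}, 0.5)
        (v,) = build_element_vectors([e], query8)
        assert (v.coords[: query8.M] == 1).all()
        assert int(v.coords[: query8.M].sum()) == len(e.genes)

    def test_gene_outside_query_errors(self, query8):
        e = make_element("E1", {"zzz"}, {"S::t"}, 0.5)
        with pytest.raises(ValueError, match="not in query"):
            build_element_vectors([e], query8)

    def test_bad_mode(self, query8):
        e = make_element("E1", {"q0"}, {"S::t"}, 0.5)
        with pytest.raises(ValueError):
            build_element_vectors([e], query8, "squared")


def vec(eid, coords):
    return ElementVector(eid, np.array(coords, dtype=float))


class TestCosineDistanceMatrix:
    def test_identical_vectors(self):
        D = cosine_distance_matrix([vec("a", [1, 1, 0]), vec("b", [1, 1, 0])])
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal(self):
        D = cosine_distance_matrix(
            [vec("a", [1, 1, 0, 0, 0]), vec("b", [0, 0, 1, 1, 0])]
        )
        assert D[0, 1] == pytest.approx(1.0)

    def test_hand_example_with_p_component(self):
        D = cosine_distance_matrix(
            [vec("a", [1, 1, 0, 0, 0.04]), vec("b", [0, 0, 1, 1, 0.04])]
        )
        assert D[0, 1] == pytest.approx(1 - 0.0016 / 2.0016, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance_matrix([vec("a", [0, 0, 0])])

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        vecs = [vec(f"v{i}", rng.integers(0, 2, 6) + 0.01) for i in range(8)]
        D = cosine_distance_matrix(vecs)
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and (D <= 1).all()
        assert np.diag(D) == pytest.approx(np.zeros(8))


def two_blocks_matrix():
    # two tight blocks: within 0.1, between 0.9
    D = np.full((4, 4), 0.9)
    D[0, 1] = D[1, 0] = 0.1
    D[2, 3] = D[3, 2] = 0.1
    np.fill_diagonal(D, 0.0)
    return D


class TestWardTree:
    def test_single_leaf(self):
        tree = ward_tree(np.zeros((1, 1)))
        assert tree.n_leaves == 1 and len(tree.merges) == 0

    def test_identical_pairs_merge_at_zero(self):
        # two identical + two identical orthogonal vectors
        vecs = [
            vec("a", [1, 0]), vec("b", [1, 0]),
            vec("c", [0, 1]), vec("d", [0, 1]),
        ]
        tree = ward_tree(cosine_distance_matrix(vecs))
        assert tree.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert tree.merges[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_blocks_top_split(self):
        tree = ward_tree(two_blocks_matrix())
        # last merge joins the two blocks
        a, b, h, size = tree.merges[-1]
        assert size == 4
        assert h > tree.merges[0, 2] and h > tree.merges[1, 2]
        # first two merges are the within-block ones at 0.1
        assert tree.merges[0, 2] == pytest.approx(0.1)
        assert tree.merges[1, 2] == pytest.approx(0.1)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=7))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = ward_tree(D)
        expected = ward_merges_enum(D)
        # compare member partitions and heights merge by merge
        members = {i: frozenset({i}) for i in range(n)}
        for step, (a, b, h, _) in enumerate(tree.merges):
            ma, mb = members[int(a)], members[int(b)]
            ea, eb, eh = expected[step]
            assert {ma, mb} == {ea, eb}
            assert h == pytest.approx(eh, abs=1e-9)
            members[n + step] = ma | mb

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            ward_tree(D)


class TestCutPreMetagroups:
    def test_all_identical_one_group(self):
        vecs = [vec(str(i), [1, 1, 0]) for i in range(4)]
        tree = ward_tree(cosine_distance_matrix(vecs))
        clusters = cut_pre_metagroups(tree)
        assert clusters == [[0, 1, 2, 3]]

    def test_two_blocks_two_groups_at_20pct(self):
        tree = ward_tree(two_blocks_matrix())
        clusters = cut_pre_metagroups(tree, depth_fraction=0.20)
        assert sorted(map(sorted, clusters)) == [[0, 1], [2, 3]]

    def test_equidistant_escalates_until_group_forms(self):
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        tree = ward_tree(D)
        clusters = cut_pre_metagroups(tree, depth_fraction=0.20, step=0.10)
        assert any(len(c) >= 2 for c in clusters)

    def test_single_leaf_tree(self):
        tree = ward_tree(np.zeros((1, 1)))
        assert cut_pre_metagroups(tree) == [[0]]

    @pytest.mark.parametrize("frac,step", [(0.0, 0.1), (1.5, 0.1), (0.2, 0.0), (0.2, -1)])
    def test_bad_parameters(self, frac, step):
        tree = ward_tree(two_blocks_matrix())
        with pytest.raises(ValueError):
            cut_pre_metagroups(tree, depth_fraction=frac, step=step)

    def test_singletons_carried_forward(self):
        # one tight pair + one far outlier: outlier survives as a singleton
        D = np.array(
            [[0.0, 0.05, 0.9], [0.05, 0.0, 0.9], [0.9, 0.9, 0.0]]
        )
        tree = ward_tree(D)
        clusters = cut_pre_metagroups(tree, depth_fraction=0.20)
        assert sorted(map(sorted, clusters)) == [[0, 1], [2]]


class TestGreedyTermMerge:
    def test_no_shared_terms_unchanged(self):
        groups = [
            [make_element("E1", {"a"}, {"S::t1"}, 0.01)],
            [make_element("E2", {"b"}, {"S::t2"}, 0.01)],
        ]
        out = greedy_term_merge(groups, POLICIES)
        assert len(out) == 2

    def test_shared_term_merges(self):
        groups = [
            [make_element("E1", {"a"}, {"S::t1"}, 0.01)],
            [make_element("E2", {"b"}, {"S::t1", "S::t2"}, 0.01)],
        ]
        out = greedy_term_merge(groups, POLICIES)
        assert len(out) == 1
        assert out[0].union_genes == {"a", "b"}

    def test_transitive_merge_via_fixed_point(self):
        groups = [
            [make_element("E1", {"a"}, {"S::t1"}, 0.01)],
            [make_element("E2", {"b"}, {"S::t1", "S::t2"}, 0.01)],
            [make_element("E3", {"c"}, {"S::t2"}, 0.01)],
        ]
        out = greedy_term_merge(groups, POLICIES)
        assert len(out) == 1
        assert out[0].union_genes == {"a", "b", "c"}

    def test_generic_terms_never_count(self):
        groups = [
            [make_element("E1", {"a"}, {"S::gen1", "S::t1"}, 0.01)],
            [make_element("E2", {"b"}, {"S::gen1", "S::t2"}, 0.01)],
        ]
        out = greedy_term_merge(groups, POLICIES)
        assert len(out) == 2

    def test_largest_shared_count_merges_first(self):
        # A shares 2 terms with C, only 1 with B; the A-C merge happens first
        groups = [
            [make_element("E1", {"a"}, {"S::t1", "S::t2"}, 0.01)],
            [make_element("E2", {"b"}, {"S::t1", "S::x"}, 0.01)],
            [make_element("E3", {"c"}, {"S::t1", "S::t2", "S::y"}, 0.01)],
        ]
        out = greedy_term_merge(groups, POLICIES)
        # all end up merged through t1, in one group
        assert len(out) == 1


class TestCompleteCover:
    def test_unique_genes_nothing_removed(self):
        g = Metagroup("MG1", [
            make_element("E1", {"a"}, {"S::t1"}, 0.01),
            make_element("E2", {"b"}, {"S::t1"}, 0.02),
        ])
        assert len(complete_cover(g).elements) == 2

    def test_subset_element_removed(self):
        e1 = make_element("E1", {"a", "b"}, {"S::t1", "S::t2"}, 1e-5)
        e2 = make_element("E2", {"a"}, {"S::t1"}, 1e-3)
        out = complete_cover(Metagroup("MG1", [e1, e2]))
        assert out.elements == [e1]

    def test_hand_trace_three_elements(self):
        e1 = make_element("E1", {"a", "b"}, {"S::t1", "S::t2"}, 1e-4)
        e2 = make_element("E2", {"a"}, {"S::t1"}, 1e-3)
        e3 = make_element("E3", {"b"}, {"S::t2"}, 1e-2)
        g = Metagroup("MG1", [e1, e2, e3])
        out = complete_cover(g)
        assert out.elements == [e1]
        assert out.union_genes == g.union_genes
        assert out.union_terms == g.union_terms

    def test_order_independent_with_distinct_p(self):
        elements = [
            make_element("E1", {"a", "b"}, {"S::t1", "S::t2"}, 1e-4),
            make_element("E2", {"a"}, {"S::t1"}, 1e-3),
            make_element("E3", {"b", "c"}, {"S::t2"}, 1e-2),
        ]
        kept = {
            frozenset(e.element_id for e in complete_cover(
                Metagroup("MG1", list(perm))).elements)
            for perm in (
                elements,
                elements[::-1],
                [elements[1], elements[2], elements[0]],
            )
        }
        assert len(kept) == 1

    def test_tied_p_broken_by_element_id(self):
        # identical content, equal p: the id visited first (ascending) goes
        e1 = make_element("E1", {"a"}, {"S::t1"}, 0.01)
        e2 = make_element("E2", {"a"}, {"S::t1"}, 0.01)
        out = complete_cover(Metagroup("MG1", [e1, e2]))
        assert [e.element_id for e in out.elements] == ["E2"]

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_completeness_and_minimality(self, data):
        n = data.draw(st.integers(min_value=1, max_value=7))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        elements = []
        for i in range(n):
            genes = frozenset(
                f"g{j}" for j in range(5) if rng.random() < 0.5
            ) or frozenset({"g0"})
            terms = frozenset(
                f"S::t{j}" for j in range(4) if rng.random() < 0.5
            ) or frozenset({"S::t0"})
            elements.append(
                GeneTermSet(f"E{i}", genes, terms, float(rng.uniform(1e-6, 1)))
            )
        g = Metagroup("MG1", elements)
        out = complete_cover(g)
        assert out.union_genes == g.union_genes
        assert out.union_terms == g.union_terms
        # single-removal minimality, checked exhaustively
        for e in out.elements:
            others = [o for o in out.elements if o is not e]
            if not others:
                continue
            genes = frozenset().union(*(o.genes for o in others))
            terms = frozenset().union(*(o.terms for o in others))
            assert not (e.genes <= genes and e.terms <= terms)


def make_space_for(elements, universe_size=100):
    """A space annotating exactly each element's genes with its terms."""
    term_to_genes: dict[str, set[str]] = {}
    for e in elements:
        for t in e.terms:
            term_to_genes.setdefault(t.split("::", 1)[1], set()).update(e.genes)
    genes = set().union(*(e.genes for e in elements))
    universe = genes | {f"u{i}" for i in range(universe_size - len(genes))}
    return AnnotationSpace(
        "S",
        {t: frozenset(g) for t, g in term_to_genes.items()},
        universe=frozenset(universe),
    )


class TestScoreMetagroups:
    def make_two_groups(self):
        ga = [
            make_element("E1", {"g1", "g2"}, {"S::t1"}, 0.01),
            make_element("E2", {"g1", "g2"}, {"S::t2"}, 0.02),
        ]
        gb = [
            make_element("E3", {"g3", "g4"}, {"S::t3"}, 0.01),
            make_element("E4", {"g3", "g4"}, {"S::t4"}, 0.02),
        ]
        groups = [Metagroup("MG1", ga), Metagroup("MG2", gb)]
        elements = ga + gb
        space = make_space_for(elements)
        ctx = QueryContext.from_genes(
            ["g1", "g2", "g3", "g4"], len(space.universe)
        )
        return groups, ctx, space

    def test_perfect_separation_silhouette_one(self):
        groups, ctx, space = self.make_two_groups()
        scored = score_metagroups(groups, ctx, [space])
        assert all(g.silhouette == pytest.approx(1.0) for g in scored)
        assert all(g.diameter == pytest.approx(0.0, abs=1e-12) for g in scored)
        assert all(
            g.similarity_coefficient == pytest.approx(1.0) for g in scored
        )

    def test_single_metagroup_silhouette_undefined(self):
        ga = [
            make_element("E1", {"g1", "g2"}, {"S::t1"}, 0.01),
            make_element("E2", {"g2"}, {"S::t2"}, 0.02),
        ]
        space = make_space_for(ga)
        ctx = QueryContext.from_genes(["g1", "g2"], len(space.universe))
        (scored,) = score_metagroups([Metagroup("MG1", ga)], ctx, [space])
        assert scored.silhouette is None

    def test_singleton_metagroup_conventions(self):
        ga = [make_element("E1", {"g1", "g2"}, {"S::t1"}, 0.01)]
        gb = [make_element("E2", {"g3"}, {"S::t2"}, 0.02)]
        space = make_space_for(ga + gb)
        ctx = QueryContext.from_genes(["g1", "g2", "g3"], len(space.universe))
        scored = score_metagroups(
            [Metagroup("MG1", ga), Metagroup("MG2", gb)], ctx, [space]
        )
        for g in scored:
            assert g.diameter == 0.0
            assert g.similarity_coefficient == 1.0
            assert g.silhouette == 0.0  # singleton-element convention

    def test_raw_p_is_hypergeometric_on_union(self):
        groups, ctx, space = self.make_two_groups()
        scored = score_metagroups(groups, ctx, [space])
        from gtlinker.enrichment import hypergeometric_tail

        for g in scored:
            K = len(
                set().union(
                    *(
                        space.term_to_genes[t.split("::", 1)[1]]
                        for t in g.union_terms
                    )
                )
            )
            expected = hypergeometric_tail(
                len(g.union_genes), ctx.M, K, ctx.universe_size
            )
            assert g.raw_p == pytest.approx(expected)
            assert g.adjusted_p >= g.raw_p - 1e-15

    def test_bh_hand_example(self):
        # BH on raw p (0.01, 0.02, 0.03) -> all adjusted to 0.03
        assert bh_adjust_enum([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    @given(
        ps=st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_bh_matches_oracle(self, ps):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests(ps, method="fdr_bh")[1]
        assert list(adjusted) == pytest.approx(bh_adjust_enum(ps))

    def test_gene_outside_query_errors(self):
        ga = [make_element("E1", {"zzz"}, {"S::t1"}, 0.01)]
        space = AnnotationSpace(
            "S", {"t1": frozenset({"zzz"})}, universe=frozenset({"zzz", "g1"})
        )
        ctx = QueryContext.from_genes(["g1"] * 1, 2)
        with pytest.raises(ValueError, match="not in query"):
            score_metagroups([Metagroup("MG1", ga)], ctx, [space])

    def test_silhouette_matches_sklearn(self):
        # crisp grouping with overlapping gene content across groups
        ga = [
            make_element("E1", {"g1", "g2"}, {"S::t1"}, 0.01),
            make_element("E2", {"g1", "g2", "g3"}, {"S::t2"}, 0.02),
        ]
        gb = [
            make_element("E3", {"g3", "g4"}, {"S::t3"}, 0.01),
            make_element("E4", {"g4", "g5"}, {"S::t4"}, 0.02),
        ]
        space = make_space_for(ga + gb)
        ctx = QueryContext.from_genes(
            ["g1", "g2", "g3", "g4", "g5"], len(space.universe)
        )
        scored = score_metagroups(
            [Metagroup("MG1", ga), Metagroup("MG2", gb)], ctx, [space]
        )

        from sklearn.metrics import silhouette_samples

        vectors = build_element_vectors(ga + gb, ctx, "off")
        D = cosine_distance_matrix(vectors)
        svals = silhouette_samples(D, [0, 0, 1, 1], metric="precomputed")
        expected = {"MG1": svals[:2].mean(), "MG2": svals[2:].mean()}
        for g in scored:
            assert g.silhouette == pytest.approx(expected[g.metagroup_id])

    def test_ranking_order(self):
        groups, ctx, space = self.make_two_groups()
        scored = score_metagroups(groups, ctx, [space])
        keys = [(g.adjusted_p, -(g.silhouette or 0), g.metagroup_id) for g in scored]
        assert keys == sorted(keys)


class TestLinkElementsEndToEnd:
    def build(self):
        # two modules of co-annotated elements + one all-generic element
        e_mod1 = [
            make_element("E1", {"g1", "g2", "g3"}, {"S::t1"}, 1e-4),
            make_element("E2", {"g1", "g2"}, {"S::t1", "S::t2"}, 1e-3),
        ]
        e_mod2 = [
            make_element("E3", {"g4", "g5", "g6"}, {"S::t3"}, 1e-4),
            make_element("E4", {"g5", "g6"}, {"S::t3", "S::t4"}, 1e-3),
        ]
        e_gen = [make_element("E5", {"g1", "g4"}, {"S::gen1"}, 1e-2)]
        elements = e_mod1 + e_mod2 + e_gen
        space = make_space_for(elements)
        ctx = QueryContext.from_genes(
            [f"g{i}" for i in range(1, 7)], len(space.universe)
        )
        return elements, ctx, space

    def test_two_metagroups_and_counts(self):
        elements, ctx, space = self.build()
        groups, counts = link_elements(elements, ctx, [space], POLICIES)
        assert counts["elements_in"] == 5
        assert counts["after_generic_filter"] == 4
        assert len(groups) == 2
        unions = sorted(tuple(sorted(g.union_genes)) for g in groups)
        assert unions == [("g1", "g2", "g3"), ("g4", "g5", "g6")]

    def test_conservation_before_cover(self):
        elements, ctx, space = self.build()
        groups, counts = link_elements(elements, ctx, [space], POLICIES)
        # every surviving filtered element's genes are covered by some group
        for e in filter_generic_only(elements, POLICIES):
            assert any(e.genes <= g.union_genes for g in groups)

    def test_determinism(self):
        elements, ctx, space = self.build()
        r1 = link_elements(elements, ctx, [space], POLICIES)
        r2 = link_elements(elements, ctx, [space], POLICIES)
        assert [
            (g.metagroup_id, g.adjusted_p, g.silhouette) for g in r1[0]
        ] == [(g.metagroup_id, g.adjusted_p, g.silhouette) for g in r2[0]]
        assert r1[1] == r2[1]

    def test_all_generic_input_yields_empty(self):
        e = make_element("E1", {"g1"}, {"S::gen1"}, 0.01)
        space = make_space_for([e])
        ctx = QueryContext.from_genes(["g1"], len(space.universe))
        groups, counts = link_elements([e], ctx, [space], POLICIES)
        assert groups == [] and counts["final_metagroups"] == 0
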