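from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divindex import (
    RuleError,
    builtin_rule,
    classify_interior,
    coefficients,
    es_score_direct,
    fp_score_direct,
    rigidity_probe,
    scores,
    table_rule,
)
from divindex.exact import to_decimal_string
from divindex.fixtures import synthetic_tree
from divindex.indices import BUILTIN_RULE_NAMES
from divindex.tree import parse_newick

F = Fraction


# Ratio-of-allocation table on the 11-leaf example tree: (left, right) terms
# at the named vertices, with "left" the first stored child.
RATIO_TABLE = {
    "fp": {"p": (F(1, 2), F(1, 2)), "q": (F(4, 5), F(1, 5)), "r": (F(3, 5), F(2, 5)),
           "s": (F(3, 4), F(1, 4)), "t": (F(2, 3), F(1, 3)), "v": (F(2, 3), F(1, 3))},
    "es": {x: (F(1, 2), F(1, 2)) for x in "pqrstv"},
    "alpha": {"p": (F(1, 2), F(1, 2)), "q": (F(2, 3), F(1, 3)), "r": (F(2, 3), F(1, 3)),
              "s": (F(2, 3), F(1, 3)), "t": (F(2, 3), F(1, 3)), "v": (F(2, 3), F(1, 3))},
    "beta": {"p": (F(1, 2), F(1, 2)), "q": (F(1), F(0)), "r": (F(1), F(0)),
             "s": (F(1), F(0)), "t": (F(1), F(0)), "v": (F(1), F(0))},
    "gamma_min": {"p": (F(1, 2), F(1, 2)), "q": (F(0), F(1)), "r": (F(0), F(1)),
                  "s": (F(0), F(1)), "t": (F(0), F(1)), "v": (F(0), F(1))},
    "delta_cherry": {"p": (F(1, 4), F(3, 4)), "q": (F(3, 4), F(1, 4)), "r": (F(1, 2), F(1, 2)),
                     "s": (F(3, 4), F(1, 4)), "t": (F(3, 4), F(1, 4)), "v": (F(3, 4), F(1, 4))},
    "epsilon_singleparent": {"p": (F(3, 4), F(1, 4)), "q": (F(1), F(0)), "r": (F(1), F(0)),
                             "s": (F(1), F(0)), "t": (F(1, 2), F(1, 2)), "v": (F(1, 2), F(1, 2))},
    "zeta_squares": {"p": (F(1, 2), F(1, 2)), "q": (F(16, 17), F(1, 17)), "r": (F(9, 13), F(4, 13)),
                     "s": (F(9, 10), F(1, 10)), "t": (F(4, 5), F(1, 5)), "v": (F(4, 5), F(1, 5))},
    "eta_hybrid": {"p": (F(1, 2), F(1, 2)), "q": (F(1, 2), F(1, 2)), "r": (F(1, 2), F(1, 2)),
                   "s": (F(3, 4), F(1, 4)), "t": (F(2, 3), F(1, 3)), "v": (F(2, 3), F(1, 3))},
    "theta": {"p": (F(1, 2), F(1, 2)), "q": (F(1), F(0)), "r": (F(5, 8), F(3, 8)),
              "s": (F(0), F(1)), "t": (F(1, 4), F(3, 4)), "v": (F(1, 4), F(3, 4))},
}

# Worked unit-length scores of x3 on the same tree, exact.
X3_SCORES = {
    "fp": F(113, 60),          # 1.88
    "es": F(31, 16),           # 1.94
    "alpha": F(16, 9),         # 1.78
    "beta": F(1),              # 1
    "gamma_min": F(2),         # 2
    "delta_cherry": F(413, 256),   # 1.61
    "epsilon_singleparent": F(23, 8),  # 2.88
    "zeta_squares": F(1389, 850),  # 1.63
    "eta_hybrid": F(85, 48),   # 1.77
    "theta": F(7, 4),          # 1.75
}

ROUNDED = {"fp": "1.88", "es": "1.94", "alpha": "1.78", "beta": "1.00",
           "gamma_min": "2.00", "delta_cherry": "1.61", "epsilon_singleparent": "2.88",
           "zeta_squares": "1.63", "eta_hybrid": "1.77", "theta": "1.75"}


def _rule(name, theta):
    return theta if name == "theta" else builtin_rule(name)


class TestRatioTable:
    @pytest.mark.parametrize("name", sorted(RATIO_TABLE))
    def test_all_cells_exact(self, name, fig3, theta):
        rule = _rule(name, theta)
        sh = fig3.shapes_at_all_vertices()
        for vertex_name, expected in RATIO_TABLE[name].items():
            v = fig3.vertex_by_label(vertex_name)
            got = rule.ratio(tuple(sh[c] for c in fig3.children[v]))
            assert got == expected, (name, vertex_name)

    def test_cherry_vertices_always_half(self, fig3, theta):
        sh = fig3.shapes_at_all_vertices()
        for name in sorted(RATIO_TABLE):
            rule = _rule(name, theta)
            for vx in "wyu":
                v = fig3.vertex_by_label(vx)
                got = rule.ratio(tuple(sh[c] for c in fig3.children[v]))
                assert got == (F(1, 2), F(1, 2))


class TestWorkedScores:
    @pytest.mark.parametrize("name", sorted(X3_SCORES))
    def test_x3(self, name, fig3, theta):
        vec = scores(fig3, _rule(name, theta))
        assert vec["x3"] == X3_SCORES[name]
        assert to_decimal_string(vec["x3"], 2) == ROUNDED[name]


class TestDirectFormulas:
    def test_fp_x3(self, fig3):
        assert fp_score_direct(fig3, "x3") == F(113, 60)

    def test_es_x3(self, fig3):
        assert es_score_direct(fig3, "x3") == F(31, 16)

    def test_two_leaf_tree(self):
        t = parse_newick("(a:1,b:1);")
        assert fp_score_direct(t, "a") == 1
        assert es_score_direct(t, "b") == 1

    def test_u12_values(self, u12):
        assert fp_score_direct(u12, "x11") == 6
        assert es_score_direct(u12, "x9") == F(25, 4)

    def test_star_tree_es_is_pendant(self):
        t = parse_newick("(a:3,b:5,c:7);")
        assert es_score_direct(t, "c") == 7  # pendant only
        assert es_score_direct(t, "a") == 3

    def test_unknown_taxon(self, fig3):
        with pytest.raises(Exception):
            fp_score_direct(fig3, "nope")


class TestCoefficients:
    def test_fp_root_edge_coefficient(self, fig3, fp):
        table = coefficients(fig3, fp)
        edge = (fig3.root, fig3.vertex_by_label("p"))
        assert table.value("x3", edge) == F(1, 10)

    def test_pendant_coefficient_is_one(self, fig3, theta):
        table = coefficients(fig3, theta)
        leaf = fig3.leaf_by_name("x6")
        assert table.value("x6", (fig3.parent[leaf], leaf)) == 1

    def test_alpha_sv_edge(self, fig3):
        table = coefficients(fig3, builtin_rule("alpha"))
        edge = fig3.edge_by_labels("s", "v")
        assert table.value("x3", edge) == F(1, 3)

    def test_descent_condition(self, fig3, fp):
        table = coefficients(fig3, fp)
        edge = fig3.edge_by_labels("r", "u")
        assert table.value("x3", edge) == 0

    def test_column_sums_equal_one(self, fig3):
        for name in BUILTIN_RULE_NAMES:
            table = coefficients(fig3, builtin_rule(name))
            for v in fig3.preorder():
                if v != fig3.root:
                    assert sum(table.gamma[v].values()) == 1

    def test_consistency(self, fig3):
        # Gamma-vectors at v proportional to the ratio at v for ancestral edges
        for name in ("fp", "zeta_squares", "delta_cherry"):
            rule = builtin_rule(name)
            table = coefficients(fig3, rule)
            sh = fig3.shapes_at_all_vertices()
            for vx in "pqrstv":
                v = fig3.vertex_by_label(vx)
                ratio = rule.ratio(tuple(sh[c] for c in fig3.children[v]))
                for f_edge in fig3.root_path_edges(v):
                    gamma_vec = []
                    for c in fig3.children[v]:
                        leaves = [w for w in fig3.preorder(c) if fig3.is_leaf(w)]
                        gamma_vec.append(sum(table.gamma[f_edge].get(w, F(0)) for w in leaves))
                    total = sum(gamma_vec)
                    assert total > 0
                    assert tuple(g / total for g in gamma_vec) == ratio


class TestRuleValidation:
    def test_unknown_builtin(self):
        with pytest.raises(RuleError):
            builtin_rule("nope")

    def test_binary_only_rules_reject_multifurcation(self):
        t = parse_newick("((a:1,b:1,c:1):1,d:1);")
        for name in ("alpha", "beta", "delta_cherry", "zeta_squares", "eta_hybrid"):
            with pytest.raises(RuleError):
                scores(t, builtin_rule(name))

    def test_fp_es_accept_multifurcation(self):
        t = parse_newick("((a:1,b:1,c:1):1,d:1);")
        assert scores(t, builtin_rule("fp"))["a"] == 1 + F(1, 3)
        assert scores(t, builtin_rule("es"))["a"] == 1 + F(1, 3)

    def test_table_rule_bad_ratio(self):
        with pytest.raises(RuleError):
            table_rule({("*", "*"): (F(1, 2), F(1, 3))})

    def test_table_rule_neutrality_violation(self):
        with pytest.raises(RuleError):
            table_rule({("*", "*"): (F(1, 3), F(2, 3))})

    def test_table_rule_missing_class(self):
        t = parse_newick("(((a:1,b:1):1,c:1):1,d:1);")
        rule = table_rule({("*", "*"): (F(1, 2), F(1, 2))})
        with pytest.raises(RuleError):
            scores(t, rule)  # the (cherry, leaf) class is unassigned

    def test_table_rule_default_uniform_matches_es(self, fig3, es):
        rule = table_rule({}, allow_default=True)
        assert scores(fig3, rule) == scores(fig3, es)


class TestClassification:
    def test_es_fp_interior(self, fig3, fp, es):
        assert not classify_interior(fp, fig3).boundary
        assert not classify_interior(es, fig3).boundary

    def test_beta_boundary_with_witness(self, fig3):
        cls = classify_interior(builtin_rule("beta"), fig3)
        assert cls.boundary
        v, term = cls.witness
        assert fig3.label.get(v) in set("qrstv")

    def test_epsilon_boundary(self, fig3):
        assert classify_interior(builtin_rule("epsilon_singleparent"), fig3).boundary


class TestRigidityProbe:
    def test_es_rigid(self, es):
        res = rigidity_probe(es, 6)
        assert res.rigid_witness_found
        b1, b2, ratio = res.witness
        assert b1 != b2 and ratio == (F(1, 2), F(1, 2))

    def test_fp_no_witness(self, fp):
        assert not rigidity_probe(fp, 12).rigid_witness_found

    def test_zeta_no_witness(self):
        assert not rigidity_probe(builtin_rule("zeta_squares"), 12).rigid_witness_found

    def test_alpha_rigid(self):
        assert rigidity_probe(builtin_rule("alpha"), 6).rigid_witness_found

    def test_bound_validation(self, es):
        with pytest.raises(ValueError):
            rigidity_probe(es, 2)


class TestProperties:
    @given(seed=st.integers(0, 5_000), n=st.integers(3, 10))
    @settings(max_examples=40, deadline=None)
    def test_conservation_all_rules(self, seed, n):
        t = synthetic_tree(n, seed, "binary")
        total = t.total_length()
        for name in BUILTIN_RULE_NAMES:
            vec = scores(t, builtin_rule(name))
            assert sum(vec.values()) == total

    @given(seed=st.integers(0, 5_000), n=st.integers(2, 12))
    @settings(max_examples=40, deadline=None)
    def test_framework_matches_direct_formulas(self, seed, n):
        t = synthetic_tree(n, seed, "multifurcating")
        vec_fp = scores(t, builtin_rule("fp"))
        vec_es = scores(t, builtin_rule("es"))
        for name in t.leaf_labels():
            assert vec_fp[name] == fp_score_direct(t, name)
            assert vec_es[name] == es_score_direct(t, name)

    def test_neutrality_mirrored_subtrees(self):
        t = parse_newick("((a:2,b:7):5,(c:2,d:7):5);")
        for name in BUILTIN_RULE_NAMES:
            vec = scores(t, builtin_rule(name))
            assert vec["a"] == vec["c"] and vec["b"] == vec["d"]
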