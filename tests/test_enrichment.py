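"""Fisher exact test, OBO parsing, propagation, and corrections."""

import random

import pytest

from _oracles import fisher_greater_oracle, fisher_two_sided_oracle
from dupprofiler import enrichment


OBO_CHAIN = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: b
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: c
alt_id: GO:0000033
is_a: GO:0000002 ! b

[Term]
id: GO:0000004
name: d (second parent of diamond)
is_a: GO:0000001 ! root

[Term]
id: GO:0000005
name: diamond leaf
is_a: GO:0000002 ! b
is_a: GO:0000004 ! d

[Term]
id: GO:0000009
name: gone
is_obsolete: true
"""


@pytest.fixture
def dag(tmp_path):
    path = tmp_path / "test.obo"
    path.write_text(OBO_CHAIN)
    return enrichment.parse_obo(path)


class TestParseObo:
    def test_chain_ancestors(self, dag):
        assert dag.ancestors("GO:0000003") == {"GO:0000002", "GO:0000001"}

    def test_two_parents_both_in_closure(self, dag):
        assert dag.ancestors("GO:0000005") == {"GO:0000002", "GO:0000004",
                                               "GO:0000001"}

    def test_obsolete_term_dropped(self, dag):
        assert "GO:0000009" not in dag.terms

    def test_alt_id_aliased(self, dag):
        assert dag.resolve("GO:0000033") == "GO:0000003"

    def test_cycle_is_hard_error(self, tmp_path):
        cyclic = OBO_CHAIN.replace(
            "id: GO:0000001\nname: root",
            "id: GO:0000001\nname: root\nis_a: GO:0000003 ! back-edge")
        path = tmp_path / "cyclic.obo"
        path.write_text(cyclic)
        with pytest.raises(ValueError, match="cycle"):
            enrichment.parse_obo(path)

    def test_annotation_to_obsolete_term_dropped(self, dag, tmp_path):
        path = tmp_path / "annos.tsv"
        path.write_text("gene1\tGO:0000009\ngene1\tGO:0000003\n")
        annos = enrichment.read_annotations(path, dag)
        assert annos == {"gene1": {"GO:0000003"}}


class TestPropagate:
    def test_leaf_closure(self, dag):
        closed = enrichment.propagate({"g": {"GO:0000003"}}, dag)
        assert closed["g"] == {"GO:0000003", "GO:0000002", "GO:0000001"}

    def test_empty_annotation(self, dag):
        assert enrichment.propagate({"g": set()}, dag) == {"g": set()}

    def test_diamond_root_counted_once(self, dag):
        closed = enrichment.propagate({"g": {"GO:0000005"}}, dag)
        assert len(closed["g"]) == 4  # set semantics, no double count

    def test_propagation_never_decreases_population_counts(self, dag):
        annos = {"g1": {"GO:0000003"}, "g2": {"GO:0000005"}, "g3": {"GO:0000002"}}
        closed = enrichment.propagate(annos, dag)
        for gene in annos:
            assert annos[gene] <= closed[gene]


class TestFisher:
    def test_textbook_one_sided_tail(self):
        # study of 3 all annotated, population 5/10: P(X>=3) = 1/12
        p, direction = enrichment.fisher_exact(3, 3, 5, 10, alternative="greater")
        assert p == pytest.approx(1 / 12, rel=1e-12)
        assert direction == "over"
        assert p == pytest.approx(fisher_greater_oracle(3, 3, 5, 10), rel=1e-12)

    def test_textbook_two_sided_matches_enumeration(self):
        p, _ = enrichment.fisher_exact(3, 3, 5, 10)
        assert p == pytest.approx(fisher_two_sided_oracle(3, 3, 5, 10), abs=1e-12)

    def test_equal_frequencies_give_p_one(self):
        p, _ = enrichment.fisher_exact(5, 10, 10, 20)
        assert p == pytest.approx(1.0)

    def test_degenerate_zero_counts(self):
        p, direction = enrichment.fisher_exact(0, 5, 0, 10)
        assert p == 1.0
        assert direction == "under"

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment.fisher_exact(5, 3, 5, 10)
        with pytest.raises(ValueError):
            enrichment.fisher_exact(2, 3, 1, 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        N = rng.randint(2, 60)
        n = rng.randint(1, N)
        K = rng.randint(0, N)
        k = rng.randint(max(0, n + K - N), min(n, K))
        p, _ = enrichment.fisher_exact(k, n, K, N)
        assert p == pytest.approx(fisher_two_sided_oracle(k, n, K, N), abs=1e-12)


class TestEnrich:
    def _setup(self, dag):
        pop = [f"g{i}" for i in range(40)]
        study = pop[:10]
        annos = {g: {"GO:0000003"} for g in pop[:12]}  # 10/10 study, 12/40 pop
        for g in pop[12:]:
            annos[g] = {"GO:0000004"}
        return study, pop, annos

    def test_planted_term_ranks_first(self, dag):
        study, pop, annos = self._setup(dag)
        table = enrichment.enrich(study, pop, annos, dag)
        assert table.iloc[0]["term_id"] in ("GO:0000003", "GO:0000002")
        assert table.iloc[0]["direction"] == "over"
        assert table.iloc[0]["p_fdr_bh"] < 0.05

    def test_corrected_ps_bounded_by_raw(self, dag):
        study, pop, annos = self._setup(dag)
        table = enrichment.enrich(study, pop, annos, dag)
        assert (table["p_bonferroni"] >= table["p"] - 1e-15).all()
        assert (table["p_sidak"] >= table["p"] - 1e-15).all()
        assert (table["p"] <= 1).all() and (table["p"] >= 0).all()

    def test_bh_monotone_after_step_up(self, dag):
        study, pop, annos = self._setup(dag)
        table = enrichment.enrich(study, pop, annos, dag)
        ordered = table.sort_values("p")["p_fdr_bh"].tolist()
        assert all(b >= a - 1e-15 for a, b in zip(ordered, ordered[1:]))

    def test_study_equals_population_all_p_one(self, dag):
        _, pop, annos = self._setup(dag)
        table = enrichment.enrich(pop, pop, annos, dag)
        assert (table["p"] == 1.0).all()

    def test_study_not_subset_rejected(self, dag):
        with pytest.raises(ValueError):
            enrichment.enrich(["x"], ["y"], {}, dag)

    def test_single_term_corrections_equal_raw(self, tmp_path):
        path = tmp_path / "single.obo"
        path.write_text("format-version: 1.2\nontology: t\n\n"
                        "[Term]\nid: GO:0000001\nname: only\n")
        dag = enrichment.parse_obo(path)
        annos = {"g0": {"GO:0000001"}, "g1": {"GO:0000001"}}
        table = enrichment.enrich(["g0"], ["g0", "g1", "g2"], annos, dag)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["p_bonferroni"] == row["p"] == row["p_sidak"] == row["p_fdr_bh"]
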