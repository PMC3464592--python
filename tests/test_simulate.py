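"""Synthetic genome generator: sequences, divergence targeting, placement."""

import pytest
from Bio.Seq import Seq

from dupprofiler import simulate
from dupprofiler.ks import pair_ks


def estimated_ks(cds_a, cds_b):
    return pair_ks(str(Seq(cds_a).translate()), str(Seq(cds_b).translate()),
                   cds_a, cds_b)


class TestRandomCds:
    def test_length_and_start_codon(self):
        cds = simulate.random_cds(100, 1)
        assert len(cds) == 300
        assert cds.startswith("ATG")

    def test_no_internal_stops(self):
        protein = str(Seq(simulate.random_cds(200, 2)).translate())
        assert "*" not in protein

    def test_deterministic_per_seed(self):
        assert simulate.random_cds(50, 3) == simulate.random_cds(50, 3)


class TestEvolveParalog:
    def test_zero_target_returns_input_unchanged(self):
        cds = simulate.random_cds(100, 4)
        assert simulate.evolve_paralog(cds, 0.0, 0.2, 5) == cds

    @pytest.mark.parametrize("target", [0.3, 1.0])
    def test_first_crossing_lands_at_or_just_above_target(self, target):
        cds = simulate.random_cds(300, 6)
        mutant = simulate.evolve_paralog(cds, target, 0.2, 7)
        r = estimated_ks(cds, mutant)
        assert r.status == "ok"
        assert target <= r.ks <= target * 1.1 + 0.05

    def test_omega_zero_means_no_amino_acid_changes(self):
        # the protein is untouched; estimated Ka is not exactly 0 because
        # pathway averaging on multi-difference codons (e.g. serine islands
        # TCA vs AGT) counts fractional nonsynonymous steps even between
        # synonymous endpoints
        cds = simulate.random_cds(200, 8)
        mutant = simulate.evolve_paralog(cds, 0.4, 0.0, 9)
        assert str(Seq(mutant).translate()) == str(Seq(cds).translate())
        assert estimated_ks(cds, mutant).ka <= 0.01

    def test_target_beyond_saturation_bound_rejected(self):
        with pytest.raises(ValueError, match="below"):
            simulate.evolve_paralog(simulate.random_cds(50, 10), 5.0, 0.2, 11)


class TestSimulateGenome:
    def _small_config(self, planted, seed=0, n_chromosomes=4):
        return simulate.SimConfig(n_chromosomes=n_chromosomes,
                                  n_background_genes=20,
                                  gene_length_mean=80, gene_length_min=40,
                                  planted_sets=planted, seed=seed)

    def test_tandem_sets_realize_sub_10kb_gaps(self):
        config = self._small_config(
            [simulate.PlantedSet(size=3, set_type="tandem", target_ks=0.3)] * 4)
        catalog, truth = simulate.simulate_genome(config)
        for tset in truth.sets:
            for (ga, gb), label in tset.pair_labels.items():
                a, b = catalog.genes[ga], catalog.genes[gb]
                gap = max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
                if label == "tandem":
                    assert a.chromosome == b.chromosome and gap < 10_000
            assert "tandem" in tset.set_labels

    def test_inter_sets_span_distinct_chromosomes(self):
        config = self._small_config(
            [simulate.PlantedSet(size=4, set_type="inter", target_ks=0.5)])
        catalog, truth = simulate.simulate_genome(config)
        chroms = {catalog.genes[g].chromosome for g in truth.sets[0].members}
        assert len(chroms) == 4
        assert truth.sets[0].set_labels == {"inter"}

    def test_wgd_event_yields_pairs_at_shared_target(self):
        config = self._small_config(
            [simulate.PlantedSet(size=5, set_type="wgd", target_ks=1.0)])
        catalog, truth = simulate.simulate_genome(config)
        assert len(truth.sets) == 5
        assert all(len(s.members) == 2 for s in truth.sets)
        assert all(s.planted_type == "wgd" for s in truth.sets)
        for s in truth.sets:
            a, b = (catalog.genes[g] for g in s.members)
            assert a.chromosome != b.chromosome

    def test_no_overlapping_genes_on_any_chromosome(self):
        config = self._small_config(
            [simulate.PlantedSet(size=2, set_type="intra", target_ks=0.3)] * 3)
        catalog, _ = simulate.simulate_genome(config)
        for genes in catalog.by_chromosome().values():
            for g1, g2 in zip(genes, genes[1:]):
                assert g2.start > g1.end

    def test_bit_identical_given_seed(self):
        config = self._small_config(
            [simulate.PlantedSet(size=2, set_type="inter", target_ks=0.3)], seed=42)
        c1, t1 = simulate.simulate_genome(config)
        c2, t2 = simulate.simulate_genome(self._small_config(
            [simulate.PlantedSet(size=2, set_type="inter", target_ks=0.3)], seed=42))
        assert {g: vars(m) for g, m in c1.genes.items()} == \
            {g: vars(m) for g, m in c2.genes.items()}
        assert [s.members for s in t1.sets] == [s.members for s in t2.sets]

    def test_negative_control_no_planted_sets(self):
        from dupprofiler.mcl import clusters_to_sets, mcl
        from dupprofiler.similarity import build_pair_list
        catalog, truth = simulate.simulate_genome(self._small_config([]))
        edges = build_pair_list(catalog)
        assert clusters_to_sets(mcl(edges)) == []
        assert truth.sets == []

    def test_catalog_passes_validation(self):
        config = self._small_config(
            [simulate.PlantedSet(size=3, set_type="mixed", target_ks=0.3)])
        catalog, _ = simulate.simulate_genome(config)
        catalog.validate()


class TestGoAnnotations:
    def _truth(self):
        truth = simulate.SyntheticTruth()
        for i in range(30):
            sid = f"p{i:03d}"
            truth.sets.append(simulate.TruthSet(
                set_id=sid, members=[f"{sid}a", f"{sid}b"],
                planted_type="inter", target_ks=0.3 if i < 15 else 2.0, omega=0.2))
        return truth

    def test_planted_term_recovered(self, tmp_path):
        from dupprofiler.enrichment import enrich, parse_obo
        truth = self._truth()
        obo_text, annos = simulate.make_go_annotations(
            truth, enriched_terms=[("GO:9100001", 0.9, 0.05)], seed=0)
        path = tmp_path / "syn.obo"
        path.write_text(obo_text)
        dag = parse_obo(path)
        table = enrich(truth.study_genes, truth.duplicated_genes, annos, dag)
        top = table.iloc[0]
        assert top["term_id"] == "GO:9100001"
        assert top["p_fdr_bh"] < 0.05

    def test_matched_frequencies_not_significant(self, tmp_path):
        from dupprofiler.enrichment import enrich, parse_obo
        truth = self._truth()
        obo_text, annos = simulate.make_go_annotations(
            truth, enriched_terms=[("GO:9100001", 0.3, 0.3)], seed=1)
        path = tmp_path / "syn.obo"
        path.write_text(obo_text)
        dag = parse_obo(path)
        table = enrich(truth.study_genes, truth.duplicated_genes, annos, dag)
        row = table[table["term_id"] == "GO:9100001"].iloc[0]
        assert row["p_fdr_bh"] > 0.05

    def test_study_set_is_low_ks_cohort(self):
        truth = self._truth()
        simulate.make_go_annotations(truth, seed=2)
        assert truth.study_genes == sorted(
            g for s in truth.sets if s.target_ks <= 1.0 for g in s.members)
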