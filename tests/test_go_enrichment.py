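import math

import pytest
from scipy.stats import hypergeom

from tcpin.go_enrichment import (
    BIN_LABELS,
    EnrichmentResult,
    build_population,
    enrich_module,
    enrich_modules,
    enrichment_report,
    hypergeom_pvalue,
    propagate_annotations,
)
from tcpin.io_formats import AnnotationSet
from tcpin.synthetic_data import ROOT_TERM, planted_term_map

from _oracles import naive_hypergeom_tail


class TestPropagation:
    def test_chain_to_root(self):
        ann = AnnotationSet(
            "BP",
            direct={"g": {"X"}},
            dag={"X": {"Y"}, "Y": {"root"}, "root": set()},
        )
        assert propagate_annotations(ann).direct["g"] == {"X", "Y", "root"}

    def test_flat_dag_adds_only_root(self):
        ann = AnnotationSet(
            "BP", direct={"g": {"X"}}, dag={"X": {"root"}, "root": set()}
        )
        assert propagate_annotations(ann).direct["g"] == {"X", "root"}

    def test_diamond_counted_once(self):
        ann = AnnotationSet(
            "BP",
            direct={"g": {"X"}},
            dag={"X": {"L", "R"}, "L": {"root"}, "R": {"root"}, "root": set()},
        )
        assert propagate_annotations(ann).direct["g"] == {"X", "L", "R", "root"}

    def test_cycle_detected(self):
        ann = AnnotationSet("BP", direct={}, dag={"X": {"Y"}, "Y": {"X"}})
        with pytest.raises(ValueError, match="cycle"):
            propagate_annotations(ann)


class TestHypergeomPvalue:
    def test_small_closed_form(self):
        # P(all 3 draws annotated) with 4 of 10 annotated
        assert hypergeom_pvalue(c=3, m=3, N=10, M=4) == pytest.approx(4 / 120)

    def test_m_zero_is_one(self):
        assert hypergeom_pvalue(c=5, m=0, N=20, M=7) == 1.0

    def test_everything_annotated_is_one(self):
        for m in range(4):
            assert hypergeom_pvalue(c=3, m=m, N=12, M=12) == pytest.approx(1.0)

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(c=3, m=4, N=10, M=10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(c=11, m=1, N=10, M=5)

    def test_nonincreasing_in_m(self):
        values = [hypergeom_pvalue(c=10, m=m, N=100, M=30) for m in range(11)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matches_scipy_on_large_population(self):
        # stability check at the population scale of a real PPI network
        for (c, m, N, M) in [(20, 15, 5000, 60), (100, 5, 9335, 400), (8, 8, 4950, 9)]:
            expected = float(hypergeom.sf(m - 1, N, M, c))
            assert hypergeom_pvalue(c=c, m=m, N=N, M=M) == pytest.approx(
                expected, rel=1e-9
            )

    def test_matches_exact_summation_spot_checks(self):
        for (c, m, N, M) in [(5, 2, 25, 9), (7, 7, 30, 10), (12, 4, 28, 14)]:
            assert hypergeom_pvalue(c=c, m=m, N=N, M=M) == pytest.approx(
                naive_hypergeom_tail(c, m, N, M), rel=1e-12
            )


class TestEnrichModule:
    def test_planted_module_finds_its_private_term(
        self, planted_network, planted_complexes, planted_annotations
    ):
        population = build_population(planted_network.nodes(), planted_annotations)
        terms = planted_term_map(planted_complexes)
        name = sorted(planted_complexes.complexes)[0]
        module = planted_complexes.complexes[name]
        result = enrich_module(module, planted_annotations, population)
        assert result.best_term == terms[name]
        assert result.significant

    def test_root_only_annotation_not_significant(self):
        ann = AnnotationSet(
            "BP",
            direct={g: {ROOT_TERM} for g in "ABCDEFGH"},
            dag={ROOT_TERM: set()},
        )
        result = enrich_module({"A", "B", "C"}, ann, set("ABCDEFGH"))
        assert result.corrected_p == 1.0
        assert not result.significant

    def test_single_term_uncorrected(self):
        ann = AnnotationSet("BP", direct={"A": {"T"}, "B": {"T"}}, dag={"T": set()})
        result = enrich_module({"A", "B"}, ann, {"A", "B", "C", "D"})
        assert result.n_terms_tested == 1
        assert result.corrected_p == result.raw_p

    def test_unannotated_module_yields_no_term(self, planted_annotations):
        result = enrich_module({"NOT_A_GENE"}, planted_annotations, {"NOT_A_GENE"})
        assert result.best_term is None
        assert not result.significant

    def test_corrected_at_least_raw(
        self, planted_modules, planted_annotations, planted_network
    ):
        population = build_population(planted_network.nodes(), planted_annotations)
        for result in enrich_modules(planted_modules, planted_annotations, population):
            assert result.corrected_p >= result.raw_p
            assert result.corrected_p <= 1.0


class TestEnrichmentReport:
    def _result(self, p):
        return EnrichmentResult(
            module_id="m", ontology="BP", best_term="T", raw_p=p,
            corrected_p=p, significant=p <= 0.01, n_terms_tested=1, module_size=3,
        )

    def test_interval_bins(self):
        report = enrichment_report([self._result(p) for p in (1e-20, 1e-3, 0.5)])
        assert report.bin_counts["<1e-15"] == 1
        assert report.bin_counts["[1e-5,0.01)"] == 1
        assert report.bin_counts[">=0.01"] == 1
        assert sum(report.bin_counts.values()) == report.n_modules

    def test_all_significant_proportion(self):
        report = enrichment_report([self._result(1e-5)] * 3)
        assert report.proportion_significant == 1.0

    def test_average_neglog10(self):
        report = enrichment_report([self._result(0.01), self._result(0.0001)])
        assert report.avg_neglog10_p == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enrichment_report([])

    def test_bin_labels_cover_all(self):
        assert len(BIN_LABELS) == 5
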