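"""Complement reasoning, query-plan generation, and end-to-end hypothesis tests."""

import itertools

import pytest

from tmarq import (
    FactorConfig,
    SyntheticConfig,
    build_hypothesis_model,
    complement_value_set,
    contingency_from_dataset,
    dataset_to_graph,
    generate_query_plans,
    generate_tma_dataset,
)
from tmarq.errors import (
    DegenerateHypothesisError,
    DomainError,
    AttributeLookupError,
    NoDataError,
)
from tmarq.hypothesis_engine import (
    HypothesisModel,
    FactorSpec,
    assemble_contingency_table,
    test_hypothesis as run_hypothesis_test,
)
from tmarq.tma_model import AttributeDefinition


class TestComplementValueSet:
    def test_grade_complement(self, registry):
        grade = registry.lookup("HistologicGrade", "Colon cancer")
        assert complement_value_set(grade, ["High-grade"]) == \
            ("Low-grade", "Intermediate-grade")

    def test_intensity_complement(self, registry):
        intensity = registry.lookup("Apaf-1 Intensity", "Colon cancer")
        assert complement_value_set(intensity, ["0"]) == ("1", "2", "3")

    def test_full_set_is_degenerate(self, registry):
        intensity = registry.lookup("Apaf-1 Intensity", "Colon cancer")
        with pytest.raises(DegenerateHypothesisError):
            complement_value_set(intensity, ["0", "1", "2", "3"])

    def test_empty_set_is_degenerate(self, registry):
        intensity = registry.lookup("Apaf-1 Intensity", "Colon cancer")
        with pytest.raises(DegenerateHypothesisError):
            complement_value_set(intensity, [])

    def test_non_subset_is_domain_error(self, registry):
        grade = registry.lookup("HistologicGrade", "Colon cancer")
        with pytest.raises(DomainError):
            complement_value_set(grade, ["ultra-grade"])

    def test_partition_property(self):
        attr = AttributeDefinition("X", "*", ("a", "b", "c", "d"))
        for r in (1, 2, 3):
            for hyp in itertools.combinations(attr.permissible_values, r):
                comp = complement_value_set(attr, hyp)
                assert set(hyp) | set(comp) == set(attr.permissible_values)
                assert set(hyp) & set(comp) == set()


class TestBuildModel:
    def test_apaf1_grade_model(self, apaf1_model):
        assert apaf1_model.classifier.complement_values == ("1", "2", "3")
        assert apaf1_model.dependent.complement_values == \
            ("Low-grade", "Intermediate-grade")

    def test_leptin_nodal_model(self, registry):
        model = build_hypothesis_model(
            ("Diagnosis", "Colon cancer"), "Leptin", ["positive"],
            "NodalStatus", ["N0"], registry)
        assert model.classifier.complement_values == ("negative",)
        assert model.dependent.complement_values == ("N1", "N2", "N3")

    def test_whole_permissible_set_rejected(self, registry):
        with pytest.raises(DegenerateHypothesisError):
            build_hypothesis_model(
                ("Diagnosis", "Colon cancer"), "Apaf-1 Intensity",
                ["0", "1", "2", "3"], "HistologicGrade", ["High-grade"], registry)

    def test_unregistered_attribute_rejected(self, registry):
        with pytest.raises(AttributeLookupError):
            build_hypothesis_model(
                ("Diagnosis", "Colon cancer"), "Nonexistent", ["x"],
                "HistologicGrade", ["High-grade"], registry)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(DomainError):
            HypothesisModel(
                "Diagnosis", "Colon cancer",
                FactorSpec("A", ("x",), ("x", "y")),
                FactorSpec("B", ("u",), ("v",)))


class TestQueryPlans:
    def test_exactly_four_plans_with_formula_valuesets(self, apaf1_model):
        """Classifier gets the hypothesis set for plans 1 and 3, the dependent
        factor for plans 1 and 2; the rest get complements."""
        plans = generate_query_plans(apaf1_model)
        assert [p.index for p in plans] == [1, 2, 3, 4]
        hyp2, comp2 = ("0",), ("1", "2", "3")
        hyp3, comp3 = ("High-grade",), ("Low-grade", "Intermediate-grade")
        expected = {
            1: (hyp2, hyp3), 2: (comp2, hyp3), 3: (hyp2, comp3), 4: (comp2, comp3),
        }
        for plan in plans:
            assert plan.valuesets[1] == ("Colon cancer",)
            assert (plan.valuesets[2], plan.valuesets[3]) == expected[plan.index]

    def test_assignments_cover_the_two_by_two(self, apaf1_model):
        plans = generate_query_plans(apaf1_model)
        seen = {(p.valuesets[2], p.valuesets[3]) for p in plans}
        assert len(seen) == 4

    def test_value_pairs_partition_across_plans(self, apaf1_model, registry):
        """Every (classifier value, dependent value) pair of the permissible
        product is matched by exactly one plan."""
        plans = generate_query_plans(apaf1_model)
        intensity = registry.lookup("Apaf-1 Intensity", "Colon cancer")
        grade = registry.lookup("HistologicGrade", "Colon cancer")
        for cv in intensity.permissible_values:
            for dv in grade.permissible_values:
                owners = [p.index for p in plans
                          if cv in p.valuesets[2] and dv in p.valuesets[3]]
                assert len(owners) == 1

    def test_one_conjunctive_query_per_value_pair(self, apaf1_model):
        plans = generate_query_plans(apaf1_model)
        for plan in plans:
            assert len(plan.queries) == \
                len(plan.valuesets[2]) * len(plan.valuesets[3])
            for query in plan.queries:
                assert str(query.count_variable) == "cr"


class TestEndToEnd:
    def test_worked_example(self, apaf1_model, worked_graph):
        result = run_hypothesis_test(apaf1_model, worked_graph, alpha=0.01)
        assert result.table.cells() == (26, 4, 6, 19)
        assert result.p_value < 0.0001
        assert result.decision == "supported"

    def test_worked_example_provenance(self, apaf1_model, worked_graph):
        result = run_hypothesis_test(apaf1_model, worked_graph)
        assert (result.n_cores, result.n_slides, result.n_experiments) == (55, 5, 3)
        assert result.n_cores == result.table.total

    def test_flat_table_is_rejected_decision(self, registry):
        """Identical dependent-value distributions in both core collections
        give p = 1 and a 'rejected' decision."""
        from tmarq.tma_model import TmaDataset
        ds = TmaDataset()
        ds.add_row("Experiment", Id="E1", Name="x", ExpType="TMA")
        ds.add_row("Block", Id="B1")
        ds.add_row("Slide", Id="SL1", ExperimentId="E1", BlockId="B1", MarkerName="Apaf-1")
        i = 0
        for intensity in ("0", "1"):
            for grade in ("High-grade", "Low-grade"):
                for _ in range(5):
                    i += 1
                    ds.add_row("Core", Id=f"C{i}", SlideId="SL1", SampleId=f"S{i}")
                    ds.add_row("SampleAttribute", SampleId=f"S{i}",
                               AttributeName="Diagnosis", Value="Colon cancer")
                    ds.add_row("SampleAttribute", SampleId=f"S{i}",
                               AttributeName="HistologicGrade", Value=grade)
                    ds.add_row("StainingResult", CoreId=f"C{i}", MarkerName="Apaf-1",
                               Intensity=intensity, Range=None)
        model = build_hypothesis_model(
            ("Diagnosis", "Colon cancer"), "Apaf-1 Intensity", ["0"],
            "HistologicGrade", ["High-grade"], registry)
        result = run_hypothesis_test(model, dataset_to_graph(ds))
        assert result.table.cells() == (5, 5, 5, 5)
        assert result.p_value == pytest.approx(1.0)
        assert result.decision == "rejected"

    def test_no_matching_cores_raises(self, apaf1_model):
        from tmarq.rdf_mapping import TripleGraph
        with pytest.raises(NoDataError):
            run_hypothesis_test(apaf1_model, TripleGraph())

    def test_conservation_of_cores(self, apaf1_model, worked_dataset, worked_graph):
        """The four cells sum to the number of cores with the shared property
        and non-missing classifier and dependent values."""
        result = run_hypothesis_test(apaf1_model, worked_graph)
        expected = 0
        for core in worked_dataset.tables["Core"]:
            sample = core["SampleId"]
            if worked_dataset.sample_attribute(sample, "Diagnosis") != "Colon cancer":
                continue
            if worked_dataset.staining_intensity(core["Id"], "Apaf-1") is None:
                continue
            if worked_dataset.sample_attribute(sample, "HistologicGrade") is None:
                continue
            expected += 1
        assert result.table.total == expected == 55

    def test_exchange_symmetry(self, registry, worked_graph):
        """Swapping hypothesis and complement sets of the classifier permutes
        table columns and preserves the two-sided p-value."""
        base = build_hypothesis_model(
            ("Diagnosis", "Colon cancer"), "Apaf-1 Intensity", ["0"],
            "HistologicGrade", ["High-grade"], registry)
        swapped = build_hypothesis_model(
            ("Diagnosis", "Colon cancer"), "Apaf-1 Intensity", ["1", "2", "3"],
            "HistologicGrade", ["High-grade"], registry)
        r1 = run_hypothesis_test(base, worked_graph)
        r2 = run_hypothesis_test(swapped, worked_graph)
        t1, t2 = r1.table, r2.table
        assert (t2.n11, t2.n12, t2.n21, t2.n22) == (t1.n12, t1.n11, t1.n22, t1.n21)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    @pytest.mark.parametrize("seed,odds_ratio,missing_rate", [
        (1, 1.0, 0.0), (2, 5.0, 0.1), (3, 20.0, 0.2), (4, 0.3, 0.05),
    ])
    def test_rdf_path_equals_tabular_path(self, registry, seed, odds_ratio, missing_rate):
        """The triple-graph route and direct tabular filtering agree cell by
        cell on randomly generated datasets (including missing data)."""
        config = SyntheticConfig(
            n_experiments=2, slides_per_experiment=2, cores_per_slide=8,
            odds_ratio=odds_ratio, missing_rate=missing_rate, seed=seed)
        dataset = generate_tma_dataset(config)
        model = build_hypothesis_model(
            ("Diagnosis", "Colon cancer"), "Apaf-1 Intensity", ["0"],
            "HistologicGrade", ["High-grade"], registry)
        graph = dataset_to_graph(dataset)
        plans = generate_query_plans(model)
        rdf_table, nc, ns, ne = assemble_contingency_table(graph, plans)
        tab_table, tnc, tns, tne = contingency_from_dataset(model, dataset)
        assert rdf_table.cells() == tab_table.cells()
        assert (nc, ns, ne) == (tnc, tns, tne)
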