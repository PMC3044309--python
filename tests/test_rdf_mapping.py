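"""Row-to-triple mapping, triple-graph semantics, query evaluation, serialization."""

import pytest
from hypothesis import given, settings, strategies as st

from tmarq import (
    CountQuery,
    Literal,
    Triple,
    TripleGraph,
    TriplePattern,
    URI,
    Variable,
    dataset_to_graph,
    default_mapping_rule,
    evaluate_count_query,
    parse_graph,
    row_to_triples,
    serialize_graph,
)
from tmarq.errors import MappingError, ParseError
from tmarq.tma_model import TmaDataset

from conftest import count_query_oracle

RULE = default_mapping_rule()


class TestRowToTriples:
    def test_experiment_row_yields_two_triples_with_rule_predicates(self):
        """A three-column row maps to two triples; 'Name' becomes 'hasName'
        while 'ExpType' keeps its column name, exactly as the rule states."""
        triples = row_to_triples(
            "Experiment", {"Id": "1", "Name": "colonTMA1", "ExpType": "TMA"}, RULE)
        assert len(triples) == 2
        predicates = {t.predicate.rsplit("#", 1)[1] for t in triples}
        assert predicates == {"hasName", "ExpType"}
        assert {str(t.object) for t in triples} == {"colonTMA1", "TMA"}
        assert all(t.subject == RULE.subject_uri("Experiment", ["1"]) for t in triples)

    def test_foreign_key_object_is_referenced_subject_uri(self):
        slide = row_to_triples(
            "Slide",
            {"Id": "SL1", "ExperimentId": "1", "BlockId": "B1", "MarkerName": "Apaf-1"},
            RULE)
        experiment_subject = RULE.subject_uri("Experiment", ["1"])
        fk = [t for t in slide if t.object == experiment_subject]
        assert len(fk) == 1
        assert isinstance(fk[0].object, URI)

    def test_all_missing_row_yields_no_triples(self):
        assert row_to_triples(
            "Experiment", {"Id": "1", "Name": None, "ExpType": None}, RULE) == []

    def test_eav_pivot_puts_attribute_name_in_predicate(self):
        triples = row_to_triples(
            "SampleAttribute",
            {"SampleId": "S1", "AttributeName": "HistologicGrade", "Value": "High-grade"},
            RULE)
        assert len(triples) == 1
        t = triples[0]
        assert t.subject == RULE.subject_uri("Sample", ["S1"])
        assert t.predicate == RULE.predicate_uri("HistologicGrade")
        assert t.object == Literal("High-grade")

    def test_unmapped_column_is_mapping_error(self):
        from tmarq.rdf_mapping import MappingRule, TableRule
        bare = MappingRule(RULE.base_uri, {"Experiment": TableRule("Experiment", ("Id",), {})})
        with pytest.raises(MappingError):
            row_to_triples("Experiment", {"Id": "1", "Name": "x", "ExpType": "TMA"}, bare)


class TestDatasetToGraph:
    def test_hand_counted_triple_total(self):
        """1 Experiment row (2 non-key cols) + 1 Slide row (3 mapped cols)."""
        ds = TmaDataset()
        ds.add_row("Experiment", Id="1", Name="colonTMA1", ExpType="TMA")
        ds.add_row("Slide", Id="SL1", ExperimentId="1", BlockId="B1", MarkerName="Apaf-1")
        graph = dataset_to_graph(ds)
        assert len(graph) == 2 + 3

    def test_empty_dataset_gives_empty_graph(self):
        assert len(dataset_to_graph(TmaDataset())) == 0

    def test_distinct_keys_never_share_subject(self, worked_dataset, worked_graph):
        subjects = {t.subject for t in worked_graph
                    if str(t.subject).startswith(RULE.base_uri + "/Core/")}
        assert len(subjects) == len(worked_dataset.tables["Core"])

    def test_mapping_is_deterministic(self, worked_dataset):
        assert dataset_to_graph(worked_dataset) == dataset_to_graph(worked_dataset)

    def test_set_semantics_reinsertion_keeps_answers(self, worked_dataset, worked_graph):
        graph = dataset_to_graph(worked_dataset)
        size = len(graph)
        graph.update(list(worked_graph))
        assert len(graph) == size
        query = CountQuery(
            (TriplePattern(Variable("cr"),
                           RULE.predicate_uri("Core_Slide"), Variable("sl")),),
            Variable("cr"))
        assert evaluate_count_query(graph, query) == \
            evaluate_count_query(worked_graph, query)


class TestCountQueries:
    def test_query_on_empty_graph_is_zero(self):
        query = CountQuery(
            (TriplePattern(Variable("cr"), URI("urn:p"), Literal("x")),), Variable("cr"))
        assert evaluate_count_query(TripleGraph(), query) == 0

    def test_single_pattern_counts_distinct_subjects(self):
        graph = TripleGraph(
            Triple(URI(f"urn:core/{i}"), URI("urn:type"), Literal("Core"))
            for i in range(7))
        graph.add(Triple(URI("urn:core/0"), URI("urn:other"), Literal("x")))
        query = CountQuery(
            (TriplePattern(Variable("cr"), URI("urn:type"), Literal("Core")),),
            Variable("cr"))
        assert evaluate_count_query(graph, query) == 7

    def test_join_on_shared_variable(self):
        graph = TripleGraph([
            Triple(URI("urn:a"), URI("urn:linked"), URI("urn:b")),
            Triple(URI("urn:b"), URI("urn:tag"), Literal("yes")),
            Triple(URI("urn:c"), URI("urn:linked"), URI("urn:d")),
        ])
        query = CountQuery((
            TriplePattern(Variable("x"), URI("urn:linked"), Variable("y")),
            TriplePattern(Variable("y"), URI("urn:tag"), Literal("yes")),
        ), Variable("x"))
        assert evaluate_count_query(graph, query) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_evaluator_matches_brute_force_oracle(self, data):
        """Random small graphs + random patterns: the indexed join evaluator
        agrees with exhaustive enumeration over all term assignments."""
        subjects = [URI(f"urn:s{i}") for i in range(4)]
        predicates = [URI(f"urn:p{i}") for i in range(3)]
        objects = subjects + [Literal(v) for v in "abc"]
        triples = data.draw(st.lists(
            st.builds(Triple, st.sampled_from(subjects), st.sampled_from(predicates),
                      st.sampled_from(objects)),
            min_size=1, max_size=25))
        graph = TripleGraph(triples)
        variables = [Variable(v) for v in ("x", "y", "z")]
        term_or_var = st.sampled_from(variables + predicates + objects)
        patterns = data.draw(st.lists(
            st.builds(TriplePattern, term_or_var, term_or_var, term_or_var),
            min_size=1, max_size=3))
        count_var = data.draw(st.sampled_from(variables))
        if not any(count_var in p.variables() for p in patterns):
            patterns.append(TriplePattern(count_var, predicates[0], Literal("a")))
        query = CountQuery(tuple(patterns), count_var)
        assert evaluate_count_query(graph, query) == count_query_oracle(graph, query)

    def test_tabular_count_commutes_with_mapping(self, worked_dataset, worked_graph):
        """Counting rows with a column predicate in the tables equals the
        one-pattern count query on the mapped graph."""
        tabular = sum(1 for r in worked_dataset.tables["StainingResult"]
                      if r["Intensity"] == "0")
        query = CountQuery(
            (TriplePattern(Variable("sr"), RULE.predicate_uri("hasIntensity"),
                           Literal("0")),),
            Variable("sr"))
        assert evaluate_count_query(worked_graph, query) == tabular


class TestSerialization:
    def test_empty_graph_round_trip(self):
        text = serialize_graph(TripleGraph(), "ntriples")
        assert text == ""
        assert len(parse_graph(text, "ntriples")) == 0

    @pytest.mark.parametrize("fmt", ["ntriples", "turtle"])
    def test_round_trip_both_formats(self, fmt):
        graph = TripleGraph([
            Triple(URI("urn:a"), URI("urn:p"), Literal('va"l\nue')),
            Triple(URI("urn:a"), URI("urn:q"), URI("urn:b")),
        ])
        assert parse_graph(serialize_graph(graph, fmt), fmt) == graph

    def test_ntriples_output_is_sorted_and_byte_stable(self, worked_graph):
        first = serialize_graph(worked_graph, "ntriples")
        second = serialize_graph(worked_graph, "ntriples")
        assert first == second
        lines = first.splitlines()
        assert lines == sorted(lines)

    def test_worked_graph_round_trips(self, worked_graph):
        assert parse_graph(serialize_graph(worked_graph, "ntriples")) == worked_graph

    def test_malformed_input_raises_parse_error(self):
        with pytest.raises(ParseError):
            parse_graph("<urn:a> <urn:p> .", "ntriples")
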