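"""Triadic hypothesis model, complement reasoning, query generation, testing.

A TMA-testable hypothesis has the form "in biological condition A, entity B
correlates (positively or negatively) with entity C":

* the **shared property** A restricts the samples (e.g. Diagnosis = "Colon
  cancer");
* the **classifier** B is an attribute plus a hypothesis-describing value set
  that splits cores into Core Collection A (hypothesis values) and Core
  Collection B (the complementary values);
* the **dependent property** C is a second attribute/value-set pair whose
  value distributions D1 and D2 within the two collections are compared.

Complementary value sets are inferred, not stated: given the hypothesis
values, the complement is the rest of the attribute's permissible value set,
so the two sets always partition the controlled vocabulary.

Four count queries are generated per hypothesis — one for each combination of
{hypothesis, complement} x {hypothesis, complement} over the classifier and
dependent factors — counting ``distinct ?cr`` (cores).  Their four answers
form the 2x2 contingency table handed to Fisher's exact test; the hypothesis
is *supported* when p < alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import (
    DegenerateHypothesisError,
    DomainError,
    NoDataError,
)
from .rdf_mapping import (
    CountQuery,
    Literal,
    MappingRule,
    TripleGraph,
    TriplePattern,
    Variable,
    default_mapping_rule,
    evaluate_select,
    link_predicate_name,
)
from .stats import ContingencyTable2x2, TestResult, fisher_exact
from .tma_model import (
    INTENSITY_SUFFIX,
    AttributeDefinition,
    AttributeRegistry,
)

DEFAULT_ALPHA = 0.01

CORE_VAR = Variable("cr")
SLIDE_VAR = Variable("sl")
EXPERIMENT_VAR = Variable("ex")
SAMPLE_VAR = Variable("s")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def complement_value_set(
    attribute: AttributeDefinition, hypothesis_values: Sequence[str]
) -> tuple[str, ...]:
    """Complement of the hypothesis values within the permissible value set.

    Preserves permissible-set order.  The hypothesis set must be a non-empty
    *proper* subset: an empty hypothesis or one covering the whole vocabulary
    leaves nothing to compare against and is rejected as degenerate.
    """
    hyp = list(dict.fromkeys(hypothesis_values))
    permissible = attribute.permissible_values
    extra = [v for v in hyp if v not in permissible]
    if extra:
        raise DomainError(
            f"values {extra} are not permissible for {attribute.name!r} "
            f"(context {attribute.context!r})"
        )
    if not hyp:
        raise DegenerateHypothesisError(f"empty hypothesis value set for {attribute.name!r}")
    complement = tuple(v for v in permissible if v not in hyp)
    if not complement:
        raise DegenerateHypothesisError(
            f"hypothesis values cover the whole permissible set of {attribute.name!r}"
        )
    return complement


@dataclass(frozen=True)
class FactorSpec:
    """One binarized factor: attribute plus hypothesis/complement value sets."""

    attribute: str
    hypothesis_values: tuple[str, ...]
    complement_values: tuple[str, ...]

    @property
    def is_staining(self) -> bool:
        """Staining factors follow the "<Marker> Intensity" naming convention."""
        return self.attribute.endswith(INTENSITY_SUFFIX)

    @property
    def marker(self) -> str:
        if not self.is_staining:
            raise DomainError(f"{self.attribute!r} is not a marker-intensity attribute")
        return self.attribute[: -len(INTENSITY_SUFFIX)]


@dataclass(frozen=True)
class HypothesisModel:
    """The triadic hypothesis: shared property, classifier, dependent property."""

    shared_attribute: str
    shared_value: str
    classifier: FactorSpec
    dependent: FactorSpec
    direction: str = "positive"  # descriptive metadata only

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise DomainError(f"direction must be positive/negative, got {self.direction!r}")
        for factor in (self.classifier, self.dependent):
            if not factor.hypothesis_values:
                raise DegenerateHypothesisError(
                    f"factor {factor.attribute!r} has an empty hypothesis value set"
                )
            if set(factor.hypothesis_values) & set(factor.complement_values):
                raise DomainError(
                    f"factor {factor.attribute!r}: hypothesis and complement sets overlap"
                )

    def describe(self) -> str:
        return (
            f"In {self.shared_attribute}={self.shared_value!r}: "
            f"{self.classifier.attribute} in {list(self.classifier.hypothesis_values)} "
            f"~ {self.dependent.attribute} in {list(self.dependent.hypothesis_values)}"
        )


def build_hypothesis_model(
    shared: tuple[str, str],
    classifier_attr: str,
    classifier_values: Sequence[str],
    dependent_attr: str,
    dependent_values: Sequence[str],
    registry: AttributeRegistry,
    direction: str = "positive",
) -> HypothesisModel:
    """Build a model, inferring complement sets from the registry.

    Attribute definitions are looked up in the shared value's context (e.g.
    "Colon cancer"), falling back to the wildcard context.
    """
    shared_attr, shared_value = shared
    context = shared_value
    cls_def = registry.lookup(classifier_attr, context)
    dep_def = registry.lookup(dependent_attr, context)
    classifier = FactorSpec(
        classifier_attr,
        tuple(dict.fromkeys(classifier_values)),
        complement_value_set(cls_def, classifier_values),
    )
    dependent = FactorSpec(
        dependent_attr,
        tuple(dict.fromkeys(dependent_values)),
        complement_value_set(dep_def, dependent_values),
    )
    return HypothesisModel(shared_attr, shared_value, classifier, dependent, direction)


# ---------------------------------------------------------------------------
# Query generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QueryPlan:
    """One of the four generated count queries.

    ``valuesets`` records the per-factor value-set assignment (factor 1 is the
    shared property, 2 the classifier, 3 the dependent property).  Value-set
    membership is realized as a disjunction: one conjunctive query per
    (classifier value, dependent value) pair, with distinct cores counted
    once across the whole plan.
    """

    index: int  # 1..4
    valuesets: dict[int, tuple[str, ...]]
    queries: tuple[CountQuery, ...]


def _skeleton_patterns(model: HypothesisModel, rule: MappingRule) -> list[TriplePattern]:
    """Core -> slide -> experiment linkage plus the shared-property match."""
    return [
        TriplePattern(CORE_VAR, rule.predicate_uri(link_predicate_name("Core", "Slide")),
                      SLIDE_VAR),
        TriplePattern(SLIDE_VAR,
                      rule.predicate_uri(link_predicate_name("Slide", "Experiment")),
                      EXPERIMENT_VAR),
        TriplePattern(CORE_VAR, rule.predicate_uri(link_predicate_name("Core", "Sample")),
                      SAMPLE_VAR),
        TriplePattern(SAMPLE_VAR, rule.predicate_uri(model.shared_attribute),
                      Literal(model.shared_value)),
    ]


def _factor_patterns(
    factor: FactorSpec, value: str, rule: MappingRule, result_var: Variable
) -> list[TriplePattern]:
    if factor.is_staining:
        return [
            TriplePattern(result_var,
                          rule.predicate_uri(link_predicate_name("StainingResult", "Core")),
                          CORE_VAR),
            TriplePattern(result_var, rule.predicate_uri("hasMarker"),
                          Literal(factor.marker)),
            TriplePattern(result_var, rule.predicate_uri("hasIntensity"), Literal(value)),
        ]
    return [TriplePattern(SAMPLE_VAR, rule.predicate_uri(factor.attribute), Literal(value))]


def generate_query_plans(
    model: HypothesisModel, rule: MappingRule | None = None
) -> list[QueryPlan]:
    """Generate exactly four count-query plans from a hypothesis model.

    The value-set assignment per plan index i and factor j is: the shared
    property for j=1; for the classifier (j=2) the hypothesis set when
    i in {1, 3}, else the complement; for the dependent property (j=3) the
    hypothesis set when i in {1, 2}, else the complement.  The four plans
    therefore cover the 2x2 of {hypothesis, complement} x {hypothesis,
    complement}, and every (classifier value, dependent value) pair in the
    product of permissible sets is matched by exactly one plan.
    """
    rule = rule or default_mapping_rule()
    plans: list[QueryPlan] = []
    for i in (1, 2, 3, 4):
        cls_set = model.classifier.hypothesis_values if i in (1, 3) \
            else model.classifier.complement_values
        dep_set = model.dependent.hypothesis_values if i in (1, 2) \
            else model.dependent.complement_values
        queries = []
        for cv in cls_set:
            for dv in dep_set:
                patterns = (
                    _skeleton_patterns(model, rule)
                    + _factor_patterns(model.classifier, cv, rule, Variable("srB"))
                    + _factor_patterns(model.dependent, dv, rule, Variable("srC"))
                )
                queries.append(CountQuery(tuple(patterns), CORE_VAR))
        plans.append(
            QueryPlan(
                index=i,
                valuesets={1: (model.shared_value,), 2: tuple(cls_set), 3: tuple(dep_set)},
                queries=tuple(queries),
            )
        )
    return plans


def evaluate_plan_bindings(
    graph: TripleGraph, plan: QueryPlan
) -> set[tuple]:
    """Distinct (core, slide, experiment) solutions over the plan's disjunction."""
    out: set[tuple] = set()
    for query in plan.queries:
        out |= evaluate_select(
            graph, query.patterns, [CORE_VAR, SLIDE_VAR, EXPERIMENT_VAR]
        )
    return out


def evaluate_plan(graph: TripleGraph, plan: QueryPlan) -> int:
    """count(distinct ?cr) over the plan's disjunction of conjunctive queries."""
    return len({sol[0] for sol in evaluate_plan_bindings(graph, plan)})


# ---------------------------------------------------------------------------
# Hypothesis testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HypothesisResult:
    model: HypothesisModel
    table: ContingencyTable2x2
    test: TestResult
    alpha: float
    n_cores: int
    n_slides: int
    n_experiments: int

    @property
    def p_value(self) -> float:
        return self.test.p_value

    @property
    def decision(self) -> str:
        return "supported" if self.p_value < self.alpha else "rejected"

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.model.describe(),
            "shared": {"attribute": self.model.shared_attribute,
                       "value": self.model.shared_value},
            "classifier": {
                "attribute": self.model.classifier.attribute,
                "hypothesis_values": list(self.model.classifier.hypothesis_values),
                "complement_values": list(self.model.classifier.complement_values),
            },
            "dependent": {
                "attribute": self.model.dependent.attribute,
                "hypothesis_values": list(self.model.dependent.hypothesis_values),
                "complement_values": list(self.model.dependent.complement_values),
            },
            "table": {"n11": self.table.n11, "n12": self.table.n12,
                      "n21": self.table.n21, "n22": self.table.n22},
            "p_value": self.p_value,
            "test": self.test.method,
            "alpha": self.alpha,
            "decision": self.decision,
            "provenance": {"cores": self.n_cores, "slides": self.n_slides,
                           "experiments": self.n_experiments},
        }

    def to_text(self) -> str:
        t = self.table
        lines = [
            f"Hypothesis: {self.model.describe()}",
            "",
            f"{'':>24} {'classifier=hyp':>16} {'classifier=comp':>16}",
            f"{'dependent=hyp':>24} {t.n11:>16d} {t.n12:>16d}",
            f"{'dependent=comp':>24} {t.n21:>16d} {t.n22:>16d}",
            "",
            f"p-value ({self.test.method}): {self.p_value:.6g}",
            f"decision at alpha={self.alpha}: {self.decision}",
            f"provenance: {self.n_cores} cores / {self.n_slides} slides / "
            f"{self.n_experiments} experiments",
        ]
        return "\n".join(lines)


def assemble_contingency_table(
    graph: TripleGraph, plans: Sequence[QueryPlan]
) -> tuple[ContingencyTable2x2, int, int, int]:
    """Evaluate the four plans and return the table plus provenance counts.

    Cell orientation: n11 <- plan 1 (hyp, hyp), n12 <- plan 2 (complement
    classifier, hyp dependent), n21 <- plan 3, n22 <- plan 4.
    """
    if len(plans) != 4:
        raise DomainError(f"expected 4 query plans, got {len(plans)}")
    solutions = [evaluate_plan_bindings(graph, plan) for plan in plans]
    counts = [len({sol[0] for sol in sols}) for sols in solutions]
    all_solutions = set().union(*solutions)
    cores = {sol[0] for sol in all_solutions}
    slides = {sol[1] for sol in all_solutions}
    experiments = {sol[2] for sol in all_solutions}
    table = ContingencyTable2x2(counts[0], counts[1], counts[2], counts[3])
    return table, len(cores), len(slides), len(experiments)


def contingency_from_dataset(model: HypothesisModel, dataset) -> tuple[ContingencyTable2x2, int, int, int]:
    """Assemble the 2x2 table by direct filtering of the tabular dataset.

    This is the relational twin of :func:`assemble_contingency_table`: the two
    routes must agree on every valid dataset (they are cross-checked in the
    test suite), but this one skips RDF materialization and is the fast path
    for large simulations.  Complete-case rule: cores missing either the
    classifier or the dependent value contribute to no cell.

    Returns ``(table, n_cores, n_slides, n_experiments)``.
    """
    core_sample = {r["Id"]: r["SampleId"] for r in dataset.tables["Core"]}
    core_slide = {r["Id"]: r["SlideId"] for r in dataset.tables["Core"]}
    slide_exp = {r["Id"]: r["ExperimentId"] for r in dataset.tables["Slide"]}
    sample_attr: dict[tuple[str, str], str] = {}
    for r in dataset.tables["SampleAttribute"]:
        if r["Value"] is not None:
            sample_attr[(r["SampleId"], r["AttributeName"])] = r["Value"]
    staining: dict[tuple[str, str], str] = {}
    for r in dataset.tables["StainingResult"]:
        if r["Intensity"] is not None:
            staining[(r["CoreId"], r["MarkerName"])] = r["Intensity"]

    def factor_value(factor: FactorSpec, core_id: str, sample_id: str) -> str | None:
        if factor.is_staining:
            return staining.get((core_id, factor.marker))
        return sample_attr.get((sample_id, factor.attribute))

    cells = [0, 0, 0, 0]
    slides: set[str] = set()
    experiments: set[str] = set()
    n_cores = 0
    for core_id, sample_id in core_sample.items():
        if sample_attr.get((sample_id, model.shared_attribute)) != model.shared_value:
            continue
        cls_value = factor_value(model.classifier, core_id, sample_id)
        dep_value = factor_value(model.dependent, core_id, sample_id)
        if cls_value is None or dep_value is None:
            continue
        if cls_value in model.classifier.hypothesis_values:
            col = 0
        elif cls_value in model.classifier.complement_values:
            col = 1
        else:
            continue
        if dep_value in model.dependent.hypothesis_values:
            row = 0
        elif dep_value in model.dependent.complement_values:
            row = 1
        else:
            continue
        cells[2 * row + col] += 1
        n_cores += 1
        slide = core_slide.get(core_id)
        if slide is not None:
            slides.add(slide)
            exp = slide_exp.get(slide)
            if exp is not None:
                experiments.add(exp)
    table = ContingencyTable2x2(*cells)
    return table, n_cores, len(slides), len(experiments)


def test_hypothesis(
    model: HypothesisModel,
    graph: TripleGraph,
    alpha: float = DEFAULT_ALPHA,
    rule: MappingRule | None = None,
) -> HypothesisResult:
    """Run the full pipeline: generate queries, count, Fisher's exact test.

    Raises :class:`NoDataError` when no core matches any of the four cells —
    the hypothesis is untestable on this graph.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    plans = generate_query_plans(model, rule)
    table, n_cores, n_slides, n_experiments = assemble_contingency_table(graph, plans)
    if table.total == 0:
        raise NoDataError(f"no cores match the hypothesis: {model.describe()}")
    result = fisher_exact(table)
    return HypothesisResult(
        model=model,
        table=table,
        test=result,
        alpha=alpha,
        n_cores=n_cores,
        n_slides=n_slides,
        n_experiments=n_experiments,
    )


# keep pytest from collecting the library entry point as a test
test_hypothesis.__test__ = False  # type: ignore[attr-defined]
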