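"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import pytest

from tmarq import (
    AttributeRegistry,
    build_hypothesis_model,
    dataset_to_graph,
    default_registry,
    make_glioma_fixture,
    make_worked_example_fixture,
)


@pytest.fixture(scope="session")
def registry() -> AttributeRegistry:
    return default_registry()


@pytest.fixture(scope="session")
def worked_dataset():
    return make_worked_example_fixture()


@pytest.fixture(scope="session")
def worked_graph(worked_dataset):
    return dataset_to_graph(worked_dataset)


@pytest.fixture(scope="session")
def apaf1_model(registry):
    return build_hypothesis_model(
        ("Diagnosis", "Colon cancer"),
        "Apaf-1 Intensity", ["0"],
        "HistologicGrade", ["High-grade"],
        registry,
    )


@pytest.fixture(scope="session")
def glioma_dataset():
    return make_glioma_fixture()


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational enumeration of the two-sided Fisher p-value.

    Enumerates every table with the observed margins, computes each
    hypergeometric probability as a Fraction, and sums those no more probable
    than the observed table (same 1e-7 relative tie rule as the library, but
    applied to exact rationals).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x: int) -> Fraction:
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), comb(n, r1))

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    observed = prob(a)
    cutoff = observed * (Fraction(10**7 + 1, 10**7))
    return float(sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= cutoff))


def count_query_oracle(graph, query) -> int:
    """Brute-force count-query evaluation: try every assignment of variables
    to graph terms and count distinct count-variable values among solutions."""
    from tmarq.rdf_mapping import Variable

    variables = sorted({v for p in query.patterns for v in p.variables()})
    terms = sorted(graph.terms() | {t.predicate for t in graph})

    def resolve(slot, assignment):
        return assignment[slot] if isinstance(slot, Variable) else slot

    matched = set()
    for combo in itertools.product(terms, repeat=len(variables)):
        assignment = dict(zip(variables, combo))
        ok = True
        for p in query.patterns:
            triple = (resolve(p.subject, assignment),
                      resolve(p.predicate, assignment),
                      resolve(p.object, assignment))
            if not any(t.as_tuple() == triple for t in graph):
                ok = False
                break
        if ok:
            matched.add(assignment[query.count_variable])
    return len(matched)
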