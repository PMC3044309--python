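"""Relational-to-RDF mapping, in-memory triple store, and count-query evaluation.

Each table row becomes a bundle of triples: the subject URI is minted from the
table's entity name and primary-key value(s); each non-key column yields one
triple whose predicate comes from the mapping rule.  Foreign-key columns yield
*object-URI* triples (the object is the subject URI of the referenced row),
literal columns yield plain string literals.  Entity–attribute–value tables
(``SampleAttribute``) use a pivot rule: the predicate is taken from the value
of one column and the object from another, so sample attributes appear as
direct predicates on the sample node.

Queries are the conjunctive fragment the hypothesis compiler emits: a basic
graph pattern (list of triple patterns with shared variables) plus a count
variable; the answer is the number of distinct bindings of that variable.
No OPTIONAL/UNION/FILTER — ordinal comparisons are expanded into explicit
value sets before compilation.

Serialization: deterministic sorted N-Triples is written natively; Turtle and
all parsing go through :mod:`rdflib`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence
from urllib.parse import quote

import rdflib

from .errors import MappingError, ParseError, ValidationError
from .tma_model import TableSchema, TmaDataset

DEFAULT_BASE_URI = "http://tmarq.example.org"


# ---------------------------------------------------------------------------
# Terms and triples
# ---------------------------------------------------------------------------

class URI(str):
    """An absolute URI term."""

    __slots__ = ()

    def __repr__(self) -> str:
        return f"<{str(self)}>"


class Literal(str):
    """A plain string literal term (no datatype/language tagging)."""

    __slots__ = ()

    def __repr__(self) -> str:
        return f'"{str(self)}"'


Term = URI | Literal


@dataclass(frozen=True)
class Triple:
    subject: URI
    predicate: URI
    object: Term

    def __post_init__(self) -> None:
        if not isinstance(self.subject, URI) or not self.subject:
            raise ValidationError("triple subject must be a non-empty URI")
        if not isinstance(self.predicate, URI) or not self.predicate:
            raise ValidationError("triple predicate must be a non-empty URI")
        if not isinstance(self.object, (URI, Literal)) or self.object == "":
            raise ValidationError("triple object must be a non-empty URI or Literal")

    def as_tuple(self) -> tuple[URI, URI, Term]:
        return (self.subject, self.predicate, self.object)


class TripleGraph:
    """Set-semantics triple store with subject / predicate / (predicate, object) indexes."""

    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: set[Triple] = set()
        self._by_subject: dict[URI, set[Triple]] = {}
        self._by_predicate: dict[URI, set[Triple]] = {}
        self._by_pred_obj: dict[tuple[URI, Term], set[Triple]] = {}
        for t in triples:
            self.add(t)

    def add(self, triple: Triple) -> None:
        if triple in self._triples:
            return
        self._triples.add(triple)
        self._by_subject.setdefault(triple.subject, set()).add(triple)
        self._by_predicate.setdefault(triple.predicate, set()).add(triple)
        self._by_pred_obj.setdefault((triple.predicate, triple.object), set()).add(triple)

    def update(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.add(t)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripleGraph):
            return NotImplemented
        return self._triples == other._triples

    def terms(self) -> set[Term]:
        """All distinct subject/object terms (used by the brute-force oracle)."""
        out: set[Term] = set()
        for t in self._triples:
            out.add(t.subject)
            out.add(t.object)
        return out

    def match(
        self,
        subject: URI | None = None,
        predicate: URI | None = None,
        object: Term | None = None,
    ) -> Iterator[Triple]:
        """Iterate triples matching the given constants (None = wildcard)."""
        if predicate is not None and object is not None:
            candidates = self._by_pred_obj.get((predicate, object), set())
        elif subject is not None:
            candidates = self._by_subject.get(subject, set())
        elif predicate is not None:
            candidates = self._by_predicate.get(predicate, set())
        else:
            candidates = self._triples
        for t in candidates:
            if subject is not None and t.subject != subject:
                continue
            if predicate is not None and t.predicate != predicate:
                continue
            if object is not None and t.object != object:
                continue
            yield t

    def count_match(self, subject=None, predicate=None, object=None) -> int:
        return sum(1 for _ in self.match(subject, predicate, object))


# ---------------------------------------------------------------------------
# Mapping rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnRule:
    """How one non-key column maps to a triple.

    Exactly one of ``predicate`` (literal-valued triple) or ``link_entity``
    (object-URI triple pointing at another row's subject) is set; for links
    the predicate defaults to ``<Table>_<Entity>``.
    """

    predicate: str | None = None
    link_entity: str | None = None

    def __post_init__(self) -> None:
        if (self.predicate is None) == (self.link_entity is None):
            raise ValidationError("ColumnRule needs exactly one of predicate/link_entity")


@dataclass(frozen=True)
class TableRule:
    """Mapping rule for one table.

    ``subject_key`` names the columns whose values mint the subject URI under
    ``subject_entity``.  Plain tables list a :class:`ColumnRule` per non-key
    column; EAV tables instead set ``predicate_from``/``object_from`` so that
    the predicate name is read from a column *value*.
    """

    subject_entity: str
    subject_key: tuple[str, ...]
    columns: Mapping[str, ColumnRule] = field(default_factory=dict)
    predicate_from: str | None = None
    object_from: str | None = None


@dataclass(frozen=True)
class MappingRule:
    base_uri: str
    tables: Mapping[str, TableRule]

    def subject_uri(self, entity: str, key_values: Sequence[str]) -> URI:
        path = "/".join(quote(str(v), safe="") for v in key_values)
        return URI(f"{self.base_uri}/{quote(entity, safe='')}/{path}")

    def predicate_uri(self, name: str) -> URI:
        return URI(f"{self.base_uri}/vocab#{quote(name, safe='')}")


def default_mapping_rule(base_uri: str = DEFAULT_BASE_URI) -> MappingRule:
    """Mapping rule for the default TMA schema.

    Predicate names are taken verbatim from this rule (``Name`` maps to
    ``hasName`` but ``ExpType`` stays ``ExpType``); there is no automatic
    prefixing convention.
    """
    return MappingRule(
        base_uri=base_uri,
        tables={
            "Experiment": TableRule(
                "Experiment", ("Id",),
                {"Name": ColumnRule(predicate="hasName"),
                 "ExpType": ColumnRule(predicate="ExpType")},
            ),
            "Slide": TableRule(
                "Slide", ("Id",),
                {"ExperimentId": ColumnRule(link_entity="Experiment"),
                 "BlockId": ColumnRule(link_entity="Block"),
                 "MarkerName": ColumnRule(predicate="hasMarker")},
            ),
            "Block": TableRule("Block", ("Id",), {}),
            "Core": TableRule(
                "Core", ("Id",),
                {"SlideId": ColumnRule(link_entity="Slide"),
                 "SampleId": ColumnRule(link_entity="Sample")},
            ),
            "SampleAttribute": TableRule(
                "Sample", ("SampleId",),
                predicate_from="AttributeName", object_from="Value",
            ),
            "StainingResult": TableRule(
                "StainingResult", ("CoreId", "MarkerName"),
                {"CoreId": ColumnRule(link_entity="Core"),
                 "MarkerName": ColumnRule(predicate="hasMarker"),
                 "Intensity": ColumnRule(predicate="hasIntensity"),
                 "Range": ColumnRule(predicate="hasRange")},
            ),
        },
    )


def link_predicate_name(table: str, entity: str) -> str:
    return f"{table}_{entity}"


def row_to_triples(table: str, row: Mapping[str, str | None], rule: MappingRule) -> list[Triple]:
    """Map one row to its triples.

    Missing values (``None``) emit no triple for that column.  A non-key
    column without a rule entry raises :class:`MappingError`.
    """
    try:
        trule = rule.tables[table]
    except KeyError:
        raise MappingError(f"no mapping rule for table {table!r}") from None

    key_values = [row.get(c) for c in trule.subject_key]
    if any(v is None for v in key_values):
        raise MappingError(f"table {table!r}: missing subject-key value in row {dict(row)!r}")
    subject = rule.subject_uri(trule.subject_entity, [str(v) for v in key_values])

    triples: list[Triple] = []

    if trule.predicate_from is not None:
        # EAV pivot: predicate from one column's value, object from another's
        pname = row.get(trule.predicate_from)
        ovalue = row.get(trule.object_from)  # type: ignore[arg-type]
        if pname is not None and ovalue is not None:
            triples.append(Triple(subject, rule.predicate_uri(pname), Literal(ovalue)))
        return triples

    for column, value in row.items():
        if column in trule.subject_key and column not in trule.columns:
            continue
        if column not in trule.columns:
            raise MappingError(f"table {table!r}: column {column!r} has no mapping rule")
        if value is None:
            continue
        crule = trule.columns[column]
        if crule.link_entity is not None:
            pred = rule.predicate_uri(link_predicate_name(table, crule.link_entity))
            obj: Term = rule.subject_uri(crule.link_entity, [value])
        else:
            pred = rule.predicate_uri(crule.predicate)  # type: ignore[arg-type]
            obj = Literal(value)
        triples.append(Triple(subject, pred, obj))
    return triples


def dataset_to_graph(dataset: TmaDataset, rule: MappingRule | None = None) -> TripleGraph:
    """Map every row of every table; deterministic in the dataset contents."""
    rule = rule or default_mapping_rule()
    graph = TripleGraph()
    for table in dataset.schema:
        if table not in rule.tables:
            raise MappingError(f"no mapping rule for table {table!r}")
        for row in dataset.tables[table]:
            graph.update(row_to_triples(table, row, rule))
    return graph


# ---------------------------------------------------------------------------
# Conjunctive count queries
# ---------------------------------------------------------------------------

class Variable(str):
    """A named query variable, e.g. ``Variable("cr")`` (rendered ``?cr``)."""

    __slots__ = ()

    def __repr__(self) -> str:
        return f"?{str(self)}"


PatternTerm = Variable | URI | Literal


@dataclass(frozen=True)
class TriplePattern:
    subject: PatternTerm
    predicate: PatternTerm
    object: PatternTerm

    def variables(self) -> set[Variable]:
        return {t for t in (self.subject, self.predicate, self.object)
                if isinstance(t, Variable)}

    def bound_count(self, bindings: Mapping[Variable, Term]) -> int:
        n = 0
        for t in (self.subject, self.predicate, self.object):
            if not isinstance(t, Variable) or t in bindings:
                n += 1
        return n


@dataclass(frozen=True)
class CountQuery:
    """``SELECT count(distinct ?<count_variable>) WHERE { patterns }``."""

    patterns: tuple[TriplePattern, ...]
    count_variable: Variable

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValidationError("CountQuery needs at least one pattern")
        if not any(self.count_variable in p.variables() for p in self.patterns):
            raise ValidationError(
                f"count variable ?{self.count_variable} appears in no pattern"
            )


def _resolve(term: PatternTerm, bindings: Mapping[Variable, Term]):
    """Constant value of a pattern slot under bindings, or None if still free."""
    if isinstance(term, Variable):
        return bindings.get(term)
    return term


def evaluate_select(
    graph: TripleGraph,
    patterns: Sequence[TriplePattern],
    project: Sequence[Variable],
) -> set[tuple[Term, ...]]:
    """All distinct projected bindings of the basic graph pattern.

    Patterns are joined greedily, most-bound-first; only correctness of the
    solution set is contractual.
    """
    solutions: list[dict[Variable, Term]] = [{}]
    remaining = list(patterns)
    while remaining:
        if not solutions:
            return set()
        bindings0 = solutions[0]
        remaining.sort(key=lambda p: -p.bound_count(bindings0))
        pattern = remaining.pop(0)
        new_solutions: list[dict[Variable, Term]] = []
        for bindings in solutions:
            s = _resolve(pattern.subject, bindings)
            p = _resolve(pattern.predicate, bindings)
            o = _resolve(pattern.object, bindings)
            for triple in graph.match(
                s if isinstance(s, URI) else None,
                p if isinstance(p, URI) else None,
                o if isinstance(o, (URI, Literal)) else None,
            ):
                ext = dict(bindings)
                ok = True
                for slot, value in (
                    (pattern.subject, triple.subject),
                    (pattern.predicate, triple.predicate),
                    (pattern.object, triple.object),
                ):
                    if isinstance(slot, Variable):
                        if slot in ext and ext[slot] != value:
                            ok = False
                            break
                        ext[slot] = value
                    elif slot != value:
                        ok = False
                        break
                if ok:
                    new_solutions.append(ext)
        solutions = new_solutions
    out: set[tuple[Term, ...]] = set()
    for bindings in solutions:
        if all(v in bindings for v in project):
            out.add(tuple(bindings[v] for v in project))
    return out


def evaluate_bindings(graph: TripleGraph, query: CountQuery) -> set[Term]:
    """Distinct values of the count variable over all solutions."""
    return {t[0] for t in evaluate_select(graph, query.patterns, [query.count_variable])}


def evaluate_count_query(graph: TripleGraph, query: CountQuery) -> int:
    """Number of distinct bindings of the count variable (0 if no solutions)."""
    return len(evaluate_bindings(graph, query))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _nt_escape(s: str) -> str:
    return (
        s.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def _nt_term(term: Term) -> str:
    if isinstance(term, URI):
        return f"<{term}>"
    return f'"{_nt_escape(str(term))}"'


def serialize_graph(graph: TripleGraph, format: str = "ntriples") -> str:
    """Serialize to N-Triples (sorted line-per-triple, byte-stable) or Turtle."""
    if format == "ntriples":
        lines = sorted(
            f"<{t.subject}> <{t.predicate}> {_nt_term(t.object)} ."
            for t in graph
        )
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "turtle":
        g = _to_rdflib(graph)
        return g.serialize(format="turtle")
    raise ValidationError(f"unsupported serialization format {format!r}")


def parse_graph(text: str, format: str = "ntriples") -> TripleGraph:
    """Parse N-Triples or Turtle text into a :class:`TripleGraph`."""
    if format not in ("ntriples", "turtle"):
        raise ValidationError(f"unsupported serialization format {format!r}")
    g = rdflib.Graph()
    try:
        g.parse(data=text, format="nt" if format == "ntriples" else "turtle")
    except Exception as exc:  # rdflib raises format-specific errors
        raise ParseError(f"malformed {format} input: {exc}") from exc
    graph = TripleGraph()
    for s, p, o in g:
        if not isinstance(s, rdflib.URIRef) or not isinstance(p, rdflib.URIRef):
            raise ParseError("only URI subjects/predicates are supported")
        obj: Term = URI(str(o)) if isinstance(o, rdflib.URIRef) else Literal(str(o))
        graph.add(Triple(URI(str(s)), URI(str(p)), obj))
    return graph


def _to_rdflib(graph: TripleGraph) -> rdflib.Graph:
    g = rdflib.Graph()
    for t in graph:
        o = rdflib.URIRef(str(t.object)) if isinstance(t.object, URI) \
            else rdflib.Literal(str(t.object))
        g.add((rdflib.URIRef(str(t.subject)), rdflib.URIRef(str(t.predicate)), o))
    return g
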