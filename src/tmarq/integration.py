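"""Marker-mediated integration of TMA and DNA-microarray data.

Expression-array probes and TMA antibodies measure the same gene product on
different platforms; a probe-to-antibody map (e.g. ``201983_s_at -> EGFR``)
is the bridge.  The cross-platform query supported here: given a probe, find
its antibody and report the distribution of histologies among the cores where
that antibody stained strongly (intensity above an ordinal threshold).

Expression values themselves are not modeled — after the mapping hop the
query touches only TMA staining data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import DomainError, NotFoundError, ParseError, ValidationError
from .rdf_mapping import (
    Literal,
    MappingRule,
    TripleGraph,
    TriplePattern,
    Variable,
    default_mapping_rule,
    evaluate_select,
    link_predicate_name,
)
from .tma_model import INTENSITY_SUFFIX, AttributeRegistry, WILDCARD_CONTEXT

_CR = Variable("cr")
_S = Variable("s")
_SR = Variable("sr")

DEFAULT_HISTOLOGY_ATTRIBUTE = "Histology"


@dataclass(frozen=True)
class ProbeAntibodyMap:
    """Exact-match map from array probe identifiers to antibody names."""

    entries: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs) -> "ProbeAntibodyMap":
        entries: dict[str, str] = {}
        for probe, antibody in pairs:
            if probe in entries:
                raise ValidationError(f"duplicate probe identifier {probe!r}")
            if not probe or not antibody:
                raise ValidationError("probe and antibody identifiers must be non-empty")
            entries[probe] = antibody
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeAntibodyMap":
        """Load a two-column (probe_id, antibody) TSV with header row."""
        path = Path(path)
        pairs = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise ParseError("empty probe map", str(path), 1) from None
            if len(header) != 2:
                raise ParseError(f"expected 2 columns, got {header!r}", str(path), 1)
            for lineno, cells in enumerate(reader, start=2):
                if len(cells) != 2:
                    raise ParseError(f"expected 2 cells, got {cells!r}", str(path), lineno)
                pairs.append((cells[0].strip(), cells[1].strip()))
        try:
            return cls.from_pairs(pairs)
        except ValidationError as exc:
            raise ValidationError(f"{exc} [{path}]") from exc

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["probe_id", "antibody"])
            for probe in sorted(self.entries):
                writer.writerow([probe, self.entries[probe]])


def map_probe_to_antibody(probe: str, probe_map: ProbeAntibodyMap) -> str:
    """Resolve a probe to its antibody; unmapped probes raise :class:`NotFoundError`."""
    try:
        return probe_map.entries[probe]
    except KeyError:
        raise NotFoundError(f"probe {probe!r} has no antibody mapping") from None


@dataclass(frozen=True)
class HistologyDistribution:
    """Histology value -> number of cores; only histologies with >= 1 core appear."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def argmax(self) -> str | None:
        if not self.counts:
            return None
        return max(sorted(self.counts), key=lambda h: self.counts[h])

    def to_dict(self) -> dict[str, int]:
        return dict(sorted(self.counts.items()))


def histology_distribution(
    graph: TripleGraph,
    antibody: str,
    intensity_threshold: str,
    registry: AttributeRegistry,
    context: str = WILDCARD_CONTEXT,
    histology_attribute: str = DEFAULT_HISTOLOGY_ATTRIBUTE,
    rule: MappingRule | None = None,
) -> HistologyDistribution:
    """Histology counts among cores staining strictly above the threshold.

    The comparison "intensity > t" is expanded into the explicit set of
    permissible values above ``t`` in registry (ordinal) order; each histology
    count is a distinct-core count query.  An empty expansion (threshold at
    the top of the scale) yields an empty distribution.
    """
    rule = rule or default_mapping_rule()
    intensity_def = registry.lookup(antibody + INTENSITY_SUFFIX, context)
    if not intensity_def.is_ordinal:
        raise DomainError(
            f"intensity attribute of {antibody!r} is not ordinal; '>' is undefined"
        )
    above = intensity_def.values_above(intensity_threshold)
    histology_def = registry.lookup(histology_attribute, context)

    counts: dict[str, int] = {}
    for histology in histology_def.permissible_values:
        cores: set = set()
        for value in above:
            patterns = (
                TriplePattern(_SR,
                              rule.predicate_uri(link_predicate_name("StainingResult", "Core")),
                              _CR),
                TriplePattern(_SR, rule.predicate_uri("hasMarker"), Literal(antibody)),
                TriplePattern(_SR, rule.predicate_uri("hasIntensity"), Literal(value)),
                TriplePattern(_CR, rule.predicate_uri(link_predicate_name("Core", "Sample")),
                              _S),
                TriplePattern(_S, rule.predicate_uri(histology_attribute),
                              Literal(histology)),
            )
            cores |= {sol[0] for sol in evaluate_select(graph, patterns, [_CR])}
        if cores:
            counts[histology] = len(cores)
    return HistologyDistribution(counts)


def integrated_query(
    probe: str,
    probe_map: ProbeAntibodyMap,
    graph: TripleGraph,
    intensity_threshold: str,
    registry: AttributeRegistry,
    context: str = WILDCARD_CONTEXT,
    histology_attribute: str = DEFAULT_HISTOLOGY_ATTRIBUTE,
    rule: MappingRule | None = None,
) -> tuple[str, HistologyDistribution]:
    """Probe -> antibody -> histology distribution of strongly stained cores."""
    antibody = map_probe_to_antibody(probe, probe_map)
    distribution = histology_distribution(
        graph, antibody, intensity_threshold, registry,
        context=context, histology_attribute=histology_attribute, rule=rule,
    )
    return antibody, distribution
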