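"""Relational data model for tissue-microarray (TMA) experiments.

A TMA experiment stains a slide carrying many tissue cores with one antibody
and scores each core on a small ordinal scale (typically 0-3).  The model here
is a minimal relational schema sufficient for triadic hypothesis testing:

    Experiment(Id, Name, ExpType)
    Slide(Id, ExperimentId, BlockId, MarkerName)
    Block(Id)
    Core(Id, SlideId, SampleId)
    SampleAttribute(SampleId, AttributeName, Value)   key: (SampleId, AttributeName)
    StainingResult(CoreId, MarkerName, Intensity, Range)  key: (CoreId, MarkerName)

``Sample`` is an implicit entity: cores and sample attributes reference a
sample identifier, but samples have no table of their own.

Categorical attributes live in an :class:`AttributeRegistry` of context-
dependent *permissible value sets* — the controlled vocabulary against which
data are validated and from which complementary value sets are later derived.
Context-specific definitions (e.g. ``("HistologicGrade", "Colon cancer")``)
shadow wildcard ones (``("HistologicGrade", "*")``).

I/O is plain TSV, one file per table, header row = column names, empty cell =
missing value.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConflictError, AttributeLookupError, ParseError, ValidationError

WILDCARD_CONTEXT = "*"

#: Marker-intensity attributes follow the naming convention "<Marker> Intensity".
INTENSITY_SUFFIX = " Intensity"


# ---------------------------------------------------------------------------
# Attribute registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeDefinition:
    """A named categorical attribute with its permissible value list.

    Parameters
    ----------
    name:
        Attribute identifier, e.g. ``"HistologicGrade"`` or ``"Apaf-1 Intensity"``.
    context:
        The diagnosis context in which this definition applies, e.g.
        ``"Colon cancer"``, or ``"*"`` for the wildcard definition.
    permissible_values:
        Ordered, duplicate-free list of allowed categorical string values.
    is_ordinal:
        If true, the list order defines the total order used by threshold
        comparisons (e.g. staining intensity ``("0","1","2","3")``).
    """

    name: str
    context: str
    permissible_values: tuple[str, ...]
    is_ordinal: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("attribute name must be non-empty")
        if not self.permissible_values:
            raise ValidationError(
                f"attribute {self.name!r}: permissible value list must be non-empty"
            )
        if len(set(self.permissible_values)) != len(self.permissible_values):
            raise ValidationError(
                f"attribute {self.name!r}: permissible values contain duplicates"
            )
        object.__setattr__(self, "permissible_values", tuple(self.permissible_values))

    def values_above(self, threshold: str) -> tuple[str, ...]:
        """Permissible values strictly above ``threshold`` in registry order.

        Only defined for ordinal attributes; this is how ``intensity > t``
        comparisons are expanded into explicit value sets.
        """
        from .errors import DomainError

        if not self.is_ordinal:
            raise DomainError(f"attribute {self.name!r} is not ordinal")
        if threshold not in self.permissible_values:
            raise DomainError(
                f"threshold {threshold!r} not a permissible value of {self.name!r}"
            )
        idx = self.permissible_values.index(threshold)
        return self.permissible_values[idx + 1:]


class AttributeRegistry:
    """Context-dependent registry of :class:`AttributeDefinition`.

    Lookup prefers the exact ``(name, context)`` entry and falls back to the
    wildcard context ``"*"``.
    """

    def __init__(self) -> None:
        self._defs: dict[tuple[str, str], AttributeDefinition] = {}

    def register(
        self,
        name: str,
        context: str,
        values: Sequence[str],
        is_ordinal: bool = False,
    ) -> AttributeDefinition:
        key = (name, context)
        if key in self._defs:
            raise ConflictError(f"attribute {name!r} already registered for context {context!r}")
        definition = AttributeDefinition(name, context, tuple(values), is_ordinal)
        self._defs[key] = definition
        return definition

    def lookup(self, name: str, context: str = WILDCARD_CONTEXT) -> AttributeDefinition:
        """Return the definition for ``(name, context)``; wildcard as fallback."""
        try:
            return self._defs[(name, context)]
        except KeyError:
            pass
        try:
            return self._defs[(name, WILDCARD_CONTEXT)]
        except KeyError:
            raise AttributeLookupError(
                f"attribute {name!r} not registered for context {context!r} or wildcard"
            ) from None

    def get(self, name: str, context: str = WILDCARD_CONTEXT) -> AttributeDefinition | None:
        try:
            return self.lookup(name, context)
        except AttributeLookupError:
            return None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._defs

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        entries = [
            {
                "attribute": d.name,
                "context": d.context,
                "values": list(d.permissible_values),
                "ordinal": d.is_ordinal,
            }
            for d in sorted(self._defs.values(), key=lambda d: (d.name, d.context))
        ]
        return yaml.safe_dump(entries, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "AttributeRegistry":
        registry = cls()
        entries = yaml.safe_load(text) or []
        for entry in entries:
            registry.register(
                entry["attribute"],
                entry.get("context", WILDCARD_CONTEXT),
                entry["values"],
                bool(entry.get("ordinal", False)),
            )
        return registry

    @classmethod
    def from_file(cls, path: str | Path) -> "AttributeRegistry":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")


def register_attribute(
    registry: AttributeRegistry,
    name: str,
    context: str,
    values: Sequence[str],
    is_ordinal: bool = False,
) -> AttributeDefinition:
    """Register a permissible value set; thin wrapper over the registry."""
    return registry.register(name, context, values, is_ordinal)


# ---------------------------------------------------------------------------
# Schema and dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Schema of one table: ordered columns, key columns, foreign keys.

    ``foreign_keys`` maps a column name to the referenced entity name.  A
    referenced entity without a table of its own (``Sample``) is skipped by
    referential-integrity checks but still receives URIs in the RDF mapping.
    """

    name: str
    columns: tuple[str, ...]
    key: tuple[str, ...]
    foreign_keys: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in self.key:
            if k not in self.columns:
                raise ValidationError(f"table {self.name!r}: key column {k!r} not in columns")
        for c in self.foreign_keys:
            if c not in self.columns:
                raise ValidationError(f"table {self.name!r}: FK column {c!r} not in columns")

    def key_of(self, row: Mapping[str, str | None]) -> tuple[str, ...]:
        return tuple(row[c] or "" for c in self.key)


def default_schema() -> dict[str, TableSchema]:
    """The fixed minimal TMA schema used throughout the package."""
    return {
        "Experiment": TableSchema("Experiment", ("Id", "Name", "ExpType"), ("Id",)),
        "Slide": TableSchema(
            "Slide",
            ("Id", "ExperimentId", "BlockId", "MarkerName"),
            ("Id",),
            {"ExperimentId": "Experiment", "BlockId": "Block"},
        ),
        "Block": TableSchema("Block", ("Id",), ("Id",)),
        "Core": TableSchema(
            "Core",
            ("Id", "SlideId", "SampleId"),
            ("Id",),
            {"SlideId": "Slide", "SampleId": "Sample"},
        ),
        "SampleAttribute": TableSchema(
            "SampleAttribute",
            ("SampleId", "AttributeName", "Value"),
            ("SampleId", "AttributeName"),
            {"SampleId": "Sample"},
        ),
        "StainingResult": TableSchema(
            "StainingResult",
            ("CoreId", "MarkerName", "Intensity", "Range"),
            ("CoreId", "MarkerName"),
            {"CoreId": "Core"},
        ),
    }


Row = dict  # column name -> str | None (None = missing)


@dataclass
class Violation:
    """One validation finding, with coordinates into the dataset."""

    kind: str  # "referential" | "value" | "duplicate_key"
    table: str
    row_index: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.table}[{self.row_index}].{self.column}: {self.message}"


class TmaDataset:
    """In-memory relational TMA dataset: named tables of rows plus a schema.

    Rows are plain dicts mapping column name to a string value or ``None``
    (missing).  Equality ignores row order.
    """

    def __init__(self, schema: Mapping[str, TableSchema] | None = None):
        self.schema: dict[str, TableSchema] = dict(schema or default_schema())
        self.tables: dict[str, list[Row]] = {name: [] for name in self.schema}

    def add_row(self, table: str, **values: str | None) -> Row:
        if table not in self.schema:
            raise ValidationError(f"unknown table {table!r}")
        ts = self.schema[table]
        unknown = set(values) - set(ts.columns)
        if unknown:
            raise ValidationError(f"table {table!r}: unknown columns {sorted(unknown)}")
        row: Row = {c: values.get(c) for c in ts.columns}
        self.tables[table].append(row)
        return row

    def rows(self, table: str) -> list[Row]:
        return self.tables[table]

    def keys(self, table: str) -> set[tuple[str, ...]]:
        ts = self.schema[table]
        return {ts.key_of(r) for r in self.tables[table]}

    # -- equality ----------------------------------------------------------

    def _canonical(self):
        return {
            t: sorted((tuple(sorted(r.items())) for r in rows))
            for t, rows in self.tables.items()
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TmaDataset):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = ", ".join(f"{t}={len(r)}" for t, r in self.tables.items())
        return f"TmaDataset({sizes})"

    # -- convenience joins used by validation and the tabular oracle -------

    def sample_of_core(self, core_id: str) -> str | None:
        for r in self.tables["Core"]:
            if r["Id"] == core_id:
                return r["SampleId"]
        return None

    def sample_attribute(self, sample_id: str, attribute: str) -> str | None:
        for r in self.tables["SampleAttribute"]:
            if r["SampleId"] == sample_id and r["AttributeName"] == attribute:
                return r["Value"]
        return None

    def staining_intensity(self, core_id: str, marker: str) -> str | None:
        for r in self.tables["StainingResult"]:
            if r["CoreId"] == core_id and r["MarkerName"] == marker:
                return r["Intensity"]
        return None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(dataset: TmaDataset, registry: AttributeRegistry) -> list[Violation]:
    """Check referential integrity and permissible-value conformance.

    Returns a list of :class:`Violation`; an empty list means the dataset is
    valid.  Violations are data, not exceptions: downstream stages should only
    accept datasets with an empty report.

    Value checks are open-world: values of attributes with no registered
    definition (in the sample's diagnosis context or the wildcard) are not
    flagged.  The context for value lookup is the sample's ``Diagnosis``
    attribute where one exists.
    """
    violations: list[Violation] = []
    schema = dataset.schema

    # duplicate primary keys
    for tname, ts in schema.items():
        seen: set[tuple[str, ...]] = set()
        for i, row in enumerate(dataset.tables[tname]):
            k = ts.key_of(row)
            if k in seen:
                violations.append(
                    Violation("duplicate_key", tname, i, ts.key[0], f"duplicate key {k}")
                )
            seen.add(k)

    # referential integrity (targets without a table, e.g. Sample, are skipped)
    key_index = {tname: dataset.keys(tname) for tname in schema}
    for tname, ts in schema.items():
        for col, target in ts.foreign_keys.items():
            if target not in schema:
                continue
            target_keys = {k[0] for k in key_index[target]}
            for i, row in enumerate(dataset.tables[tname]):
                v = row.get(col)
                if v is not None and v not in target_keys:
                    violations.append(
                        Violation(
                            "referential", tname, i, col,
                            f"value {v!r} has no matching {target} row",
                        )
                    )

    # context per sample = its Diagnosis value, if present
    diagnosis: dict[str, str] = {}
    for row in dataset.tables["SampleAttribute"]:
        if row["AttributeName"] == "Diagnosis" and row["Value"] is not None:
            diagnosis[row["SampleId"]] = row["Value"]
    core_sample = {r["Id"]: r["SampleId"] for r in dataset.tables["Core"]}

    def check_value(table: str, i: int, column: str, attr: str, value: str | None, ctx: str):
        if value is None:
            return
        definition = registry.get(attr, ctx)
        if definition is not None and value not in definition.permissible_values:
            violations.append(
                Violation(
                    "value", table, i, column,
                    f"{value!r} not in permissible set of {attr!r} "
                    f"(context {definition.context!r})",
                )
            )

    for i, row in enumerate(dataset.tables["SampleAttribute"]):
        ctx = diagnosis.get(row["SampleId"], WILDCARD_CONTEXT)
        if row["AttributeName"] is not None:
            check_value("SampleAttribute", i, "Value", row["AttributeName"], row["Value"], ctx)

    for i, row in enumerate(dataset.tables["StainingResult"]):
        sample = core_sample.get(row["CoreId"])
        ctx = diagnosis.get(sample, WILDCARD_CONTEXT) if sample else WILDCARD_CONTEXT
        marker = row["MarkerName"]
        if marker:
            check_value("StainingResult", i, "Intensity",
                        marker + INTENSITY_SUFFIX, row["Intensity"], ctx)
            check_value("StainingResult", i, "Range",
                        marker + " Range", row["Range"], ctx)

    return violations


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_dataset(dataset: TmaDataset, directory: str | Path) -> list[Path]:
    """Write one ``<Table>.tsv`` per table; missing values become empty cells.

    Rows are emitted sorted by key so output bytes are deterministic.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for tname, ts in dataset.schema.items():
        path = directory / f"{tname}.tsv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(ts.columns)
            for row in sorted(dataset.tables[tname], key=ts.key_of):
                writer.writerow([row[c] if row[c] is not None else "" for c in ts.columns])
        written.append(path)
    return written


def read_dataset(
    directory: str | Path,
    schema: Mapping[str, TableSchema] | None = None,
) -> TmaDataset:
    """Read a dataset from a directory of ``<Table>.tsv`` files.

    Tables whose file is absent are left empty.  Raises :class:`ParseError`
    (with file and line) for malformed headers or duplicated primary keys.
    """
    directory = Path(directory)
    dataset = TmaDataset(schema)
    for tname, ts in dataset.schema.items():
        path = directory / f"{tname}.tsv"
        if not path.exists():
            continue
        _read_table(dataset, tname, ts, path)
    # reject stray TSV files that match no schema table
    for path in sorted(directory.glob("*.tsv")):
        if path.stem not in dataset.schema:
            raise ParseError(f"unknown table {path.stem!r}", str(path))
    return dataset


def _read_table(dataset: TmaDataset, tname: str, ts: TableSchema, path: Path) -> None:
    seen: set[tuple[str, ...]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file: missing header row", str(path), 1) from None
        if tuple(header) != ts.columns:
            raise ParseError(
                f"malformed header {header!r}; expected {list(ts.columns)}", str(path), 1
            )
        for lineno, cells in enumerate(reader, start=2):
            if len(cells) != len(ts.columns):
                raise ParseError(
                    f"expected {len(ts.columns)} cells, got {len(cells)}", str(path), lineno
                )
            row = {
                c: (cell.strip() if cell.strip() != "" else None)
                for c, cell in zip(ts.columns, cells)
            }
            k = ts.key_of(row)
            if k in seen:
                raise ParseError(f"duplicate primary key {k}", str(path), lineno)
            seen.add(k)
            dataset.tables[tname].append(row)


def dataset_to_tsv_bytes(dataset: TmaDataset) -> bytes:
    """Concatenated TSV serialization of all tables; used for byte-determinism checks."""
    out = io.StringIO()
    for tname, ts in sorted(dataset.schema.items()):
        out.write(f"# {tname}\n")
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(ts.columns)
        for row in sorted(dataset.tables[tname], key=ts.key_of):
            writer.writerow([row[c] if row[c] is not None else "" for c in ts.columns])
    return out.getvalue().encode("utf-8")
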