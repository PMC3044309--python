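# tmarq

Semantic hypothesis testing over tissue-microarray (TMA) databases.

A TMA experiment stains a slide carrying dozens of tissue cores with one
antibody and scores each core on a small ordinal scale (0–3). Most hypotheses
such experiments can decide are *triadic*: "in biological condition *A*,
entity *B* correlates (positively or negatively) with entity *C*" — for
example, *reduced Apaf-1 expression in colon cancer correlates with
high-grade phenotype*. `tmarq` turns that sentence into a statistical
decision automatically:

1. **Data model** — relational TMA tables (Experiment / Slide / Block / Core /
   SampleAttribute / StainingResult) with a registry of context-dependent
   *permissible value sets* for every categorical attribute, read and written
   as plain TSV.
2. **RDF mapping** — a declarative rule maps every row to triples (subject URI
   minted from the primary key; foreign keys become object-URI links), stored
   in an indexed in-memory triple graph.
3. **Hypothesis compilation** — the triad (shared property *A*; classifier
   *B* = attribute + hypothesis-describing value set; dependent property *C*)
   is completed by *complement reasoning*: the complementary value set is the
   rest of the attribute's permissible set, e.g. intensity {0} ⇒ {1, 2, 3},
   grade {High} ⇒ {Low, Intermediate}. Four conjunctive count queries are
   generated — one per cell of {hypothesis, complement} × {hypothesis,
   complement} — each counting `count(distinct ?cr)` over the core → slide →
   experiment / core → sample / core → staining-result graph pattern.
4. **Statistics** — the four counts form a 2×2 contingency table
   (n₁₁, n₁₂ / n₂₁, n₂₂). Fisher's exact test (hypergeometric null with fixed
   margins; two-sided p = Σ P(T) over all tables no more probable than the
   observed one) decides the hypothesis: *supported* iff p < α (default 0.01).
   A χ² test with optional Yates correction is included.
5. **Integration** — DNA-microarray probes map to TMA antibodies through a
   probe→antibody table, enabling cross-platform queries such as "the
   histology distribution of cores where the antibody for probe `201983_s_at`
   stains with intensity > 1".
6. **Synthetic cohorts** — a generator draws cores from the unique 2×2 joint
   distribution with prescribed marginals and odds ratio, so calibration
   (type-I error, power) is testable end to end; deterministic fixtures
   reproduce the packaged worked example.

## Worked example

```sh
tmarq synth data/worked --fixture worked-example
cat > apaf1.yaml <<EOF
shared: {attribute: Diagnosis, value: Colon cancer}
classifier: {attribute: Apaf-1 Intensity, values: ['0']}
dependent: {attribute: HistologicGrade, values: [High-grade]}
alpha: 0.01
EOF
tmarq test-hypothesis data/worked apaf1.yaml
```

prints

```json
{
  "decision": "supported",
  "p_value": 5.098046693481034e-06,
  "table": {"n11": 26, "n12": 4, "n21": 6, "n22": 19},
  "provenance": {"cores": 55, "slides": 5, "experiments": 3},
  ...
}
```

Reading: of the 55 colon-cancer cores (on 5 slides from 3 experiments) with
both an Apaf-1 score and a grade, 26 are Apaf-1-negative *and* high-grade
versus only 4 Apaf-1-positive high-grade cores (odds ratio ≈ 20.6); the
two-sided Fisher p ≈ 5.1 × 10⁻⁶ < 0.01, so the database supports the
hypothesis.

The same pipeline is available as a library:

```python
from tmarq import (build_hypothesis_model, dataset_to_graph,
                   default_registry, make_worked_example_fixture, test_hypothesis)

registry = default_registry()
graph = dataset_to_graph(make_worked_example_fixture())
model = build_hypothesis_model(("Diagnosis", "Colon cancer"),
                               "Apaf-1 Intensity", ["0"],
                               "HistologicGrade", ["High-grade"], registry)
result = test_hypothesis(model, graph)   # result.table.cells() == (26, 4, 6, 19)
```

Other subcommands: `tmarq validate` (referential integrity + vocabulary
conformance), `tmarq export-rdf` (deterministic N-Triples or Turtle),
`tmarq integrate` (probe → antibody → histology distribution),
`tmarq synth` (seeded synthetic cohorts).

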