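# Methods

## The triadic hypothesis model

TMA-decidable hypotheses are modeled as a triad:

* **Shared property (factor 1)** — an attribute/value pair all counted samples
  must carry, matched as a sample attribute (`Diagnosis = "Colon cancer"`).
* **Classifier (factor 2)** — an attribute plus a *hypothesis-describing*
  value set; cores whose value falls in it form Core Collection A, the rest
  Core Collection B.
* **Dependent property (factor 3)** — a second attribute/value-set pair whose
  within-collection value distributions (D1 vs D2) carry the evidence.

Complementary value sets are inferred, never user-stated: every categorical
attribute has a context-dependent *permissible value set* registered up
front, and the complement is the permissible set minus the hypothesis values
(order preserved). The two sets therefore always partition the vocabulary;
an empty hypothesis set, or one covering the whole vocabulary, is rejected as
degenerate. Binarizing a multi-level attribute (3-level grade → High vs
rest) *is* this partition — there is no separate "drop the middle level"
mode.

Four count queries are generated per hypothesis, indexed i = 1..4. Factor 1
always contributes its constant; the classifier takes its hypothesis set for
i ∈ {1, 3} and its complement for i ∈ {2, 4}; the dependent factor takes its
hypothesis set for i ∈ {1, 2} and its complement for i ∈ {3, 4}. Counts are
of **distinct cores** (`count(distinct ?cr)`): a sample contributing several
cores contributes each of them. Cell orientation is n11 ← plan 1,
n12 ← plan 2, n21 ← plan 3, n22 ← plan 4, i.e. columns split on the
classifier, rows on the dependent factor; the two-sided Fisher p-value is
invariant to this layout choice.

Cores missing either the classifier or the dependent value are excluded from
all four counts (complete-case analysis). Value-set membership is compiled
as a disjunction — one conjunctive query per member value (and per value pair
across the two factors), with distinct cores unioned before counting — so the
query language needs no FILTER/IN constructs.

## Query evaluation

Relational rows map to RDF by a declarative rule: the subject URI is
`<base>/<entity>/<pk>`, predicates are `<base>/vocab#<name>` taken verbatim
from the rule (no automatic `has` prefixing — the vocabulary itself mixes
`hasName` with `ExpType`), foreign keys become object-URI triples, and the
entity–attribute–value table (`SampleAttribute`) is pivoted so attribute
names become predicates on the sample node. The store is a native in-memory
triple set with subject, predicate and (predicate, object) indexes; a
mediator over a live SQL backend would answer identically and is not needed
here.

Basic graph patterns are evaluated by greedy most-bound-first join; only the
solution *set* is contractual, and the evaluator is property-tested against
a brute-force enumerator over all term assignments. Ordinal threshold
queries ("intensity > 1") expand the threshold into the explicit set of
permissible values above it, in registry order — ordinal semantics live in
the vocabulary, never in lexical literal comparison.

A tabular twin (`contingency_from_dataset`) computes the same table by
direct relational filtering. The two routes are cross-checked cell-by-cell
on seeded random datasets; the tabular route is used for large simulation
runs where materializing thousands of graphs would be pointless.

## Fisher's exact test

Under independence with both margins fixed, the top-left cell is
hypergeometric. The two-sided p-value follows the probability-mass rule
(the default of R's `fisher.test`): sum P(T) over all tables with the
observed margins whose probability does not exceed the observed table's,
with a 1e-7 relative tolerance absorbing floating-point ties. Probabilities
are computed through log-factorials; exact rational arithmetic is not needed
for correctness at realistic table sizes, and the implementation is verified
against an exact-rational enumeration oracle (and spot-checked against
scipy) in the tests. One-sided tails are exposed as an option; the default
is two-sided because the direction slot of the hypothesis is treated as
descriptive metadata, not as a licence for a one-tailed test. The default
significance threshold is α = 0.01, configurable per hypothesis.

The χ² companion uses the textbook statistic with 1 df; Yates' continuity
correction (|O−E|−0.5, floored at 0) is off by default. No multiple-testing
control is applied across hypotheses — each submitted hypothesis is tested
in isolation, which users should keep in mind when screening many.

## Synthetic cohorts

The generator emulates a multi-experiment TMA study: experiments × slides ×
cores-per-slide, one block and one antibody per slide, one sample per core,
cores assigned to slides round-robin. Per core, the joint (classifier ∈
hypothesis, dependent ∈ hypothesis) cell is drawn from the unique 2×2
distribution with prescribed marginals (p_B, p_C) and odds ratio ψ (p11
solves the quadratic ψ = p11·p00/(p10·p01)); the concrete categorical value
is then drawn uniformly within the chosen side of the partition. Missing
values are injected independently per factor at a configurable rate.
Identical seeds yield byte-identical TSV output.

Defaults mirror the packaged worked example's observed regime: p_B = 0.58,
p_C = 0.55 (the marginals 32/55 and 30/55 of its table), ψ = 20
(26·19/(4·6) ≈ 20.6), three experiments of two slides. The deterministic
worked-example fixture places 55 colon-cancer cores on 5 slides across 3
experiments so the Apaf-1/grade table is exactly (26, 4, 6, 19); non-zero
intensities cycle 1, 2, 3. Its grade values are High/Low only — how
intermediate-grade cores would have entered that printed table is not
determinable, so the fixture uses the minimal assignment that reproduces it.
The glioma fixture gives EGFR strong staining predominantly in glioblastoma
cores ((total, above-1) per histology: 12/10, 8/2, 6/1, 4/0).

What the generator does *not* model: slide- or experiment-level random
effects (the exact test pools cores, ignoring clustering, and the generator
mirrors that — a real cohort with correlated cores would have an inflated
type-I error that these simulations cannot reveal), image-derived intensity
noise, inter-observer scoring variability, and expression values on the
array side of the integration (the probe→antibody map is taken as input, and
the cross-platform query touches only TMA staining data).

## Numerical and design choices

* **Problem sizes.** Calibration runs use 1000 replicates of 200 cores for
  type-I error (expected 0.05 ± 0.02), 1000 replicates of the 55-core design
  at ψ = 20 for power (observed ≈ 0.99 at α = 0.01 — consistent with the
  worked example's p < 10⁻⁴ outcome), and 5000-core cohorts for odds-ratio
  recovery, where the empirical Haldane-corrected OR falls within ±20% of the
  target in ≥ 95% of seeds. Unit tests run reduced replicate counts of the
  same designs; the acceptance script runs them in full.
* **Determinism.** All randomness flows through a single integer seed per
  dataset (`numpy.random.default_rng`); TSV emission and N-Triples export
  sort rows/lines so repeated runs are byte-identical.
* **Staining vs sample attributes.** A factor whose attribute is named
  `"<Marker> Intensity"` compiles to staining-result patterns; any other
  attribute compiles to a sample-attribute pattern. Positive/negative
  expression classifiers are therefore modeled as sample attributes in the
  synthetic cohorts.
* **Degenerate inputs.** All-zero tables, zero margins (χ²), infeasible
  marginal/odds-ratio combinations, hypothesis sets that are not proper
  subsets, and thresholds at the top of an ordinal scale all raise typed
  errors (or, for the last case, return an empty distribution).
* **Value comparison.** Controlled-vocabulary strings are compared
  case-sensitively after whitespace trimming at parse time.
* **Staining `Range`** is carried by the data model and the RDF mapping but
  participates in no shipped hypothesis — it mirrors the shape of real TMA
  staining records.

## Known limitations

Compound hypotheses (logical combinations of triads), survival endpoints,
continuous marker values, r×c exact tests and mid-p variants are out of
scope. Passing calibration on these synthetic cohorts shows the machinery is
correct under the stated sampling model; it does not validate the
complete-case assumption or the pooling of clustered cores on real data.
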