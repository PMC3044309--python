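"""Synthetic TMA datasets with a controlled marker-phenotype association.

Every stage of the pipeline is testable without external downloads: this
module generates multi-experiment TMA datasets whose binarized classifier and
dependent factors follow the unique 2x2 joint distribution with prescribed
marginals and odds ratio, plus two deterministic fixtures — the worked
colon-cancer example whose Apaf-1/grade table is exactly (26, 4, 6, 19) over
55 cores / 5 slides / 3 experiments, and a glioma dataset for the
probe-to-antibody integration query.

Default generator parameters mirror the worked example's observed regime:
classifier marginal 0.58 (32/55 cores with Apaf-1 intensity 0), dependent
marginal 0.55 (30/55 high-grade), odds ratio 20 (26*19 / (4*6) ~ 20.6), and
three experiments of two slides each.  Slide and experiment membership is
assigned round-robin over cores; there are no slide-level random effects —
the exact test pools cores, and the generator mirrors that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError
from .integration import ProbeAntibodyMap
from .tma_model import (
    INTENSITY_SUFFIX,
    AttributeRegistry,
    TmaDataset,
)


# ---------------------------------------------------------------------------
# Registry of the controlled vocabularies used by the synthetic cohorts
# ---------------------------------------------------------------------------

def default_registry() -> AttributeRegistry:
    """Permissible value sets for the attributes the synthetic cohorts use."""
    registry = AttributeRegistry()
    registry.register("Diagnosis", "*",
                      ("Colon cancer", "Stomach cancer", "Glioma"))
    registry.register("HistologicGrade", "*",
                      ("Low-grade", "Intermediate-grade", "High-grade"), is_ordinal=True)
    registry.register("HistologicGrade", "Colon cancer",
                      ("Low-grade", "Intermediate-grade", "High-grade"), is_ordinal=True)
    registry.register("NodalStatus", "*", ("N0", "N1", "N2", "N3"), is_ordinal=True)
    registry.register("Leptin", "*", ("negative", "positive"))
    registry.register("HDAC2 expression", "*", ("negative", "positive"))
    registry.register("Histology", "*",
                      ("Glioblastoma", "Astrocytoma", "Oligodendroglioma", "Meningioma"))
    for marker in ("Apaf-1", "EGFR"):
        registry.register(marker + INTENSITY_SUFFIX, "*",
                          ("0", "1", "2", "3"), is_ordinal=True)
    return registry


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorConfig:
    """One binarized factor: attribute, hypothesis-describing values, marginal
    probability of a core falling in the hypothesis side."""

    attribute: str
    hypothesis_values: tuple[str, ...]
    marginal: float

    def __post_init__(self) -> None:
        if not (0.0 < self.marginal < 1.0):
            raise ValidationError(f"marginal probability must be in (0,1), got {self.marginal}")
        if not self.hypothesis_values:
            raise ValidationError(f"factor {self.attribute!r}: empty hypothesis value set")


@dataclass(frozen=True)
class SyntheticConfig:
    n_experiments: int = 3
    slides_per_experiment: int = 2
    cores_per_slide: int = 10
    shared_attribute: str = "Diagnosis"
    shared_value: str = "Colon cancer"
    classifier: FactorConfig = field(
        default_factory=lambda: FactorConfig("Apaf-1 Intensity", ("0",), 0.58))
    dependent: FactorConfig = field(
        default_factory=lambda: FactorConfig("HistologicGrade", ("High-grade",), 0.55))
    odds_ratio: float = 20.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("n_experiments", self.n_experiments),
                            ("slides_per_experiment", self.slides_per_experiment),
                            ("cores_per_slide", self.cores_per_slide)):
            if value < 1:
                raise ValidationError(f"{name} must be >= 1, got {value}")
        if not (self.odds_ratio > 0.0) or not math.isfinite(self.odds_ratio):
            raise ValidationError(f"odds ratio must be positive and finite, got {self.odds_ratio}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError(f"missing_rate must be in [0,1), got {self.missing_rate}")

    @property
    def n_cores(self) -> int:
        return self.n_experiments * self.slides_per_experiment * self.cores_per_slide


def joint_cell_probabilities(p_b: float, p_c: float, odds_ratio: float
                             ) -> tuple[float, float, float, float]:
    """The unique 2x2 joint distribution with the given marginals and odds ratio.

    Returns ``(p11, p10, p01, p00)`` where ``p11 = P(B=hyp, C=hyp)``; ``p11``
    solves the quadratic ``psi = p11*p00 / (p10*p01)``.  Infeasible
    combinations raise :class:`DomainError`.
    """
    if not (0.0 < p_b < 1.0 and 0.0 < p_c < 1.0):
        raise DomainError("marginals must be in (0,1)")
    psi = odds_ratio
    if psi <= 0 or not math.isfinite(psi):
        raise DomainError(f"odds ratio must be positive and finite, got {psi}")
    if psi == 1.0:
        p11 = p_b * p_c
    else:
        s = 1.0 + (p_b + p_c) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * p_b * p_c
        if disc < 0:
            raise DomainError("no joint distribution with these marginals and odds ratio")
        p11 = (s - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    cells = (p11, p_b - p11, p_c - p11, 1.0 - p_b - p_c + p11)
    if any(p < -1e-12 for p in cells):
        raise DomainError("marginals and odds ratio admit no valid joint distribution")
    return tuple(max(p, 0.0) for p in cells)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Dataset assembly helpers
# ---------------------------------------------------------------------------

def _scaffold(dataset: TmaDataset, n_experiments: int, slides_per_experiment: int,
              marker: str | None, exp_prefix: str = "E") -> list[str]:
    """Create experiments, blocks, slides; return slide ids in order."""
    slide_ids: list[str] = []
    s = 0
    for e in range(1, n_experiments + 1):
        exp_id = f"{exp_prefix}{e}"
        dataset.add_row("Experiment", Id=exp_id, Name=f"synthTMA{e}", ExpType="TMA")
        for _ in range(slides_per_experiment):
            s += 1
            block_id = f"B{s:03d}"
            slide_id = f"SL{s:03d}"
            dataset.add_row("Block", Id=block_id)
            dataset.add_row("Slide", Id=slide_id, ExperimentId=exp_id,
                            BlockId=block_id, MarkerName=marker)
            slide_ids.append(slide_id)
    return slide_ids


def _emit_core(dataset: TmaDataset, index: int, slide_id: str, shared_attribute: str,
               shared_value: str, assignments: list[tuple[str, str | None]]) -> None:
    """Add one core, its sample, and its attribute/staining rows.

    ``assignments`` pairs attribute names with values (None = missing, row
    omitted); "<Marker> Intensity" attributes become StainingResult rows.
    """
    core_id = f"C{index:05d}"
    sample_id = f"S{index:05d}"
    dataset.add_row("Core", Id=core_id, SlideId=slide_id, SampleId=sample_id)
    dataset.add_row("SampleAttribute", SampleId=sample_id,
                    AttributeName=shared_attribute, Value=shared_value)
    for attribute, value in assignments:
        if value is None:
            continue
        if attribute.endswith(INTENSITY_SUFFIX):
            marker = attribute[: -len(INTENSITY_SUFFIX)]
            dataset.add_row("StainingResult", CoreId=core_id, MarkerName=marker,
                            Intensity=value, Range=None)
        else:
            dataset.add_row("SampleAttribute", SampleId=sample_id,
                            AttributeName=attribute, Value=value)


# ---------------------------------------------------------------------------
# Random generator
# ---------------------------------------------------------------------------

def generate_tma_dataset(
    config: SyntheticConfig,
    registry: AttributeRegistry | None = None,
) -> TmaDataset:
    """Generate a dataset with the configured marker-phenotype association.

    Per core, the joint (classifier-in-hypothesis, dependent-in-hypothesis)
    cell is drawn from :func:`joint_cell_probabilities`; the concrete
    categorical value is then drawn uniformly within the chosen side of the
    partition.  Missing values are injected independently per factor at
    ``missing_rate``.  Identical seeds produce identical datasets.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    cells = joint_cell_probabilities(
        config.classifier.marginal, config.dependent.marginal, config.odds_ratio)

    def sides(factor: FactorConfig) -> tuple[tuple[str, ...], tuple[str, ...]]:
        definition = registry.lookup(factor.attribute, config.shared_value)
        hyp = tuple(factor.hypothesis_values)
        missing = set(hyp) - set(definition.permissible_values)
        if missing:
            raise DomainError(
                f"hypothesis values {sorted(missing)} not permissible for "
                f"{factor.attribute!r}")
        comp = tuple(v for v in definition.permissible_values if v not in hyp)
        if not comp:
            raise DomainError(f"factor {factor.attribute!r}: hypothesis set covers "
                              "the whole permissible set")
        return hyp, comp

    cls_sides = sides(config.classifier)
    dep_sides = sides(config.dependent)

    classifier_marker = (config.classifier.attribute[: -len(INTENSITY_SUFFIX)]
                         if config.classifier.attribute.endswith(INTENSITY_SUFFIX) else None)

    dataset = TmaDataset()
    slide_ids = _scaffold(dataset, config.n_experiments, config.slides_per_experiment,
                          classifier_marker)

    cum = np.cumsum(cells)
    for i in range(config.n_cores):
        u = rng.random()
        cell = int(np.searchsorted(cum, u, side="right"))
        cell = min(cell, 3)
        b_hyp = cell in (0, 1)
        c_hyp = cell in (0, 2)
        cls_pool = cls_sides[0] if b_hyp else cls_sides[1]
        dep_pool = dep_sides[0] if c_hyp else dep_sides[1]
        cls_value: str | None = cls_pool[int(rng.integers(len(cls_pool)))]
        dep_value: str | None = dep_pool[int(rng.integers(len(dep_pool)))]
        if config.missing_rate > 0.0:
            if rng.random() < config.missing_rate:
                cls_value = None
            if rng.random() < config.missing_rate:
                dep_value = None
        _emit_core(
            dataset, i + 1, slide_ids[i % len(slide_ids)],
            config.shared_attribute, config.shared_value,
            [(config.classifier.attribute, cls_value),
             (config.dependent.attribute, dep_value)],
        )
    return dataset


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

def make_worked_example_fixture() -> TmaDataset:
    """The colon-cancer Apaf-1/grade cohort: 55 cores, 5 slides, 3 experiments.

    The Apaf-1 intensity / histologic grade 2x2 table is exactly
    (26, 4, 6, 19): 26 cores with intensity 0 and high grade, 4 with
    intensity 1-3 and high grade, 6 with intensity 0 and low grade, 19 with
    intensity 1-3 and low grade.  Non-zero intensities cycle deterministically
    through 1, 2, 3.
    """
    cycle = ("1", "2", "3")
    cells: list[tuple[str, str]] = []
    cells += [("0", "High-grade")] * 26
    cells += [(cycle[k % 3], "High-grade") for k in range(4)]
    cells += [("0", "Low-grade")] * 6
    cells += [(cycle[k % 3], "Low-grade") for k in range(19)]
    assert len(cells) == 55

    dataset = TmaDataset()
    # 3 experiments; slides 2 + 2 + 1 = 5
    slide_ids: list[str] = []
    for e, n_slides in enumerate((2, 2, 1), start=1):
        exp_id = f"E{e}"
        dataset.add_row("Experiment", Id=exp_id, Name=f"colonTMA{e}", ExpType="TMA")
        for _ in range(n_slides):
            s = len(slide_ids) + 1
            dataset.add_row("Block", Id=f"B{s:03d}")
            dataset.add_row("Slide", Id=f"SL{s:03d}", ExperimentId=exp_id,
                            BlockId=f"B{s:03d}", MarkerName="Apaf-1")
            slide_ids.append(f"SL{s:03d}")

    for i, (intensity, grade) in enumerate(cells, start=1):
        _emit_core(
            dataset, i, slide_ids[(i - 1) % len(slide_ids)],
            "Diagnosis", "Colon cancer",
            [("Apaf-1 Intensity", intensity), ("HistologicGrade", grade)],
        )
    return dataset


def make_glioma_fixture() -> TmaDataset:
    """A glioma cohort for the integration use case.

    EGFR stains strongly (intensity > 1) predominantly in glioblastoma cores:
    per histology, (cores, cores above intensity 1) are Glioblastoma (12, 10),
    Astrocytoma (8, 2), Oligodendroglioma (6, 1), Meningioma (4, 0).
    """
    plan = (
        ("Glioblastoma", 12, 10),
        ("Astrocytoma", 8, 2),
        ("Oligodendroglioma", 6, 1),
        ("Meningioma", 4, 0),
    )
    dataset = TmaDataset()
    slide_ids = _scaffold(dataset, 1, 2, "EGFR", exp_prefix="G")
    high_cycle = ("2", "3")
    low_cycle = ("0", "1")
    i = 0
    for histology, n_total, n_high in plan:
        for k in range(n_total):
            i += 1
            intensity = high_cycle[k % 2] if k < n_high else low_cycle[k % 2]
            _emit_core(
                dataset, i, slide_ids[(i - 1) % len(slide_ids)],
                "Diagnosis", "Glioma",
                [("EGFR Intensity", intensity), ("Histology", histology)],
            )
    return dataset


def demo_probe_map() -> ProbeAntibodyMap:
    """Probe-to-antibody entries for the integration demo."""
    return ProbeAntibodyMap.from_pairs([
        ("201983_s_at", "EGFR"),
        ("204689_at", "HDAC2"),
        ("207092_at", "Leptin"),
    ])
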