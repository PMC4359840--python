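"""Synthetic decision tables and AD-like screening cohorts.

Two generators stand in for the (undeposited) 500-case hospital dataset:

* **Planted-reduct tables** for validating the reduction machinery: a set of
  *relevant* attributes drawn uniformly whose tuple deterministically fixes
  the decision (so the planted set has dependency degree 1 by construction),
  optional *redundant* attributes that are value-permuted copies of relevant
  columns (interchangeable in any reduct), and *irrelevant* attributes drawn
  independently of the decision.

* **Cohorts** emulating the study population: ~500 subjects in three
  diagnostic classes (Normal / MCI / AD), ~34 grouped ordinal items from 11
  named scale families, class-dependent score distributions.  Discriminative
  items use a binomial location-shift family whose success probability
  decreases Normal -> MCI -> AD, respecting the bounded ordinal supports;
  a contamination rate replaces scores with uniform noise.  A ``separable``
  mode draws discriminative scores from disjoint per-class bands, giving a
  cohort the classifier can resolve perfectly — useful for pipeline sanity
  checks, not realism.  Items are conditionally independent given the class
  (matching the naive network's assumption), which real scale batteries are
  not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .table import DecisionTable

__all__ = [
    "SynthError",
    "PlantedTableSpec",
    "CohortSpec",
    "generate_planted_table",
    "generate_cohort",
    "SCALE_FAMILIES",
]


class SynthError(ValueError):
    pass


SCALE_FAMILIES = (
    "MMSE",
    "MoCA",
    "CDR",
    "GDS",
    "ADL",
    "WordList",
    "FigureCopy",
    "NewWordDiscrimination",
    "TrailMaking",
    "Similarity",
    "Perception",
)


@dataclass
class PlantedTableSpec:
    """Defaults plant 5 relevant binary attributes among 10 irrelevant ones
    at 300 objects.  Binary value supports keep the joint cardinality of any
    small attribute subset far below the object count, so irrelevant
    attributes cannot spuriously discern the sample and the planted set is
    genuinely the minimal reduct."""

    n_objects: int = 300
    relevant: int = 5
    redundant: int = 0
    irrelevant: int = 10
    n_classes: int = 3
    value_cardinality: int = 2
    seed: int | None = None

    def validate(self) -> None:
        if self.relevant < 1:
            raise SynthError("need at least one relevant attribute")
        if self.value_cardinality < 2:
            raise SynthError("value_cardinality must be >= 2")
        if self.value_cardinality**self.relevant < self.n_classes:
            raise SynthError("too few relevant value combinations for the classes")
        if self.relevant * (self.value_cardinality - 1) + 1 < self.n_classes:
            raise SynthError("decision function cannot reach every class")
        if min(self.n_objects, self.n_classes) < 1 or self.redundant < 0 or self.irrelevant < 0:
            raise SynthError("counts must be non-negative (objects/classes >= 1)")


def generate_planted_table(
    spec: PlantedTableSpec,
) -> tuple[DecisionTable, dict]:
    """Decision table with a known planted attribute set of dependency 1.

    The decision is the sum of the relevant value codes modulo the number of
    classes (for two binary relevant attributes this is exactly XOR), so it
    depends on every relevant attribute and is surjective onto the classes.
    Returns the table and a ground-truth dict (planted set, redundant map,
    spec echo).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, v = spec.n_objects, spec.value_cardinality
    rel = rng.integers(0, v, size=(n, spec.relevant))
    decision = rel.sum(axis=1) % spec.n_classes
    columns: dict[str, np.ndarray] = {}
    rel_names = [f"rel{j}" for j in range(spec.relevant)]
    for j, name in enumerate(rel_names):
        columns[name] = rel[:, j]
    redundant_map: dict[str, str] = {}
    for j in range(spec.redundant):
        src = int(rng.integers(0, spec.relevant))
        perm = rng.permutation(v)
        name = f"dup{j}"
        columns[name] = perm[rel[:, src]]
        redundant_map[name] = rel_names[src]
    for j in range(spec.irrelevant):
        columns[f"irr{j}"] = rng.integers(0, v, size=n)
    frame = pd.DataFrame({k: col.astype(str) for k, col in columns.items()})
    frame["Result"] = np.asarray([f"d{c}" for c in decision])
    table = DecisionTable(frame, "Result")
    truth = {
        "planted": tuple(rel_names),
        "redundant_map": redundant_map,
        "irrelevant": tuple(f"irr{j}" for j in range(spec.irrelevant)),
        "n_classes": spec.n_classes,
        "value_cardinality": v,
        "seed": spec.seed,
    }
    return table, truth


@dataclass
class CohortSpec:
    """Statistical description of the emulated screening cohort.

    ``class_probs`` is ordered (Normal, MCI, AD); the default reproduces the
    reported mix of 28.8% normal cognition, 37.7% MCI and 33.5% AD.  The 34
    default items are the grouped granularity the reduction operates on (the
    raw batteries hold 101 items; set ``n_items=101`` for that view).
    """

    n_subjects: int = 500
    class_probs: tuple[float, float, float] = (0.288, 0.377, 0.335)
    n_items: int = 34
    item_max_scores: Sequence[int] | None = None
    n_discriminative: int = 10
    effect: float = 0.25
    effect_profile: Sequence[float] | None = None
    noise: float = 0.05
    separable: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_items < 1:
            raise SynthError("need at least one subject and one item")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise SynthError("class probabilities must sum to 1")
        if not 0 <= self.n_discriminative <= self.n_items:
            raise SynthError("n_discriminative outside [0, n_items]")
        if not 0.0 <= self.noise <= 1.0:
            raise SynthError("noise must be in [0, 1]")
        if self.item_max_scores is not None and len(self.item_max_scores) != self.n_items:
            raise SynthError("item_max_scores length mismatch")
        if self.effect_profile is not None and len(self.effect_profile) != self.n_items:
            raise SynthError("effect_profile length mismatch")


_CLASSES = ("Normal", "MCI", "AD")
_NONDISC_MAXES = (5, 3, 2, 1)  # mixed ordinal ranges for background items


def _default_item_names(n_items: int) -> list[str]:
    names = []
    for i in range(n_items):
        scale = SCALE_FAMILIES[i % len(SCALE_FAMILIES)]
        names.append(f"{scale}_item{i // len(SCALE_FAMILIES) + 1}")
    return names


def generate_cohort(spec: CohortSpec) -> tuple[DecisionTable, dict]:
    """Draw a synthetic screening cohort; returns (table, ground_truth).

    Class labels come from ``class_probs``; the first ``n_discriminative``
    items carry the class signal.  Scores are binomial with class-dependent
    success probability (higher = better cognition, so means are ordered
    Normal >= MCI >= AD), truncated to each item's ordinal support; with
    ``separable`` the discriminative items instead use disjoint per-class
    score bands.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    stage = rng.choice(3, size=n, p=list(spec.class_probs))  # 0=Normal 1=MCI 2=AD
    labels = np.asarray(_CLASSES, dtype=object)[stage]

    if spec.effect_profile is not None:
        effects = np.asarray(spec.effect_profile, dtype=float)
    else:
        effects = np.zeros(spec.n_items)
        effects[: spec.n_discriminative] = spec.effect
    if spec.item_max_scores is not None:
        maxes = np.asarray(spec.item_max_scores, dtype=int)
    else:
        maxes = np.asarray(
            [
                5 if effects[i] > 0 else _NONDISC_MAXES[i % len(_NONDISC_MAXES)]
                for i in range(spec.n_items)
            ]
        )
    if spec.separable and (maxes[effects > 0] < 2).any():
        raise SynthError("separable mode needs max score >= 2 on signal items")

    names = _default_item_names(spec.n_items)
    data: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        m = int(maxes[i])
        if effects[i] > 0:
            if spec.separable:
                # disjoint bands: AD low, MCI middle, Normal high
                lo = np.asarray([2 * (m + 1) // 3, (m + 1) // 3, 0])[stage]
                hi = np.asarray([m + 1, 2 * (m + 1) // 3, (m + 1) // 3])[stage]
                scores = lo + rng.integers(0, np.maximum(hi - lo, 1))
            else:
                p = np.clip(0.85 - effects[i] * stage, 0.05, 0.95)
                scores = rng.binomial(m, p)
        else:
            scores = rng.binomial(m, 0.6, size=n)
        if spec.noise > 0:
            contaminate = rng.random(n) < spec.noise
            scores = np.where(contaminate, rng.integers(0, m + 1, size=n), scores)
        data[name] = scores.astype(int)

    frame = pd.DataFrame({k: v.astype(str) for k, v in data.items()})
    frame["Result"] = labels
    table = DecisionTable(frame, "Result")
    truth = {
        "discriminative": tuple(names[i] for i in range(spec.n_items) if effects[i] > 0),
        "item_max_scores": [int(m) for m in maxes],
        "effects": [float(e) for e in effects],
        "class_probs": {c: p for c, p in zip(_CLASSES, spec.class_probs)},
        "separable": spec.separable,
        "noise": spec.noise,
        "seed": spec.seed,
    }
    return table, truth
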