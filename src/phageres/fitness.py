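"""Relative fitness from maximum growth rates, and cost additivity.

Fitness of a resistant mutant is its maximum growth rate divided by the
mean ancestral maximum growth rate measured on the same plate (replicates
matched within plates); 1 means no cost.  The maximum growth rate is used
because it correlates well with both the curve integral and the yield.

The additive-cost prediction for a double mutant hitting two different
receptors is 1 minus the sum of the mean single-mutation costs of each
receptor category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .growth import NO_PHAGE, GrowthMetrics
from .stats import WelchTResult, welch_t


@dataclass(frozen=True)
class FitnessRecord:
    lineage: str
    relative_fitness: float  # mean over technical replicates
    se: float  # NaN with < 2 technical replicates
    n_technical: int
    plate_id: str


class AdditivePrediction(NamedTuple):
    value: float
    floored: bool  # True when the summed costs drive the prediction to <= 0


def relative_fitness(
    mutant_metrics: Sequence[GrowthMetrics],
    ancestor_metrics: Sequence[GrowthMetrics],
    plate_matched: bool = True,
) -> FitnessRecord:
    """Relative fitness of one mutant: max rate over plate-matched ancestral mean.

    Each technical replicate of the mutant is divided by the mean ancestral
    maximum growth rate of its own plate (or of all ancestor measurements
    when ``plate_matched`` is False); the record carries the mean ± SE over
    technical replicates.
    """
    if not mutant_metrics:
        raise ValueError("no mutant measurements")
    if not ancestor_metrics:
        raise ValueError("no ancestor measurements")
    lineages = {m.lineage for m in mutant_metrics}
    if len(lineages) != 1:
        raise ValueError(f"mutant metrics mix lineages: {sorted(lineages)}")
    anc_by_plate: dict[str, list[float]] = {}
    for a in ancestor_metrics:
        anc_by_plate.setdefault(a.plate_id, []).append(a.max_rate)
    values = []
    for m in mutant_metrics:
        if plate_matched:
            if m.plate_id not in anc_by_plate:
                raise ValueError(
                    f"no ancestor measurement on plate {m.plate_id!r} "
                    f"for lineage {m.lineage!r}"
                )
            anc_mean = float(np.mean(anc_by_plate[m.plate_id]))
        else:
            anc_mean = float(np.mean([a.max_rate for a in ancestor_metrics]))
        values.append(m.max_rate / anc_mean)
    values = np.asarray(values)
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) >= 2 else float("nan")
    return FitnessRecord(
        lineage=next(iter(lineages)),
        relative_fitness=float(values.mean()),
        se=se,
        n_technical=len(values),
        plate_id=mutant_metrics[0].plate_id,
    )


def fitness_table(
    metrics: Iterable[GrowthMetrics],
    ancestor_lineages: set[str],
    plate_matched: bool = True,
) -> list[FitnessRecord]:
    """Relative fitness for every non-ancestor lineage in a metrics set.

    Only no-phage measurements enter the fitness calculation.
    """
    no_phage = [m for m in metrics if m.condition == NO_PHAGE]
    ancestors = [m for m in no_phage if m.lineage in ancestor_lineages]
    if not ancestors:
        raise ValueError("no ancestral no-phage measurements found")
    by_lineage: dict[str, list[GrowthMetrics]] = {}
    for m in no_phage:
        if m.lineage not in ancestor_lineages:
            by_lineage.setdefault(m.lineage, []).append(m)
    return [
        relative_fitness(by_lineage[lin], ancestors, plate_matched=plate_matched)
        for lin in sorted(by_lineage)
    ]


def fitness_frame(records: Iterable[FitnessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lineage": r.lineage,
                "relative_fitness": r.relative_fitness,
                "se": r.se,
                "n_technical": r.n_technical,
                "plate_id": r.plate_id,
            }
            for r in records
        ]
    )


def additive_cost_prediction(
    mean_rf_by_category: Mapping[str, float],
) -> AdditivePrediction:
    """Predicted double-mutant relative fitness under cost additivity.

    cost_k = 1 − mean RF of single mutations in category k; the prediction
    is 1 − Σ costs.  Symmetric in its arguments; a category with zero cost
    leaves the prediction at the other category's RF.  A non-positive
    prediction is reported as-is with the ``floored`` flag set.
    """
    if len(mean_rf_by_category) < 2:
        raise ValueError("need mean RF for at least two receptor categories")
    total_cost = sum(1.0 - rf for rf in mean_rf_by_category.values())
    value = 1.0 - total_cost
    return AdditivePrediction(value=value, floored=value <= 0.0)


@dataclass(frozen=True)
class BurdenComparison:
    n_single: int
    n_multiple: int
    mean_single: float
    mean_multiple: float
    welch: WelchTResult


def fitness_by_mutation_burden(
    fitness: Sequence[FitnessRecord],
    counts: Mapping[str, int],
) -> BurdenComparison:
    """Welch's t comparing single- vs multi-mutation lineages (single − multiple).

    A positive t means single-mutation lineages are fitter.  Lineages with
    zero counted mutations are left out of both groups.
    """
    single, multiple = [], []
    for rec in fitness:
        k = counts.get(rec.lineage)
        if k is None or k == 0:
            continue
        (single if k == 1 else multiple).append(rec.relative_fitness)
    if len(single) < 2 or len(multiple) < 2:
        raise ValueError(
            f"each burden group needs >= 2 lineages (got {len(single)} single, "
            f"{len(multiple)} multiple)"
        )
    return BurdenComparison(
        n_single=len(single),
        n_multiple=len(multiple),
        mean_single=float(np.mean(single)),
        mean_multiple=float(np.mean(multiple)),
        welch=welch_t(single, multiple),
    )
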