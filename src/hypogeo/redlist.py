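"""Provisional IUCN Criterion-B categorization from eDNA incidence.

Population size of a phylotype is estimated from ASV-type incidence as

    N = Σᵢ ASVᵢ × 10 × 12/7

where ASVᵢ is the number of distinct ASV types of the phylotype in sample
i, 10 is the mature-individual multiplier for fungi, and 12/7 corrects for
the average number of host trees contributing to a pooled sample.
Phylotypes with N above the eligibility threshold (500 mature individuals)
are scored against the Criterion-B1 (EOO) and B2 (AOO) area thresholds;
when the two criteria disagree the higher threat category is assigned.
Phylotypes at or below the threshold are Data Deficient regardless of
geometry.  Because a single-timepoint eDNA survey cannot assess the B
subcriteria (fragmentation, decline, fluctuation), the output is a
provisional flag of potential conservation concern, not a full IUCN
listing.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import IncidenceTable, SampleTable
from .range_metrics import EooStatus, OccurrenceSet, RangeMetrics, range_metrics_for

__all__ = [
    "Category",
    "ThresholdTable",
    "PopulationEstimate",
    "RedListAssessment",
    "estimate_population",
    "categorize_b1",
    "categorize_b2",
    "combine_categories",
    "assess_phylotype",
    "assess_table",
    "MATURE_INDIVIDUAL_MULTIPLIER",
    "POOLING_FACTOR",
]

#: Mature-individual multiplier for fungi.
MATURE_INDIVIDUAL_MULTIPLIER = 10.0
#: Average-trees-per-pooled-sample correction (12/7), kept exact.
POOLING_FACTOR = Fraction(12, 7)


@functools.total_ordering
class Category(enum.Enum):
    """Red-list categories ordered by threat severity (CR most severe)."""

    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"
    DD = "DD"
    NOT_EVALUATED = "NOT_EVALUATED"

    @property
    def severity(self) -> int:
        return {"CR": 5, "EN": 4, "VU": 3, "NT": 2, "LC": 1,
                "DD": 0, "NOT_EVALUATED": 0}[self.value]

    def __lt__(self, other: "Category") -> bool:
        return self.severity < other.severity


@dataclass(frozen=True)
class ThresholdTable:
    """Criterion-B area thresholds (km², strict upper bounds) and the
    population-size eligibility gate.

    Defaults follow the IUCN v3.1 Criterion B table: B1 (EOO) CR < 100,
    EN < 5,000, VU < 20,000; B2 (AOO) CR < 10, EN < 500, VU < 2,000.
    NT has no numeric Criterion-B bound and is reachable only through a
    user-supplied custom table.
    """

    b1: tuple[tuple[Category, float], ...] = (
        (Category.CR, 100.0), (Category.EN, 5_000.0), (Category.VU, 20_000.0),
    )
    b2: tuple[tuple[Category, float], ...] = (
        (Category.CR, 10.0), (Category.EN, 500.0), (Category.VU, 2_000.0),
    )
    eligibility_n: float = 500.0

    def __post_init__(self) -> None:
        for name, bounds in (("b1", self.b1), ("b2", self.b2)):
            values = [b for _, b in bounds]
            if any(x >= y for x, y in zip(values, values[1:])):
                raise ValueError(f"{name} thresholds must be strictly increasing")


@dataclass
class PopulationEstimate:
    """Estimated mature individuals for one phylotype."""

    phylotype_id: str
    n_estimated: float
    multiplier: float = MATURE_INDIVIDUAL_MULTIPLIER
    pooling_factor: float = float(POOLING_FACTOR)
    per_sample_terms: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class RedListAssessment:
    phylotype_id: str
    n_estimated: float
    eligible: bool
    category_b1: Category
    category_b2: Category
    category_final: Category
    thresholds: ThresholdTable = field(repr=False, default_factory=ThresholdTable)


def estimate_population(
    incidence: Sequence[int] | np.ndarray,
    sample_ids: Sequence[str] | None = None,
    phylotype_id: str = "",
    multiplier: float = MATURE_INDIVIDUAL_MULTIPLIER,
    pooling_factor: float | Fraction = POOLING_FACTOR,
) -> PopulationEstimate:
    """Apply N = Σ(ASVᵢ × multiplier × pooling_factor) to one phylotype.

    The default pooling factor is the exact fraction 12/7, so e.g. a total
    of 7 ASV types gives N = 120 exactly.  Empty incidence yields N = 0.
    """
    counts = np.asarray(incidence, dtype=float)
    if counts.size and np.any(counts < 0):
        raise ValueError("ASV-type counts must be non-negative")
    total = int(counts.sum()) if counts.size else 0
    if isinstance(pooling_factor, Fraction):
        n_est = float(total * Fraction(multiplier) * pooling_factor)
    else:
        n_est = total * multiplier * pooling_factor
    terms = []
    if sample_ids is not None:
        terms = [(sid, int(c)) for sid, c in zip(sample_ids, counts) if c > 0]
    return PopulationEstimate(phylotype_id, n_est, float(multiplier),
                              float(pooling_factor), terms)


def _categorize(area: float | None, bounds: tuple[tuple[Category, float], ...]) -> Category:
    if area is None:
        return Category.NOT_EVALUATED
    if area < 0:
        raise ValueError("area must be non-negative")
    for cat, upper in bounds:
        if area < upper:  # strict "<": boundary values fall to the less-threatened side
            return cat
    return Category.LC


def categorize_b1(eoo_km2: float | None, thresholds: ThresholdTable | None = None) -> Category:
    """Criterion B1 category from EOO; undefined EOO → NOT_EVALUATED."""
    t = thresholds or ThresholdTable()
    return _categorize(eoo_km2, t.b1)


def categorize_b2(aoo_km2: float, thresholds: ThresholdTable | None = None) -> Category:
    """Criterion B2 category from AOO."""
    t = thresholds or ThresholdTable()
    return _categorize(aoo_km2, t.b2)


def combine_categories(b1: Category, b2: Category) -> Category:
    """Higher-threat combination: the more severe of the two criteria wins.

    NOT_EVALUATED on one side defers to the other; both NOT_EVALUATED
    stays NOT_EVALUATED.
    """
    if b1 is Category.NOT_EVALUATED and b2 is Category.NOT_EVALUATED:
        return Category.NOT_EVALUATED
    if b1 is Category.NOT_EVALUATED:
        return b2
    if b2 is Category.NOT_EVALUATED:
        return b1
    return max(b1, b2)


def assess_phylotype(
    metrics: RangeMetrics,
    pop: PopulationEstimate,
    thresholds: ThresholdTable | None = None,
    degenerate_eoo_policy: str = "not_evaluated",
    require_eoo: bool = False,
) -> RedListAssessment:
    """Full provisional assessment of one phylotype.

    Eligibility is strict: N > eligibility_n is assessed, N ≤ eligibility_n
    is Data Deficient regardless of geometry.  A degenerate (collinear,
    zero-area) EOO does not auto-trigger CR: the default policy drops B1
    and relies on B2, since a zero hull area is a sampling-geometry
    artifact.  With ``require_eoo`` phylotypes whose EOO is undefined are
    NOT_EVALUATED rather than assessed on B2 alone.
    """
    t = thresholds or ThresholdTable()
    if metrics.phylotype_id and pop.phylotype_id and metrics.phylotype_id != pop.phylotype_id:
        raise ValueError("metrics and population estimate refer to different phylotypes")
    eligible = pop.n_estimated > t.eligibility_n
    if metrics.eoo_status is EooStatus.OK:
        b1 = categorize_b1(metrics.eoo_km2, t)
    elif metrics.eoo_status is EooStatus.DEGENERATE_COLLINEAR and degenerate_eoo_policy == "as_zero":
        b1 = categorize_b1(0.0, t)
    else:
        b1 = Category.NOT_EVALUATED
    b2 = categorize_b2(metrics.aoo_km2, t)
    if not eligible:
        final = Category.DD
    elif require_eoo and metrics.eoo_status is not EooStatus.OK:
        final = Category.NOT_EVALUATED
    else:
        final = combine_categories(b1, b2)
    return RedListAssessment(metrics.phylotype_id, pop.n_estimated, eligible, b1, b2, final, t)


def assess_table(
    incidence: IncidenceTable,
    samples: SampleTable,
    thresholds: ThresholdTable | None = None,
    cell_km: float = 2.0,
    correction_factor: float = 1.0,
    alpha: float = 0.0,
    require_eoo: bool = False,
) -> pd.DataFrame:
    """Assess every phylotype in an incidence table; one output row each.

    Occurrence points are the coordinates of samples where the phylotype
    has at least one ASV type.  Columns cover the population estimate,
    range metrics, per-criterion categories and the combined provisional
    category.
    """
    incidence.check_joinable(samples)
    t = thresholds or ThresholdTable()
    rows = []
    for i, pid in enumerate(incidence.phylotype_ids):
        counts = incidence.asv_types[i]
        present = counts > 0
        pop = estimate_population(counts, incidence.sample_ids, pid)
        if not present.any():
            rows.append({
                "phylotype_id": pid, "genus": incidence.genera[i],
                "n_samples": 0, "n_grids": 0, "n_estimated": 0.0,
                "aoo_km2": 0.0, "n_occupied_cells": 0,
                "eoo_km2": np.nan, "eoo_status": EooStatus.UNDEFINED_TOO_FEW_POINTS.value,
                "category_b1": Category.NOT_EVALUATED.value,
                "category_b2": Category.NOT_EVALUATED.value,
                "category_final": Category.DD.value,
            })
            continue
        recs = [samples[sid] for sid, p in zip(incidence.sample_ids, present) if p]
        occ = OccurrenceSet(pid, [(r.latitude, r.longitude) for r in recs])
        metrics = range_metrics_for(occ, cell_km, correction_factor, alpha)
        res = assess_phylotype(metrics, pop, t, require_eoo=require_eoo)
        rows.append({
            "phylotype_id": pid, "genus": incidence.genera[i],
            "n_samples": int(present.sum()),
            "n_grids": len({r.grid_id for r in recs}),
            "n_estimated": res.n_estimated,
            "aoo_km2": metrics.aoo_km2,
            "n_occupied_cells": metrics.n_occupied_cells,
            "eoo_km2": metrics.eoo_km2 if metrics.eoo_km2 is not None else np.nan,
            "eoo_status": metrics.eoo_status.value,
            "category_b1": res.category_b1.value,
            "category_b2": res.category_b2.value,
            "category_final": res.category_final.value,
        })
    columns = ["phylotype_id", "genus", "n_samples", "n_grids", "n_estimated",
               "aoo_km2", "n_occupied_cells", "eoo_km2", "eoo_status",
               "category_b1", "category_b2", "category_final"]
    return pd.DataFrame(rows, columns=columns)
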