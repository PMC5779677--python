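"""Chromosome counting, modal complements, and B-chromosome frequency tables.

Diploid sphaeriid karyotypes commonly carry supernumerary (B) chromosomes:
small dispensable elements whose number varies between cells of one
individual, typically in even counts. A cell's raw chromosome count is
therefore decomposed against the population's modal diploid number into
one of four categories: ``modal`` (the 2n complement), ``hypodiploid``
(chromosome loss), ``hyperdiploid`` (2n + B chromosomes), and ``polyploid``
(doubled, about 4n, complements).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import AmbiguousModeError, ValidationError
from .io import MetaphaseSpread

CATEGORIES = ("modal", "hypodiploid", "hyperdiploid", "polyploid")

#: Polyploid band half-widths: a doubled complement may have lost up to
#: this many chromosomes ...
POLYPLOID_LOSS_TOLERANCE = 2
#: ... or carry up to this many Bs and still be scored 4n.
POLYPLOID_MAX_B = 8


@dataclass(frozen=True)
class CellAnnotation:
    """Ploidy category of one metaphase relative to the modal complement."""

    cell_id: str
    raw_count: int
    category: str
    b_count: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown ploidy category {self.category!r}")
        if (self.category == "hyperdiploid") != (self.b_count is not None):
            raise ValidationError("b_count is defined iff category is hyperdiploid")
        if self.b_count is not None and self.b_count <= 0:
            raise ValidationError("hyperdiploid b_count must be positive")


@dataclass(frozen=True)
class CountTable:
    """Chromosome-number frequency distribution for one population."""

    population_code: str
    counts: Mapping[int, int]
    total_cells: int
    modal_number: int
    percentages: Mapping[int, float]

    def __post_init__(self):
        if self.total_cells != sum(self.counts.values()):
            raise ValidationError("total_cells inconsistent with counts")
        if abs(sum(self.percentages.values()) - 100.0) > 0.1:
            raise ValidationError("percentages do not sum to 100")
        if self.counts[self.modal_number] != max(self.counts.values()):
            raise ValidationError("modal_number does not attain the maximum count")

    def to_dataframe(self) -> pd.DataFrame:
        nums = sorted(self.counts)
        return pd.DataFrame(
            {
                "population": self.population_code,
                "chromosome_number": nums,
                "cells": [self.counts[k] for k in nums],
                "percent": [round(self.percentages[k], 2) for k in nums],
            }
        )


def count_chromosomes(spread: MetaphaseSpread) -> int:
    """Number of chromosomes in a metaphase = number of measured records."""
    return len(spread.records)


def modal_complement(counts: Mapping[int, int]) -> int:
    """Chromosome number attaining the maximal cell count.

    Raises :class:`AmbiguousModeError` listing the tied values when the
    maximum is not unique.
    """
    if not counts:
        raise ValidationError("empty count distribution has no mode")
    top = max(counts.values())
    modes = [k for k, v in counts.items() if v == top]
    if len(modes) > 1:
        raise AmbiguousModeError(modes)
    return modes[0]


def annotate_count(
    cell_id: str, raw_count: int, modal_number: int, polyploid_factor: int = 2
) -> CellAnnotation:
    """Categorize one cell's raw chromosome count against the modal 2n."""
    if modal_number <= 0:
        raise ValidationError("modal_number must be positive")
    poly_lo = polyploid_factor * modal_number - POLYPLOID_LOSS_TOLERANCE
    if raw_count == modal_number:
        return CellAnnotation(cell_id, raw_count, "modal")
    if raw_count >= poly_lo:
        return CellAnnotation(cell_id, raw_count, "polyploid")
    if raw_count < modal_number:
        return CellAnnotation(cell_id, raw_count, "hypodiploid")
    return CellAnnotation(
        cell_id, raw_count, "hyperdiploid", b_count=raw_count - modal_number
    )


def annotate_cells(
    spreads: Iterable[MetaphaseSpread], modal_number: int, polyploid_factor: int = 2
) -> list[CellAnnotation]:
    """Annotate every metaphase of a sample against the modal complement."""
    return [
        annotate_count(s.cell_id, count_chromosomes(s), modal_number, polyploid_factor)
        for s in spreads
    ]


def frequency_table(
    annotations: Iterable[CellAnnotation], population_code: str = ""
) -> CountTable:
    """Chromosome-number frequency distribution with percentages.

    Percentages are ``100 * cells / total`` per observed chromosome number
    (reported at 2 decimals by the writers; stored unrounded here).
    """
    anns = list(annotations)
    if not anns:
        raise ValidationError("no cell annotations supplied")
    counts = Counter(a.raw_count for a in anns)
    total = len(anns)
    return CountTable(
        population_code=population_code,
        counts=dict(sorted(counts.items())),
        total_cells=total,
        modal_number=modal_complement(counts),
        percentages={k: 100.0 * v / total for k, v in sorted(counts.items())},
    )


def b_count_distribution(annotations: Iterable[CellAnnotation]) -> dict[int, int]:
    """B-chromosome count distribution over all non-polyploid cells.

    Modal cells count as 0 Bs; hyperdiploid cells contribute their
    ``b_count``. Hypodiploid and polyploid cells are excluded (their B
    status is confounded with loss/doubling).
    """
    dist: Counter[int] = Counter()
    for a in annotations:
        if a.category == "modal":
            dist[0] += 1
        elif a.category == "hyperdiploid":
            dist[a.b_count] += 1
    return dict(sorted(dist.items()))
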