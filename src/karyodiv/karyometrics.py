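"""Karyotype assembly and karyometric statistics.

This module implements the morphometric half of a comparative-cytogenetics
workflow for diploid karyotypes: homolog pairing by morphology, the total
haploid complement length (TCL), relative chromosome lengths, the
centromeric index (CI), Levan centromere classification with a 95%
confidence-interval "binary" rule for boundary-straddling pairs, per-
population summary tables, and interpopulation comparisons by the pooled-
variance two-sample Student's *t* test.

Definitions
-----------
centromeric index
    ``100 * short_arm / (short_arm + long_arm)``; at most 50 by
    construction since the short arm is the shorter one.
relative length
    ``100 * pair_length / TCL`` where TCL is the sum of one representative
    (pair-mean) length per chromosome pair of a metaphase.
Levan classes
    metacentric (m) for CI in (37.5, 50], submetacentric (sm) in
    (25, 37.5], subtelocentric (st) in (12.5, 25], telocentric (t) in
    (0, 12.5]. Boundary values belong to the lower class (CI = 37.5 is sm).
binary terminology
    When the two-sided 95% confidence interval of a pair's mean CI spans a
    Levan boundary, the pair receives a dual label such as ``m-sm``, with
    the mean's own class first.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientComplementError, ValidationError
from .io import ChromosomeRecord, MetaphaseSpread

LEVAN_CLASSES = ("m", "sm", "st", "t")
#: Upper CI bound of each class, descending; boundaries belong to the class below.
LEVAN_BOUNDS = (50.0, 37.5, 25.0, 12.5)


class MeanSD(NamedTuple):
    mean: float
    sd: float


@dataclass(frozen=True)
class HomologPair:
    """Two homologous chromosomes matched within one metaphase."""

    first: ChromosomeRecord
    second: ChromosomeRecord

    @property
    def mean_length(self) -> float:
        return (self.first.total_length + self.second.total_length) / 2.0

    @property
    def mean_ci(self) -> float:
        return (
            centromeric_index(self.first.short_arm, self.first.long_arm)
            + centromeric_index(self.second.short_arm, self.second.long_arm)
        ) / 2.0


@dataclass(frozen=True)
class KaryotypePairSummary:
    """Per-pair summary statistics across the karyotypes of one population."""

    pair_index: int
    abs_len: MeanSD
    rel_len: MeanSD
    ci: MeanSD
    n_karyotypes: int
    levan_class: str

    def __post_init__(self):
        if not (0.0 < self.ci.mean <= 50.0):
            raise ValidationError(
                f"pair {self.pair_index}: mean CI {self.ci.mean} outside (0, 50]"
            )
        if not (0.0 < self.rel_len.mean < 100.0):
            raise ValidationError(
                f"pair {self.pair_index}: mean relative length "
                f"{self.rel_len.mean} outside (0, 100)"
            )


@dataclass(frozen=True)
class KaryotypeTable:
    """Population-level karyotype table: ordered pair summaries plus TCL."""

    population_code: str
    pairs: tuple[KaryotypePairSummary, ...]
    tcl: float

    def __post_init__(self):
        if self.pairs:
            rel_sum = sum(p.rel_len.mean for p in self.pairs)
            if abs(rel_sum - 100.0) > 0.5:
                raise ValidationError(
                    f"relative lengths sum to {rel_sum:.3f}, expected 100 +/- 0.5"
                )
            abs_sum = sum(p.abs_len.mean for p in self.pairs)
            if abs(abs_sum - self.tcl) > 0.01 * len(self.pairs):
                raise ValidationError(
                    f"TCL {self.tcl} inconsistent with pair-length sum {abs_sum:.4f}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [p.pair_index for p in self.pairs],
                "abs_len_mean": [p.abs_len.mean for p in self.pairs],
                "abs_len_sd": [p.abs_len.sd for p in self.pairs],
                "rel_len_mean": [p.rel_len.mean for p in self.pairs],
                "rel_len_sd": [p.rel_len.sd for p in self.pairs],
                "ci_mean": [p.ci.mean for p in self.pairs],
                "ci_sd": [p.ci.sd for p in self.pairs],
                "class": [p.levan_class for p in self.pairs],
            }
        )


def centromeric_index(short_arm: float, long_arm: float) -> float:
    """CI = 100 * short / (short + long), in (0, 50]."""
    if short_arm <= 0 or long_arm <= 0:
        raise ValidationError("arm lengths must be strictly positive")
    if short_arm > long_arm:
        raise ValidationError("short arm exceeds long arm")
    return 100.0 * short_arm / (short_arm + long_arm)


def total_complement_length(pair_mean_lengths: Iterable[float]) -> float:
    """TCL: sum of one representative length per chromosome pair (haploid sum)."""
    lengths = list(pair_mean_lengths)
    if not lengths:
        raise ValidationError("TCL of an empty complement is undefined")
    if any(x <= 0 for x in lengths):
        raise ValidationError("pair lengths must be strictly positive")
    return float(sum(lengths))


def relative_length(pair_length: float, tcl: float) -> float:
    """RL = 100 * pair_length / TCL."""
    if pair_length <= 0:
        raise ValidationError("pair length must be strictly positive")
    if pair_length > tcl:
        raise ValidationError(f"pair length {pair_length} exceeds TCL {tcl}")
    return 100.0 * pair_length / tcl


def classify_levan(ci: float) -> str:
    """Levan centromere class from a centromeric index.

    Bands (upper bound inclusive): m (37.5, 50], sm (25, 37.5],
    st (12.5, 25], t (0, 12.5].
    """
    if not (0.0 < ci <= 50.0):
        raise ValidationError(f"centromeric index {ci} outside (0, 50]")
    for cls, bound in zip(LEVAN_CLASSES, LEVAN_BOUNDS):
        lower = LEVAN_BOUNDS[LEVAN_BOUNDS.index(bound) + 1] if bound != 12.5 else 0.0
        if lower < ci <= bound:
            return cls
    raise AssertionError("unreachable")  # pragma: no cover


def ci_confidence_interval(
    ci_mean: float, ci_sd: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided t confidence interval for a mean CI, clipped to (0, 50].

    Uses the Student t quantile with ``n - 1`` degrees of freedom.
    """
    if n < 2:
        raise ValidationError("confidence interval requires n >= 2 karyotypes")
    if ci_sd < 0:
        raise ValidationError("SD must be non-negative")
    q = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    half = q * ci_sd / math.sqrt(n)
    lo = max(ci_mean - half, np.nextafter(0.0, 1.0))
    hi = min(ci_mean + half, 50.0)
    return float(lo), float(hi)


def classify_with_ci_rule(ci_mean: float, ci_sd: float, n: int) -> str:
    """Levan class with the 95%-CI binary rule.

    If the 95% confidence interval of the mean CI lies within one Levan
    band the single class is returned; if it spans a band boundary a dual
    label is returned with the mean's own class first (e.g. mean 38.8 with
    an interval spanning 37.5 gives ``m-sm``; mean 36.6 gives ``sm-m``).
    """
    lo, hi = ci_confidence_interval(ci_mean, ci_sd, n)
    mean_cls = classify_levan(ci_mean)
    spanned = {classify_levan(lo), classify_levan(hi), mean_cls}
    if len(spanned) == 1:
        return mean_cls
    ordered = [mean_cls] + [
        c
        for c in sorted(spanned - {mean_cls}, key=LEVAN_CLASSES.index)
        if c != mean_cls
    ]
    return "-".join(ordered)


def classify_joint(summaries: Sequence[tuple[float, float, int]]) -> str:
    """Joint Levan label for one pair reported across several populations.

    The pooled (unweighted) mean CI across populations decides the leading
    class; the label is binary whenever any single population's 95%
    confidence interval spans a Levan boundary.
    """
    if not summaries:
        raise ValidationError("no population summaries supplied")
    pooled_mean = float(np.mean([m for m, _, _ in summaries]))
    lead = classify_levan(pooled_mean)
    spanned = {lead}
    for mean, sd, n in summaries:
        lo, hi = ci_confidence_interval(mean, sd, n)
        spanned |= {classify_levan(lo), classify_levan(hi)}
    if len(spanned) == 1:
        return lead
    ordered = [lead] + sorted(spanned - {lead}, key=LEVAN_CLASSES.index)
    return "-".join(ordered)


def _pair_dissimilarity(
    a: ChromosomeRecord, b: ChromosomeRecord, length_scale: float
) -> float:
    """Squared distance in (total length, CI) space, with length in units of
    the complement's mean chromosome length and CI in units of its full
    0-50 range, so neither axis dominates."""
    dl = (a.total_length - b.total_length) / length_scale
    dc = (
        centromeric_index(a.short_arm, a.long_arm)
        - centromeric_index(b.short_arm, b.long_arm)
    ) / 50.0
    return dl * dl + dc * dc


def assemble_karyotype(
    spread: MetaphaseSpread, n_pairs: int
) -> tuple[list[HomologPair], list[ChromosomeRecord]]:
    """Pair homologs by morphology within one metaphase.

    The ``2 * n_pairs`` longest chromosomes are grouped into ``n_pairs``
    pairs minimizing the total within-pair dissimilarity in (total length,
    centromeric index) space, via minimum-weight perfect matching. Pairs
    are returned ordered by descending mean length; the remaining (short)
    chromosomes are returned as leftover — candidate supernumerary Bs.
    """
    if len(spread.records) < 2 * n_pairs:
        raise InsufficientComplementError(
            f"cell {spread.cell_id!r}: {len(spread.records)} chromosomes, "
            f"need {2 * n_pairs} for {n_pairs} pairs"
        )
    ranked = sorted(
        spread.records, key=lambda r: (-r.total_length, r.chrom_id)
    )
    members = ranked[: 2 * n_pairs]
    leftover = ranked[2 * n_pairs :]

    length_scale = float(np.mean([r.total_length for r in members]))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(members)))
    for i, j in itertools.combinations(range(len(members)), 2):
        graph.add_edge(
            i, j, weight=_pair_dissimilarity(members[i], members[j], length_scale)
        )
    matching = nx.min_weight_matching(graph)

    pairs = []
    for i, j in matching:
        a, b = members[min(i, j)], members[max(i, j)]
        pairs.append(HomologPair(a, b))
    pairs.sort(key=lambda p: -p.mean_length)
    return pairs, leftover


def karyotype_metrics(pairs: Sequence[HomologPair]) -> pd.DataFrame:
    """Per-pair absolute length, relative length and CI for one metaphase.

    The pair value is the arithmetic mean of its two homologs; relative
    lengths are normalized within the metaphase and sum to exactly 100.
    """
    abs_len = np.array([p.mean_length for p in pairs])
    tcl = total_complement_length(abs_len)
    return pd.DataFrame(
        {
            "pair": np.arange(1, len(pairs) + 1),
            "abs_len": abs_len,
            "rel_len": 100.0 * abs_len / tcl,
            "ci": [p.mean_ci for p in pairs],
        }
    )


def summarize_population(
    spreads: Iterable[MetaphaseSpread],
    n_pairs: int,
    population_code: str = "",
) -> KaryotypeTable:
    """Per-pair mean +/- SD karyotype table over a population's karyotypes.

    Each metaphase contributes one value per pair per statistic (the mean
    of its two homologs); relative lengths are computed per metaphase and
    then averaged. Pairs are indexed positionally by descending length
    rank within each karyotype. SDs are sample SDs (divisor n - 1). The
    Levan label applies the 95%-CI binary rule to the CI summary.
    """
    per_cell = []
    for spread in spreads:
        pairs, _ = assemble_karyotype(spread, n_pairs)
        per_cell.append(karyotype_metrics(pairs))
    if len(per_cell) < 2:
        raise ValidationError("population summary requires >= 2 karyotypes")
    if len({len(m) for m in per_cell}) != 1:
        raise ValidationError("karyotypes have inconsistent pair counts")

    n = len(per_cell)
    abs_mat = np.column_stack([m["abs_len"].to_numpy() for m in per_cell])
    rel_mat = np.column_stack([m["rel_len"].to_numpy() for m in per_cell])
    ci_mat = np.column_stack([m["ci"].to_numpy() for m in per_cell])

    order = np.argsort(-abs_mat.mean(axis=1), kind="stable")
    summaries = []
    for rank, idx in enumerate(order, start=1):
        ci_mean = float(ci_mat[idx].mean())
        ci_sd = float(ci_mat[idx].std(ddof=1))
        summaries.append(
            KaryotypePairSummary(
                pair_index=rank,
                abs_len=MeanSD(float(abs_mat[idx].mean()), float(abs_mat[idx].std(ddof=1))),
                rel_len=MeanSD(float(rel_mat[idx].mean()), float(rel_mat[idx].std(ddof=1))),
                ci=MeanSD(ci_mean, ci_sd),
                n_karyotypes=n,
                levan_class=classify_with_ci_rule(ci_mean, ci_sd, n),
            )
        )
    tcl = float(sum(s.abs_len.mean for s in summaries))
    return KaryotypeTable(
        population_code=population_code, pairs=tuple(summaries), tcl=tcl
    )


def two_sample_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float, int]:
    """Pooled-variance two-sample Student t from summary statistics.

    Returns ``(t, p, df)`` with two-sided p from the t distribution with
    ``n_a + n_b - 2`` degrees of freedom. Zero pooled variance with equal
    means yields ``t = 0, p = 1``.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("t test requires n >= 2 in each sample")
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled == 0.0:
        if mean_a == mean_b:
            return 0.0, 1.0, df
        return math.copysign(math.inf, mean_a - mean_b), 0.0, df
    se = math.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def compare_populations(
    table_a: KaryotypeTable, table_b: KaryotypeTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise interpopulation comparison of relative lengths and CIs.

    One pooled-variance Student t test per chromosome pair per statistic,
    flagged significant when two-sided P < ``alpha`` (no multiple-testing
    correction; each pair is judged at the flat threshold).
    """
    if len(table_a.pairs) != len(table_b.pairs):
        raise ValidationError(
            "populations have different pair counts: "
            f"{len(table_a.pairs)} vs {len(table_b.pairs)}"
        )
    rows = []
    for pa, pb in zip(table_a.pairs, table_b.pairs):
        for stat_name in ("rel_len", "ci"):
            ma, mb = getattr(pa, stat_name), getattr(pb, stat_name)
            t, p, df = two_sample_t_from_stats(
                ma.mean, ma.sd, pa.n_karyotypes, mb.mean, mb.sd, pb.n_karyotypes
            )
            rows.append(
                {
                    "pair": pa.pair_index,
                    "statistic": stat_name,
                    "t": t,
                    "df": df,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
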