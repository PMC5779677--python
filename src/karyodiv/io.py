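"""Data model and file I/O for chromosome measurement data and karyotype reports.

Measurements are exchanged as long-format TSV, one measured chromosome per
row, with columns ``population``, ``individual``, ``cell``, ``chromosome``,
``arm1_um`` and ``arm2_um`` (an optional ``species`` column labels the
population's species). Arm lengths are micrometres; the two arms may appear
in either order in the file and are canonicalized at read time so that
``short_arm <= long_arm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = (
    "population",
    "individual",
    "cell",
    "chromosome",
    "arm1_um",
    "arm2_um",
)


@dataclass(frozen=True)
class ChromosomeRecord:
    """One measured chromosome in one metaphase spread.

    Arms are stored canonically: ``short_arm <= long_arm``, both strictly
    positive and finite, in micrometres.
    """

    cell_id: str
    chrom_id: str
    short_arm: float
    long_arm: float

    def __post_init__(self):
        for name in ("short_arm", "long_arm"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"chromosome {self.chrom_id!r} in cell {self.cell_id!r}: "
                    f"{name} must be a positive finite length, got {v!r}"
                )
        if self.short_arm > self.long_arm:
            raise ValidationError(
                f"chromosome {self.chrom_id!r}: short_arm > long_arm "
                "(arms must be canonicalized before construction)"
            )

    @classmethod
    def from_arms(cls, cell_id: str, chrom_id: str, arm1: float, arm2: float):
        """Build a record from arms in arbitrary order (canonicalizes)."""
        a, b = sorted((float(arm1), float(arm2)))
        return cls(cell_id, chrom_id, a, b)

    @property
    def total_length(self) -> float:
        return self.short_arm + self.long_arm


@dataclass(frozen=True)
class MetaphaseSpread:
    """All measured chromosomes of one cell."""

    cell_id: str
    individual_id: str
    population_code: str
    records: tuple[ChromosomeRecord, ...]

    def __post_init__(self):
        if len(self.records) == 0:
            raise ValidationError(f"spread {self.cell_id!r} has no chromosomes")
        bad = {r.cell_id for r in self.records} - {self.cell_id}
        if bad:
            raise ValidationError(
                f"spread {self.cell_id!r} contains records from cells {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PopulationSample:
    """All metaphase spreads from one sampled population."""

    species_label: str
    population_code: str
    spreads: list[MetaphaseSpread] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len({s.individual_id for s in self.spreads})

    @property
    def n_cells(self) -> int:
        return len(self.spreads)


@dataclass(frozen=True)
class CBandPattern:
    """C-banding result: which pairs carry heterochromatin blocks.

    ``positive_pairs`` indexes into 1..n_pairs; ``b_positive`` records
    whether supernumerary (B) chromosomes showed any C-band.
    """

    n_pairs: int
    positive_pairs: frozenset[int]
    b_positive: bool = False

    def __post_init__(self):
        bad = set(self.positive_pairs) - set(range(1, self.n_pairs + 1))
        if bad:
            raise ValidationError(
                f"C-band positive pairs {sorted(bad)} outside 1..{self.n_pairs}"
            )


def read_measurements(path) -> list[PopulationSample]:
    """Read a long-format measurement TSV into population samples.

    Arms are canonicalized (short <= long); rows are grouped into spreads
    by (population, individual, cell) preserving row order within a spread,
    and spreads into populations preserving first-appearance order.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If an arm length is non-numeric or not strictly positive; the
        message names the offending data row (1-based, excluding header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement table missing column(s): {', '.join(missing)}")

    populations: dict[str, PopulationSample] = {}
    spread_rows: dict[tuple, list[ChromosomeRecord]] = {}
    spread_meta: dict[tuple, tuple[str, str, str]] = {}
    order: list[tuple] = []

    has_species = "species" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            arm1 = float(row.arm1_um)
            arm2 = float(row.arm2_um)
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {i}: non-numeric arm length "
                f"({row.arm1_um!r}, {row.arm2_um!r})"
            ) from None
        try:
            rec = ChromosomeRecord.from_arms(
                str(row.cell), str(row.chromosome), arm1, arm2
            )
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
        key = (str(row.population), str(row.individual), str(row.cell))
        if key not in spread_rows:
            spread_rows[key] = []
            species = str(getattr(row, "species", "")) if has_species else ""
            spread_meta[key] = (str(row.population), str(row.individual), species)
            order.append(key)
        spread_rows[key].append(rec)

    for key in order:
        pop_code, individual, species = spread_meta[key]
        spread = MetaphaseSpread(
            cell_id=key[2],
            individual_id=individual,
            population_code=pop_code,
            records=tuple(spread_rows[key]),
        )
        if pop_code not in populations:
            populations[pop_code] = PopulationSample(
                species_label=species, population_code=pop_code
            )
        populations[pop_code].spreads.append(spread)

    return list(populations.values())


def write_measurements(samples, path) -> None:
    """Inverse of :func:`read_measurements` (used by the simulator CLI)."""
    rows = []
    for sample in samples:
        for spread in sample.spreads:
            for rec in spread.records:
                rows.append(
                    {
                        "population": sample.population_code,
                        "species": sample.species_label,
                        "individual": spread.individual_id,
                        "cell": spread.cell_id,
                        "chromosome": rec.chrom_id,
                        "arm1_um": f"{rec.short_arm:.4f}",
                        "arm2_um": f"{rec.long_arm:.4f}",
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


REPORT_COLUMNS = (
    "pair",
    "abs_len_mean",
    "abs_len_sd",
    "rel_len_mean",
    "rel_len_sd",
    "ci_mean",
    "ci_sd",
    "class",
)


def write_karyotype_report(table, path) -> None:
    """Write a karyotype summary table as TSV, 2-decimal fixed precision.

    One data row per chromosome pair with columns ``pair``,
    ``abs_len_mean``, ``abs_len_sd``, ``rel_len_mean``, ``rel_len_sd``,
    ``ci_mean``, ``ci_sd``, ``class``. Round-trips through
    :func:`read_karyotype_report` up to the 2-decimal rounding.
    """
    if not table.pairs:
        raise ValidationError("refusing to write an empty karyotype table")
    rows = []
    for p in table.pairs:
        rows.append(
            {
                "pair": p.pair_index,
                "abs_len_mean": f"{p.abs_len.mean:.2f}",
                "abs_len_sd": f"{p.abs_len.sd:.2f}",
                "rel_len_mean": f"{p.rel_len.mean:.2f}",
                "rel_len_sd": f"{p.rel_len.sd:.2f}",
                "ci_mean": f"{p.ci.mean:.2f}",
                "ci_sd": f"{p.ci.sd:.2f}",
                "class": p.levan_class,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_karyotype_report(path, population_code: str = "", n_karyotypes: int = 10):
    """Read a karyotype report TSV back into a KaryotypeTable."""
    from .karyometrics import KaryotypePairSummary, KaryotypeTable, MeanSD

    df = pd.read_csv(path, sep="\t", dtype={"class": str})
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"karyotype report missing column(s): {', '.join(missing)}")
    pairs = tuple(
        KaryotypePairSummary(
            pair_index=int(r["pair"]),
            abs_len=MeanSD(float(r["abs_len_mean"]), float(r["abs_len_sd"])),
            rel_len=MeanSD(float(r["rel_len_mean"]), float(r["rel_len_sd"])),
            ci=MeanSD(float(r["ci_mean"]), float(r["ci_sd"])),
            n_karyotypes=n_karyotypes,
            levan_class=str(r["class"]),
        )
        for r in df.to_dict("records")
    )
    tcl = float(sum(p.abs_len.mean for p in pairs))
    return KaryotypeTable(population_code=population_code, pairs=pairs, tcl=tcl)
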