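"""Synthetic metaphase spreads and sequence alignments with known truth.

Two generators emulate the raw inputs of the karyometric / molecular
pipeline so that every downstream stage can be tested against a planted
ground truth:

* :func:`simulate_metaphases` draws per-cell chromosome measurements from
  a :class:`KaryotypeTruth`: a per-cell condensation factor (lognormal,
  median 1) scales all lengths — chromosomes condense to different
  degrees on different slides, which spreads absolute lengths while
  leaving relative lengths and centromeric indices untouched; each arm
  additionally receives independent multiplicative measurement noise.
  Cells may carry supernumerary (B) chromosomes drawn from a planted
  count distribution, lose one chromosome (hypodiploidy), or double the
  complement (tetraploidy).
* :func:`simulate_alignment` builds gapped alignments from a
  :class:`SeqTruth`: a random root sequence plus per-group planted
  substitutions and deletions, so group mean difference counts and
  ungapped lengths are known exactly.

All randomness flows through a single seeded generator; identical seed
and truth give identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .errors import ValidationError
from .io import ChromosomeRecord, MetaphaseSpread, PopulationSample
from .seqdiv import AlignedSeq
from . import datasets

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class KaryotypeTruth:
    """Generative parameters for one population's karyotype.

    Parameters
    ----------
    pair_lengths, pair_cis
        True total length (μm) and centromeric index (%) per chromosome
        pair, longest first.
    b_length, b_ci
        Size (μm) and centromeric index of supernumerary B chromosomes.
    b_count_pmf
        Distribution of the per-cell B count (must sum to 1).
    p_hypodiploid, p_tetraploid
        Per-cell probabilities of losing one chromosome / doubling the
        complement.
    sigma_condensation
        Lognormal sigma of the per-cell condensation factor (median 1);
        multiplicative and shared by all chromosomes of a cell.
    sigma_measure
        Lognormal sigma of the independent per-arm measurement noise.
    """

    pair_lengths: tuple[float, ...]
    pair_cis: tuple[float, ...]
    b_length: float = 2.5
    b_ci: float = 45.0
    b_count_pmf: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    p_hypodiploid: float = 0.0
    p_tetraploid: float = 0.0
    sigma_condensation: float = 0.15
    sigma_measure: float = 0.02

    def __post_init__(self):
        if len(self.pair_lengths) != len(self.pair_cis):
            raise ValidationError("pair_lengths and pair_cis length mismatch")
        if any(x <= 0 for x in self.pair_lengths) or self.b_length <= 0:
            raise ValidationError("lengths must be strictly positive")
        if any(not (0 < c <= 50) for c in self.pair_cis) or not (0 < self.b_ci <= 50):
            raise ValidationError("centromeric indices must lie in (0, 50]")
        probs = list(self.b_count_pmf.values())
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("b_count_pmf must be a probability distribution")
        for name in ("p_hypodiploid", "p_tetraploid"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be a probability")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_lengths)

    @property
    def modal_number(self) -> int:
        return 2 * self.n_pairs


def _truth_from_population(pop: str) -> KaryotypeTruth:
    counts = datasets.metaphase_counts()[pop]
    if pop == "E":
        df = datasets.mamillanum_karyotype_summary()
        modal = datasets.mamillanum_modal_number()
    else:
        df = datasets.nucleus_karyotype_summaries()[pop]
        modal = datasets.nucleus_modal_number()
    total = sum(counts.values())
    tetra = sum(v for k, v in counts.items() if k >= 2 * modal - 2)
    hypo = sum(v for k, v in counts.items() if k < modal)
    body = {
        k - modal: v
        for k, v in counts.items()
        if modal <= k < 2 * modal - 2
    }
    denom = sum(body.values())
    return KaryotypeTruth(
        pair_lengths=tuple(df["abs_mean"]),
        pair_cis=tuple(df["ci_mean"]),
        b_count_pmf={k: v / denom for k, v in body.items()},
        p_hypodiploid=hypo / total,
        p_tetraploid=tetra / total,
    )


def slovak_truth() -> KaryotypeTruth:
    """*S. nucleus* Slovak-population truth (2n = 28, B counts 0/4/6/8)."""
    return _truth_from_population("S")


def lithuanian_truth() -> KaryotypeTruth:
    return _truth_from_population("L")


def czech_truth() -> KaryotypeTruth:
    return _truth_from_population("C")


def mamillanum_truth() -> KaryotypeTruth:
    """*S. corneum* var. *mamillanum* truth (2n = 30, B counts 0-6)."""
    return _truth_from_population("E")


def simulate_metaphases(
    truth: KaryotypeTruth,
    n_cells: int,
    seed: int | np.random.Generator | None = None,
    population_code: str = "SYN",
    species_label: str = "synthetic",
    cells_per_individual: int = 1,
) -> PopulationSample:
    """Draw measured metaphase spreads from a karyotype truth.

    Per cell: a condensation factor scales all lengths; every homolog arm
    gets independent multiplicative noise; a B count is drawn from the
    planted distribution; with ``p_tetraploid`` the complement is doubled,
    else with ``p_hypodiploid`` one random chromosome is lost. Records
    are emitted in shuffled order.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    b_counts = sorted(truth.b_count_pmf)
    b_probs = np.array([truth.b_count_pmf[k] for k in b_counts], dtype=float)
    b_probs = b_probs / b_probs.sum()

    spreads = []
    for i in range(n_cells):
        cell_id = f"cell{i + 1:04d}"
        individual_id = f"ind{i // cells_per_individual + 1:04d}"
        cond = float(np.exp(rng.normal(0.0, truth.sigma_condensation)))
        tetra = rng.random() < truth.p_tetraploid
        hypo = (not tetra) and rng.random() < truth.p_hypodiploid
        n_b = int(rng.choice(b_counts, p=b_probs)) if b_counts else 0

        arms = []  # (true_short, true_long) per chromosome
        copies = 4 if tetra else 2
        for length, ci in zip(truth.pair_lengths, truth.pair_cis):
            short, long_ = length * ci / 100.0, length * (100.0 - ci) / 100.0
            arms.extend([(short, long_)] * copies)
        b_short = truth.b_length * truth.b_ci / 100.0
        b_long = truth.b_length - b_short
        arms.extend([(b_short, b_long)] * n_b)

        if hypo:
            drop = int(rng.integers(len(arms)))
            arms = arms[:drop] + arms[drop + 1 :]

        records = []
        for k, (short, long_) in enumerate(arms):
            noise = np.exp(rng.normal(0.0, truth.sigma_measure, size=2))
            records.append(
                ChromosomeRecord.from_arms(
                    cell_id,
                    f"chr{k + 1:03d}",
                    cond * short * noise[0],
                    cond * long_ * noise[1],
                )
            )
        order = rng.permutation(len(records))
        spreads.append(
            MetaphaseSpread(
                cell_id=cell_id,
                individual_id=individual_id,
                population_code=population_code,
                records=tuple(records[j] for j in order),
            )
        )
    return PopulationSample(
        species_label=species_label,
        population_code=population_code,
        spreads=spreads,
    )


# ---------------------------------------------------------------------------
# sequence truth


@dataclass(frozen=True)
class GroupSpec:
    """Planted edits defining one sequence group relative to the root."""

    substitutions: tuple[tuple[int, str], ...] = ()
    deletions: tuple[tuple[int, int], ...] = ()  # (start, length)
    n_seqs: int = 1


@dataclass(frozen=True)
class SeqTruth:
    """Root length plus per-group planted substitutions and deletions."""

    root_length: int
    groups: Mapping[str, GroupSpec]

    def __post_init__(self):
        if self.root_length < 1:
            raise ValidationError("root_length must be positive")
        for label, spec in self.groups.items():
            deleted = set()
            for start, length in spec.deletions:
                if start < 0 or length < 1 or start + length > self.root_length:
                    raise ValidationError(
                        f"group {label!r}: deletion ({start}, {length}) out of range"
                    )
                deleted |= set(range(start, start + length))
            for pos, base in spec.substitutions:
                if not (0 <= pos < self.root_length):
                    raise ValidationError(
                        f"group {label!r}: substitution position {pos} out of range"
                    )
                if base not in BASES:
                    raise ValidationError(
                        f"group {label!r}: invalid substitution base {base!r}"
                    )
                if pos in deleted:
                    raise ValidationError(
                        f"group {label!r}: substitution at {pos} inside a deletion"
                    )
            if spec.n_seqs < 1:
                raise ValidationError(f"group {label!r}: n_seqs must be >= 1")


def simulate_alignment(
    truth: SeqTruth, seed: int | np.random.Generator | None = None
) -> list[AlignedSeq]:
    """Generate a gapped alignment realizing a sequence truth.

    The root is drawn uniformly over A/C/G/T; at every planted
    substitution site the root base is re-drawn from the bases not
    planted by any group there, so each planted edit is guaranteed to be
    a real difference from the unedited groups. Copies within a group are
    identical; deletions appear as gap columns.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    root = list(rng.choice(BASES, size=truth.root_length))

    planted: dict[int, set[str]] = {}
    for spec in truth.groups.values():
        for pos, base in spec.substitutions:
            planted.setdefault(pos, set()).add(base)
    for pos, bases in sorted(planted.items()):
        allowed = [b for b in BASES if b not in bases]
        if not allowed:
            raise ValidationError(
                f"all four bases planted at position {pos}; no root base left"
            )
        if root[pos] in bases:
            root[pos] = str(rng.choice(allowed))

    out = []
    for label, spec in truth.groups.items():
        seq = root.copy()
        for pos, base in spec.substitutions:
            seq[pos] = base
        for start, length in spec.deletions:
            for p in range(start, start + length):
                seq[p] = "-"
        residues = "".join(seq)
        for k in range(spec.n_seqs):
            out.append(
                AlignedSeq(f"{label}_{k + 1}", residues, group_label=label)
            )
    return out


def _partitions(n: int, max_blocks: int = 4):
    """All partitions of range(n) with 2..max_blocks blocks."""
    for rgs in itertools.product(*[range(i + 1) for i in range(n)]):
        # restricted growth string condition
        if any(rgs[i] > max(rgs[:i], default=-1) + 1 for i in range(n)):
            continue
        k = max(rgs) + 1
        if not (2 <= k <= max_blocks):
            continue
        blocks = [tuple(i for i in range(n) if rgs[i] == b) for b in range(k)]
        yield tuple(blocks)


def truth_from_distance_matrix(
    labels: Sequence[str],
    matrix: np.ndarray,
    root_length: int,
    deletions: Mapping[str, tuple[tuple[int, int], ...]] | None = None,
    n_seqs: Mapping[str, int] | int = 1,
    offset: int = 0,
) -> SeqTruth:
    """Plant substitutions realizing a target integer difference matrix.

    Each alignment site induces a partition of the groups (groups sharing
    a base fall in one block); a site separates exactly the cross-block
    pairs. The requested matrix is decomposed into a non-negative integer
    combination of such partition indicators (at most four blocks — one
    base per block) by integer programming, and one variant column is
    planted per unit weight, at consecutive positions starting at
    ``offset``. Raises if the matrix is not realizable (e.g. a triangle
    inequality violation or more groups than representable).
    """
    labels = list(labels)
    n = len(labels)
    d = np.asarray(matrix, dtype=float)
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValidationError("matrix must be square and symmetric")
    if not np.allclose(d, np.round(d)):
        raise ValidationError("planted distances must be integers")
    pairs = list(itertools.combinations(range(n), 2))
    target = np.array([d[i, j] for i, j in pairs])

    parts = list(_partitions(n))
    A = np.zeros((len(pairs), len(parts)))
    for c, blocks in enumerate(parts):
        block_of = {}
        for b, members in enumerate(blocks):
            for m in members:
                block_of[m] = b
        for r, (i, j) in enumerate(pairs):
            if block_of[i] != block_of[j]:
                A[r, c] = 1.0
    res = milp(
        c=np.ones(len(parts)),
        constraints=LinearConstraint(A, target, target),
        integrality=np.ones(len(parts)),
        bounds=(0, np.inf),
    )
    if not res.success:
        raise ValidationError("difference matrix is not realizable by planted sites")
    weights = np.round(res.x).astype(int)

    subs: dict[str, list[tuple[int, str]]] = {lab: [] for lab in labels}
    pos = offset
    for c, w in enumerate(weights):
        for _ in range(int(w)):
            if pos >= root_length:
                raise ValidationError("root_length too short for planted sites")
            for b, members in enumerate(parts[c]):
                for m in members:
                    subs[labels[m]].append((pos, BASES[b]))
            pos += 1

    deletions = deletions or {}
    if isinstance(n_seqs, int):
        n_seqs = {lab: n_seqs for lab in labels}
    groups = {
        lab: GroupSpec(
            substitutions=tuple(subs[lab]),
            deletions=tuple(deletions.get(lab, ())),
            n_seqs=n_seqs.get(lab, 1),
        )
        for lab in labels
    }
    return SeqTruth(root_length=root_length, groups=groups)


def its1_like_truth(n_seqs_lsr: int = 3) -> SeqTruth:
    """ITS1-structured truth: three *S. nucleus* haplotype groups.

    Ukraine (550 bp), Lithuania/Slovakia/Russia (554 bp, ``n_seqs_lsr``
    identical copies) and Czech (556 bp) with planted differences 4
    (Ukraine vs either) and 2 (LSR vs Czech), realized as private sites
    (3, 1, 1) and group-specific terminal deletions.
    """
    labels = ["nucleus_Ukraine", "nucleus_LithSlovRus", "nucleus_Czech"]
    d = np.array([[0, 4, 4], [4, 0, 2], [4, 2, 0]])
    return truth_from_distance_matrix(
        labels,
        d,
        root_length=556,
        deletions={
            "nucleus_Ukraine": ((550, 6),),
            "nucleus_LithSlovRus": ((554, 2),),
        },
        n_seqs={"nucleus_LithSlovRus": n_seqs_lsr},
        offset=100,
    )


def s16_like_truth(n_seqs: int = 2) -> SeqTruth:
    """16S-structured truth: the four *S. nucleus* haplotype groups.

    Planted integer difference matrix equal to the published 16S
    *S. nucleus* block; multi-sequence groups carry identical copies so
    within-group means are exactly zero. The Czech group is one base
    shorter (474 vs 475 bp), as a terminal deletion.
    """
    block = datasets.s16_nucleus_block()
    labels = list(block.index)
    return truth_from_distance_matrix(
        labels,
        block.to_numpy(),
        root_length=475,
        deletions={"nucleus_Czech": ((474, 1),)},
        n_seqs={lab: n_seqs for lab in labels if lab != "nucleus_Ukraine"},
        offset=50,
    )
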