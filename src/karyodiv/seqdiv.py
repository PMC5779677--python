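"""Haplotype collapsing, number-of-differences distances, and NJ trees.

The distance used throughout is the raw *number of differences*: the count
of alignment sites at which two sequences carry different unambiguous
bases (A/C/G/T), with *pairwise deletion* — for each pair separately,
sites holding a gap (``-``), missing symbol (``?``/``N``) or any IUPAC
ambiguity code in either member are excluded. All substitutions count
equally (transitions and transversions); no substitution-model correction
is applied. Group-level matrices report the arithmetic mean of these
counts over all cross-group (or within-group) sequence pairs.

A dependency-free affine-gap global pairwise aligner is provided as
plumbing for near-identical sequence pairs; multiple alignments are
expected to be produced externally and read in as aligned FASTA. The
neighbor-joining tree built from a distance matrix is a visualization
aid only, not a phylogenetic inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import AlignmentError, ValidationError

UNAMBIGUOUS = frozenset("ACGT")
GAPLIKE = frozenset("-?")


def normalize_residues(residues: str) -> str:
    """Uppercase and normalize U (RNA) to T."""
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class AlignedSeq:
    """One sequence row of an alignment, with its group label."""

    seq_id: str
    residues: str
    group_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", normalize_residues(self.residues))
        if not self.residues:
            raise ValidationError(f"sequence {self.seq_id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.residues if c not in GAPLIKE)


def pairwise_differences(x: AlignedSeq, y: AlignedSeq) -> int:
    """Number of differences between two aligned sequences.

    Counts sites where both symbols are unambiguous bases and differ;
    sites with a gap, missing symbol or ambiguity code in either sequence
    are excluded (pairwise deletion).
    """
    if len(x) != len(y):
        raise AlignmentError(
            f"{x.seq_id!r} and {y.seq_id!r} have unequal aligned lengths "
            f"({len(x)} vs {len(y)})"
        )
    return sum(
        1
        for a, b in zip(x.residues, y.residues)
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS and a != b
    )


def shared_sites(x: AlignedSeq, y: AlignedSeq) -> int:
    """Number of sites retained by pairwise deletion for this pair."""
    if len(x) != len(y):
        raise AlignmentError("unequal aligned lengths")
    return sum(
        1
        for a, b in zip(x.residues, y.residues)
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS
    )


def collapse_haplotypes(seqs: Iterable[AlignedSeq]) -> dict[str, list[str]]:
    """Collapse aligned sequences into haplotypes.

    Sequences collapse together when they have zero pairwise differences
    *and* an identical gap/missing pattern. Returns a mapping from the
    canonical representative (lexicographically smallest ``seq_id``) to
    the sorted member ids.
    """
    buckets: dict[str, list[str]] = {}
    for s in seqs:
        key = "".join(c if c in UNAMBIGUOUS else "." for c in s.residues)
        buckets.setdefault(key, []).append(s.seq_id)
    return {min(ids): sorted(ids) for ids in buckets.values()}


@dataclass(frozen=True)
class DiffMatrix:
    """Group-level mean pairwise-difference matrix.

    ``between[i, j]`` (i != j) is the mean difference count over all
    cross pairs of groups i and j; ``within[label]`` is the mean over
    within-group pairs, or ``None`` for singleton groups.
    ``group_lengths`` holds one representative ungapped length per group.
    """

    group_labels: tuple[str, ...]
    between: np.ndarray
    within: Mapping[str, float | None]
    group_lengths: Mapping[str, int]

    def __post_init__(self):
        b = np.asarray(self.between, dtype=float)
        if b.shape != (len(self.group_labels),) * 2:
            raise ValidationError("between matrix shape mismatch")
        if not np.allclose(b, b.T):
            raise ValidationError("between matrix must be symmetric")
        if (b < 0).any():
            raise ValidationError("difference counts cannot be negative")

    def to_dataframe(self) -> pd.DataFrame:
        """Square table with within-group means on the diagonal."""
        df = pd.DataFrame(
            self.between, index=self.group_labels, columns=self.group_labels
        )
        for i, g in enumerate(self.group_labels):
            w = self.within[g]
            df.iloc[i, i] = np.nan if w is None else w
        return df


def group_distance_matrix(seqs: Iterable[AlignedSeq]) -> DiffMatrix:
    """Mean number-of-differences matrix between and within sequence groups.

    Groups are ordered by first appearance in the input. The between-group
    entry is the plain arithmetic mean over all cross pairs, so multi-
    member groups naturally yield fractional means; singleton groups have
    no within-group mean.
    """
    groups: dict[str, list[AlignedSeq]] = {}
    for s in seqs:
        groups.setdefault(s.group_label, []).append(s)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups for a distance matrix")
    for label, members in groups.items():
        if not members:
            raise ValidationError(f"group {label!r} is empty")

    labels = tuple(groups)
    k = len(labels)
    between = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = [
                pairwise_differences(a, b)
                for a in groups[labels[i]]
                for b in groups[labels[j]]
            ]
            between[i, j] = between[j, i] = float(np.mean(d))
    within: dict[str, float | None] = {}
    for label in labels:
        members = groups[label]
        if len(members) < 2:
            within[label] = None
        else:
            d = [
                pairwise_differences(members[i], members[j])
                for i in range(len(members))
                for j in range(i + 1, len(members))
            ]
            within[label] = float(np.mean(d))
    lengths = {label: groups[label][0].ungapped_length for label in labels}
    return DiffMatrix(labels, between, within, lengths)


# ---------------------------------------------------------------------------
# pairwise global alignment (Gotoh affine-gap dynamic programming)

_NEG = float("-inf")


def align_pair(
    x: str,
    y: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under affine gap scoring.

    The first residue of a gap scores ``gap_open``, each further residue
    ``gap_extend``. Traceback ties are broken deterministically: an
    aligned (match/mismatch) column is preferred over a gap, and a gap in
    ``x`` over a gap in ``y``. Returns the two gapped strings and the
    alignment score.
    """
    x = normalize_residues(x)
    y = normalize_residues(y)
    if not x or not y:
        raise ValidationError("cannot align an empty sequence")
    n, m = len(x), len(y)

    # state 0 = aligned column, 1 = gap in x (consumes y), 2 = gap in y
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    GX = [[_NEG] * (m + 1) for _ in range(n + 1)]
    GY = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        GX[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        GY[i][0] = gap_open + gap_extend * (i - 1)

    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            s = match if xi == y[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], GX[i - 1][j - 1], GY[i - 1][j - 1])
            GX[i][j] = max(
                M[i][j - 1] + gap_open,
                GX[i][j - 1] + gap_extend,
                GY[i][j - 1] + gap_open,
            )
            GY[i][j] = max(
                M[i - 1][j] + gap_open,
                GX[i - 1][j] + gap_open,
                GY[i - 1][j] + gap_extend,
            )

    # traceback; preference order on ties: M, then GX (gap in x), then GY
    i, j = n, m
    finals = (M[n][m], GX[n][m], GY[n][m])
    score = max(finals)
    state = finals.index(score)
    ax: list[str] = []
    ay: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            s = match if x[i - 1] == y[j - 1] else mismatch
            ax.append(x[i - 1])
            ay.append(y[j - 1])
            prevs = (M[i - 1][j - 1], GX[i - 1][j - 1], GY[i - 1][j - 1])
            target = M[i][j] - s
            i, j = i - 1, j - 1
        elif state == 1:
            ax.append("-")
            ay.append(y[j - 1])
            prevs = (
                M[i][j - 1] + gap_open,
                GX[i][j - 1] + gap_extend,
                GY[i][j - 1] + gap_open,
            )
            target = GX[i][j]
            j -= 1
        else:
            ax.append(x[i - 1])
            ay.append("-")
            prevs = (
                M[i - 1][j] + gap_open,
                GX[i - 1][j] + gap_open,
                GY[i - 1][j] + gap_extend,
            )
            target = GY[i][j]
            i -= 1
        if i == 0 and j == 0:
            break
        if j == 0:
            state = 2
        elif i == 0:
            state = 1
        else:
            for k in range(3):
                if abs(prevs[k] - target) < 1e-9:
                    state = k
                    break
    return "".join(reversed(ax)), "".join(reversed(ay)), float(score)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(labels: Sequence[str], matrix: np.ndarray | DiffMatrix) -> str:
    """Neighbor-joining tree (Newick) from a symmetric distance matrix.

    Negative branch lengths arising from the NJ formulas are clamped to
    zero. For a :class:`DiffMatrix`, the between-group means are used with
    a zero diagonal. The result is a visualization of the distance
    structure, not a model-based phylogeny.
    """
    if isinstance(matrix, DiffMatrix):
        labels = matrix.group_labels
        matrix = matrix.between
    dm = np.asarray(matrix, dtype=float).copy()
    np.fill_diagonal(dm, 0.0)
    if len(labels) < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    tree = _skbio_nj(DistanceMatrix(dm, ids=list(labels)), neg_as_zero=True)
    out = StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()


# ---------------------------------------------------------------------------
# file I/O

def read_fasta(path, groups: Mapping[str, str] | None = None) -> list[AlignedSeq]:
    """Read (aligned or unaligned) FASTA; attach group labels if given.

    Sequences without an entry in ``groups`` form their own singleton
    group labelled by their id.
    """
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = groups.get(rec.id, rec.id) if groups is not None else rec.id
        seqs.append(AlignedSeq(rec.id, str(rec.seq), group_label=label))
    if not seqs:
        raise ValidationError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: Iterable[AlignedSeq], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n{s.residues}\n")


def read_group_table(path) -> dict[str, str]:
    """Two-column TSV (seq_id, group) to a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("group table needs two columns: seq_id, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_diffmatrix(dm: DiffMatrix, path) -> None:
    """DiffMatrix as TSV: square between-group table plus a within column."""
    df = dm.to_dataframe().round(2)
    df.insert(0, "bp", [dm.group_lengths[g] for g in dm.group_labels])
    df.to_csv(path, sep="\t", index_label="group")


def write_phylip(labels: Sequence[str], matrix: np.ndarray, path) -> None:
    """Square PHYLIP-style distance matrix."""
    dm = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, dm):
            name = lab[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{v:.4f}" for v in row) + "\n")
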