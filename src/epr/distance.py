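"""Yule dissimilarity between binary observation profiles.

For two profiles the 2x2 contingency counts are C_TT (shared presences),
C_FF (shared absences), and C_TF / C_FT (observations found in one profile
only).  The score is

    2 * C_TF * C_FT / (C_TT * C_FF + C_TF * C_FT)

with the convention that a zero numerator gives 0 even when the denominator
is also 0 (identical, nested or complementary degenerate profiles).  Shared
presence and shared absence enter symmetrically, so the score weighs gene
gain and loss equally; it ranges over [0, 2] and is a dissimilarity, not a
metric (the triangle inequality is not guaranteed).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Sequence

import numpy as np

from epr.observations import ObservationMatrix


class ContingencyCounts(NamedTuple):
    c_tt: int
    c_ff: int
    c_tf: int
    c_ft: int


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of pairwise Yule scores, zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("distance matrix shape does not match labels")

    @property
    def m(self) -> int:
        return len(self.labels)


def _as_binary(u: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(u)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError("profiles must be binary")
    return arr.astype(bool)


def contingency(u: Sequence[int] | np.ndarray, v: Sequence[int] | np.ndarray) -> ContingencyCounts:
    """Positionwise (1,1)/(0,0)/(1,0)/(0,1) counts for two equal-length profiles."""
    ub, vb = _as_binary(u), _as_binary(v)
    if ub.shape != vb.shape:
        raise ValueError(f"length mismatch: {ub.shape} vs {vb.shape}")
    return ContingencyCounts(
        c_tt=int(np.sum(ub & vb)),
        c_ff=int(np.sum(~ub & ~vb)),
        c_tf=int(np.sum(ub & ~vb)),
        c_ft=int(np.sum(~ub & vb)),
    )


def yule_from_counts(counts: ContingencyCounts) -> Fraction:
    num = 2 * counts.c_tf * counts.c_ft
    if num == 0:
        return Fraction(0)
    return Fraction(num, counts.c_tt * counts.c_ff + counts.c_tf * counts.c_ft)


def yule_exact(u: Sequence[int] | np.ndarray, v: Sequence[int] | np.ndarray) -> Fraction:
    """Yule dissimilarity as an exact rational."""
    return yule_from_counts(contingency(u, v))


def yule(u: Sequence[int] | np.ndarray, v: Sequence[int] | np.ndarray) -> float:
    return float(yule_exact(u, v))


def distance_matrix(matrix: ObservationMatrix | np.ndarray, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """All-pairs Yule dissimilarities of the observation-matrix rows."""
    if isinstance(matrix, ObservationMatrix):
        cells = matrix.cells
        labels = matrix.genome_ids
    else:
        cells = _as_binary(matrix)
        if labels is None:
            labels = tuple(str(i) for i in range(cells.shape[0]))
    m, n = cells.shape
    if m < 2:
        raise ValueError("need at least 2 genomes")
    if n == 0:
        raise ValueError("matrix has no observation columns")
    b = cells.astype(np.int64)
    tt = b @ b.T
    tf = b @ (1 - b).T
    ft = tf.T
    ff = n - tt - tf - ft
    num = 2 * tf * ft
    den = tt * ff + tf * ft
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(num == 0, 0.0, num / np.where(den == 0, 1, den))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(labels), values=d)
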