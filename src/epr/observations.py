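"""Binary "Function;Family" observation matrices.

An observation pairs a CAZy family with a molecular function (EC number or
``unknown``); the same EC in two families is two distinct observations.
Scoring distributes one unit of mass per annotated secreted protein:
decisive calls contribute 1 to their observation, indecisive calls split
the unit evenly across the candidate functions.  Scores are kept as exact
rationals so that two half-counts reach exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from epr.annot_io import EC_RE, FAMILY_RE, UNKNOWN_FUNCTION, AnnotationRecord

_SUBFAMILY_RE = re.compile(r"_[0-9]+$")


@dataclass(frozen=True, order=True)
class ObservationId:
    """One Function;Family observation. Canonical string form is ``FAMILY:EC``."""

    family: str
    function: str

    def __post_init__(self) -> None:
        if not FAMILY_RE.match(self.family):
            raise ValueError(f"malformed family token {self.family!r}")
        if self.function != UNKNOWN_FUNCTION and not EC_RE.match(self.function):
            raise ValueError(f"malformed function token {self.function!r}")

    def __str__(self) -> str:
        return f"{self.family}:{self.function}"

    @classmethod
    def parse(cls, text: str) -> "ObservationId":
        """Parse ``FAMILY:EC`` (canonical) or the reversed ``EC;FAMILY`` order."""
        for sep in (":", ";"):
            if sep in text:
                left, right = text.split(sep, 1)
                if FAMILY_RE.match(left):
                    return cls(family=left, function=right)
                if FAMILY_RE.match(right):
                    return cls(family=right, function=left)
        raise ValueError(f"cannot parse observation id {text!r}")


def collapse_subfamily(family: str) -> str:
    """``GH5_5`` -> ``GH5``; families without a subfamily suffix pass through."""
    return _SUBFAMILY_RE.sub("", family)


@dataclass
class ObservationMatrix:
    """Genomes x observations binary matrix with optional score provenance."""

    genome_ids: tuple[str, ...]
    observation_ids: tuple[ObservationId, ...]
    cells: np.ndarray
    provenance: dict[str, dict[ObservationId, Fraction]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        m, n = self.cells.shape
        if m != len(self.genome_ids) or n != len(self.observation_ids):
            raise ValueError("cell shape does not match labels")
        if len(set(self.genome_ids)) != m:
            raise ValueError("duplicate genome_id")
        if len(set(self.observation_ids)) != n:
            raise ValueError("duplicate observation_id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def row(self, genome_id: str) -> np.ndarray:
        return self.cells[self.genome_ids.index(genome_id)]

    def presence_set(self, genome_id: str) -> set[ObservationId]:
        mask = self.row(genome_id)
        return {o for o, present in zip(self.observation_ids, mask) if present}

    def column_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0)


def accumulate_scores(
    records: Sequence[AnnotationRecord],
    secreted: set[str],
    genome_id: str | None = None,
    collapse: bool = True,
) -> dict[ObservationId, Fraction]:
    """Sum per-observation scores over one genome's secreted proteins.

    A decisive record adds 1 to its observation; an indecisive record with k
    candidate functions adds 1/k to each.  Proteins outside ``secreted``
    contribute nothing.
    """
    if genome_id is None and records:
        genome_id = records[0].genome_id
    scores: dict[ObservationId, Fraction] = {}
    for rec in records:
        if rec.genome_id != genome_id:
            raise ValueError(
                f"record for genome {rec.genome_id!r} passed to accumulation for {genome_id!r}"
            )
        if rec.protein_id not in secreted:
            continue
        family = collapse_subfamily(rec.family) if collapse else rec.family
        share = Fraction(1, len(rec.functions))
        for func in rec.functions:
            obs = ObservationId(family=family, function=func)
            scores[obs] = scores.get(obs, Fraction(0)) + share
    return scores


def binarize(scores: Mapping[ObservationId, Fraction]) -> set[ObservationId]:
    """Observations with accumulated score >= 1; redundancy collapses to one."""
    present = set()
    for obs, score in scores.items():
        if score < 0:
            raise ValueError(f"negative score for {obs}")
        if score >= 1:
            present.add(obs)
    return present


def build_matrix(
    per_genome_presence: Mapping[str, set[ObservationId]] | Sequence[tuple[str, set[ObservationId]]],
    provenance: Mapping[str, Mapping[ObservationId, Fraction]] | None = None,
) -> ObservationMatrix:
    """Assemble the m x n binary matrix from per-genome presence sets.

    Columns are the union of all presence sets, ordered lexicographically.
    """
    items = list(per_genome_presence.items()) if isinstance(per_genome_presence, Mapping) else list(
        per_genome_presence
    )
    genome_ids = [g for g, _ in items]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome_id")
    if len(genome_ids) < 2:
        raise ValueError("need at least 2 genomes")
    universe = sorted(set().union(*(s for _, s in items)))
    col_index = {obs: j for j, obs in enumerate(universe)}
    cells = np.zeros((len(genome_ids), len(universe)), dtype=bool)
    for i, (_, presence) in enumerate(items):
        for obs in presence:
            cells[i, col_index[obs]] = True
    prov = {g: dict(p) for g, p in provenance.items()} if provenance else {}
    return ObservationMatrix(
        genome_ids=tuple(genome_ids),
        observation_ids=tuple(universe),
        cells=cells,
        provenance=prov,
    )


def filter_singletons(matrix: ObservationMatrix) -> ObservationMatrix:
    """Drop observations found in at most one genome (column sum <= 1)."""
    keep = matrix.column_sums() > 1
    return ObservationMatrix(
        genome_ids=matrix.genome_ids,
        observation_ids=tuple(o for o, k in zip(matrix.observation_ids, keep) if k),
        cells=matrix.cells[:, keep],
        provenance=matrix.provenance,
    )


def genome_presence_sets(
    records: Iterable[AnnotationRecord],
    secreted: set[str],
    collapse: bool = True,
) -> tuple[dict[str, set[ObservationId]], dict[str, dict[ObservationId, Fraction]]]:
    """Group records by genome, accumulate scores and binarize each genome."""
    by_genome: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    presence = {}
    provenance = {}
    for gid, recs in by_genome.items():
        scores = accumulate_scores(recs, secreted, genome_id=gid, collapse=collapse)
        provenance[gid] = scores
        presence[gid] = binarize(scores)
    return presence, provenance
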