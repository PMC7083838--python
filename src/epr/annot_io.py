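"""Readers and writers for the tabular and tree formats the pipeline touches.

All tables are UTF-8, tab-separated, one header row, no quoting.  Multiple
EC numbers inside a single ``functions`` field are joined with ``;``.  The
literal token ``unknown`` marks a protein whose family call carries no EC
assignment (distinct from a partial EC such as ``3.2.1.-``).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from epr.distance import DistanceMatrix
    from epr.grouping import Dendrogram
    from epr.observations import ObservationMatrix

FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)[0-9]+(_[0-9]+)?$")
EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")
UNKNOWN_FUNCTION = "unknown"

_ASSEMBLY_STATUSES = frozenset({"full", "partial"})


class ParseError(ValueError):
    """Raised when an input table violates its dialect."""


def _check_family(token: str, path: Path, lineno: int) -> str:
    if not FAMILY_RE.match(token):
        raise ParseError(f"{path}:{lineno}: malformed family token {token!r}")
    return token


def _check_function(token: str, path: Path, lineno: int) -> str:
    if token != UNKNOWN_FUNCTION and not EC_RE.match(token):
        raise ParseError(f"{path}:{lineno}: malformed EC token {token!r}")
    return token


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein's family + function call.

    ``functions`` holds one EC token (or ``unknown``) for a decisive call,
    or several tokens when the annotation was indecisive between molecular
    functions; ``indecisive`` is true exactly in the latter case.
    """

    genome_id: str
    protein_id: str
    family: str
    functions: tuple[str, ...]
    indecisive: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.functions:
            raise ValueError("functions must be non-empty")
        if not FAMILY_RE.match(self.family):
            raise ValueError(f"malformed family token {self.family!r}")
        for token in self.functions:
            if token != UNKNOWN_FUNCTION and not EC_RE.match(token):
                raise ValueError(f"malformed EC token {token!r}")
        if self.indecisive != (len(self.functions) > 1):
            raise ValueError("indecisive must be true iff more than one function is listed")

    @classmethod
    def make(
        cls, genome_id: str, protein_id: str, family: str, functions: Iterable[str]
    ) -> "AnnotationRecord":
        funcs = tuple(functions)
        return cls(genome_id, protein_id, family, funcs, indecisive=len(funcs) > 1)


@dataclass(frozen=True)
class SecretionCalls:
    """Boolean secretion votes from the three prediction tools."""

    protein_id: str
    calls: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if len(self.calls) != 3:
            raise ValueError(f"expected exactly 3 calls, got {len(self.calls)}")


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    species: str
    section: str
    genus: str
    phylum: str
    assembly_status: str
    habitat: str | None = None

    def __post_init__(self) -> None:
        if self.assembly_status not in _ASSEMBLY_STATUSES:
            raise ValueError(f"assembly_status must be one of {sorted(_ASSEMBLY_STATUSES)}")


def _read_rows(path: Path, required: Sequence[str]) -> tuple[list[str], list[tuple[int, list[str]]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=2) if row]
    missing = [col for col in required if col not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return header, rows


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a per-protein annotation table.

    Columns: ``genome_id``, ``protein_id``, ``family``, ``functions``
    (``;``-joined EC tokens or ``unknown``).
    """
    path = Path(path)
    header, rows = _read_rows(path, ["genome_id", "protein_id", "family", "functions"])
    if not rows:
        raise ParseError(f"{path}: no annotation rows")
    idx = {col: header.index(col) for col in ("genome_id", "protein_id", "family", "functions")}
    records = []
    for lineno, row in rows:
        if len(row) < len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}")
        family = _check_family(row[idx["family"]], path, lineno)
        functions = tuple(
            _check_function(tok, path, lineno) for tok in row[idx["functions"]].split(";")
        )
        records.append(
            AnnotationRecord(
                genome_id=row[idx["genome_id"]],
                protein_id=row[idx["protein_id"]],
                family=family,
                functions=functions,
                indecisive=len(functions) > 1,
            )
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "protein_id", "family", "functions"])
        for rec in records:
            writer.writerow([rec.genome_id, rec.protein_id, rec.family, ";".join(rec.functions)])


def read_secretion_calls(path: str | Path) -> dict[str, SecretionCalls]:
    """Read the three-tool secretion vote table (columns: protein_id + 3 tools)."""
    path = Path(path)
    header, rows = _read_rows(path, ["protein_id"])
    if len(header) != 4:
        raise ParseError(
            f"{path}: expected protein_id plus exactly 3 tool columns, got {len(header) - 1}"
        )
    pid_idx = header.index("protein_id")
    call_idx = [i for i in range(4) if i != pid_idx]
    out: dict[str, SecretionCalls] = {}
    for lineno, row in rows:
        if len(row) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
        pid = row[pid_idx]
        if pid in out:
            raise ParseError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
        calls = []
        for i in call_idx:
            if row[i] not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: call values must be 0 or 1, got {row[i]!r}")
            calls.append(row[i] == "1")
        out[pid] = SecretionCalls(protein_id=pid, calls=tuple(calls))
    return out


def write_secretion_calls(calls: Mapping[str, SecretionCalls], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "tool1", "tool2", "tool3"])
        for pid in calls:
            writer.writerow([pid] + [int(c) for c in calls[pid].calls])


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    path = Path(path)
    required = ["genome_id", "species", "section", "genus", "phylum", "assembly_status"]
    header, rows = _read_rows(path, required)
    has_habitat = "habitat" in header
    idx = {col: header.index(col) for col in required}
    seen: set[str] = set()
    out = []
    for lineno, row in rows:
        if len(row) < len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}")
        gid = row[idx["genome_id"]]
        if gid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate genome_id {gid!r}")
        seen.add(gid)
        out.append(
            GenomeMetadata(
                genome_id=gid,
                species=row[idx["species"]],
                section=row[idx["section"]],
                genus=row[idx["genus"]],
                phylum=row[idx["phylum"]],
                assembly_status=row[idx["assembly_status"]],
                habitat=row[header.index("habitat")] if has_habitat else None,
            )
        )
    return out


def write_metadata(metadata: Iterable[GenomeMetadata], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "species", "section", "genus", "phylum", "assembly_status", "habitat"])
        for m in metadata:
            writer.writerow(
                [m.genome_id, m.species, m.section, m.genus, m.phylum, m.assembly_status, m.habitat or ""]
            )


# ---------------------------------------------------------------------------
# Matrices


def write_matrix(matrix: "ObservationMatrix | DistanceMatrix", path: str | Path) -> None:
    """Write a labeled binary observation matrix or square distance matrix as TSV."""
    from epr.distance import DistanceMatrix
    from epr.observations import ObservationMatrix

    path = Path(path)
    if isinstance(matrix, ObservationMatrix):
        if matrix.cells.size == 0:
            raise ValueError("empty matrix")
        df = pd.DataFrame(
            matrix.cells.astype(int),
            index=list(matrix.genome_ids),
            columns=[str(o) for o in matrix.observation_ids],
        )
        df.to_csv(path, sep="\t", index_label="genome_id")
    elif isinstance(matrix, DistanceMatrix):
        d = np.asarray(matrix.values, dtype=float)
        if d.size == 0:
            raise ValueError("empty matrix")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValueError("distance matrix is asymmetric beyond 1e-12")
        df = pd.DataFrame(d, index=list(matrix.labels), columns=list(matrix.labels))
        df.to_csv(path, sep="\t", index_label="genome_id", float_format="%.17g")
    else:
        raise TypeError(f"unsupported matrix type {type(matrix).__name__}")


def read_observation_matrix(path: str | Path) -> "ObservationMatrix":
    from epr.observations import ObservationId, ObservationMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty matrix")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ParseError(f"{path}: observation matrix cells must be 0/1")
    return ObservationMatrix(
        genome_ids=tuple(str(g) for g in df.index),
        observation_ids=tuple(ObservationId.parse(c) for c in df.columns),
        cells=values.astype(bool),
    )


def read_distance_matrix(path: str | Path) -> "DistanceMatrix":
    from epr.distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty matrix")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: distance matrix must be square with matching labels")
    return DistanceMatrix(labels=tuple(str(g) for g in df.index), values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Newick

_NEWICK_UNSAFE = re.compile(r"[\s(),:;'\[\]]")


def newick_string(dendrogram: "Dendrogram") -> str:
    """Serialize a dendrogram as an ultrametric Newick string.

    Each node sits at elevation ``merge_height / 2`` so that the path length
    between two leaves equals their cophenetic distance (the height of their
    lowest common merge).
    """
    leaves = list(dendrogram.leaves)
    m = len(leaves)
    if m < 2:
        raise ValueError("Newick output requires at least 2 leaves")
    for label in leaves:
        if _NEWICK_UNSAFE.search(label):
            raise ValueError(f"leaf label {label!r} contains Newick metacharacters")

    heights: dict[int, float] = {i: 0.0 for i in range(m)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h) in enumerate(dendrogram.merges):
        if not math.isfinite(h):
            raise ValueError("non-finite merge height")
        node = m + k
        heights[node] = float(h)
        children[node] = (a, b)

    def render(node: int, parent_height: float) -> str:
        branch = (parent_height - heights[node]) / 2.0
        if node < m:
            return f"{leaves[node]}:{branch!r}"
        a, b = children[node]
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{branch!r}"

    root = m + len(dendrogram.merges) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


def write_newick(dendrogram: "Dendrogram", path: str | Path) -> None:
    Path(path).write_text(newick_string(dendrogram) + "\n", encoding="utf-8")
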