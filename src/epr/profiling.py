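"""Section-level profiling of observation matrices.

Per section: total distinct observations (union over members), shared
observations (intersection), observations absent from the section but
present elsewhere in the analysis, the present:absent ratio, and the
derived producer type (I strong / II moderate / III weak).  The
"function overlap" statistic counts distinct EC numbers occurring in more
than one family within a section's union; the ``unknown`` sentinel counts
as a function but is not an EC number and is excluded from overlap.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from epr.annot_io import UNKNOWN_FUNCTION
from epr.observations import ObservationId, ObservationMatrix

CELL_ALL = "all_members"
CELL_SOME = "some_members"
CELL_NONE = "none"


@dataclass(frozen=True)
class SectionSummary:
    section: str
    n_species: int
    total_observations: int
    total_different_functions: int
    function_overlap_between_families: int
    shared_observations: int
    absent_observations: int
    present_absent_ratio: float
    profile_type: str


@dataclass(frozen=True)
class ComparisonTable:
    sections: tuple[str, ...]
    groups: dict[str, tuple[ObservationId, ...]]
    cells: dict[tuple[str, str], str]


def assign_profile_type(ratio: float) -> str:
    """Producer type from the present:absent ratio: <1 III, [1,2] II, >2 I."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if ratio < 1:
        return "III"
    if ratio <= 2:
        return "II"
    return "I"


def _function_stats(union: set[ObservationId], overlap_per_extra_family: bool) -> tuple[int, int]:
    families_per_function: dict[str, set[str]] = {}
    for obs in union:
        families_per_function.setdefault(obs.function, set()).add(obs.family)
    n_functions = len(families_per_function)
    overlap = 0
    for func, fams in families_per_function.items():
        if func == UNKNOWN_FUNCTION or len(fams) < 2:
            continue
        overlap += len(fams) - 1 if overlap_per_extra_family else 1
    return n_functions, overlap


def section_summary(
    matrix: ObservationMatrix,
    members: Mapping[str, Sequence[str]],
    overlap_per_extra_family: bool = False,
) -> list[SectionSummary]:
    """One summary row per section, in ``members`` order."""
    assigned = [g for gids in members.values() for g in gids]
    if len(assigned) != len(set(assigned)):
        raise ValueError("each genome must belong to exactly one section")
    unassigned = set(matrix.genome_ids) - set(assigned)
    if unassigned:
        raise ValueError(f"genomes without a section: {sorted(unassigned)}")
    if len(members) < 2:
        raise ValueError("need at least 2 sections")

    presence = {g: matrix.presence_set(g) for g in matrix.genome_ids}
    global_union: set[ObservationId] = set().union(*presence.values()) if presence else set()
    out = []
    for section, gids in members.items():
        sets = [presence[g] for g in gids]
        union = set().union(*sets)
        shared = set.intersection(*sets)
        absent = global_union - union
        ratio = len(union) / len(absent) if absent else math.inf
        n_functions, overlap = _function_stats(union, overlap_per_extra_family)
        out.append(
            SectionSummary(
                section=section,
                n_species=len(gids),
                total_observations=len(union),
                total_different_functions=n_functions,
                function_overlap_between_families=overlap,
                shared_observations=len(shared),
                absent_observations=len(absent),
                present_absent_ratio=ratio,
                profile_type=assign_profile_type(ratio),
            )
        )
    return out


def shared_across_all(matrix: ObservationMatrix) -> set[ObservationId]:
    """Observations present in every genome of the matrix."""
    if matrix.cells.size == 0:
        raise ValueError("empty matrix")
    full = matrix.cells.all(axis=0)
    return {o for o, f in zip(matrix.observation_ids, full) if f}


def compare_sections(
    matrix: ObservationMatrix,
    members: Mapping[str, Sequence[str]],
    observation_groups: Mapping[str, Sequence[ObservationId]],
) -> ComparisonTable:
    """Classify each (section, observation) as all/some/none of the members."""
    known = set(matrix.observation_ids)
    presence = {g: matrix.presence_set(g) for g in matrix.genome_ids}
    cells: dict[tuple[str, str], str] = {}
    for category, obs_list in observation_groups.items():
        for obs in obs_list:
            if obs not in known:
                raise ValueError(f"unknown observation {obs} in group {category!r}")
            for section, gids in members.items():
                hits = sum(1 for g in gids if obs in presence[g])
                if hits == len(gids):
                    cells[(section, str(obs))] = CELL_ALL
                elif hits == 0:
                    cells[(section, str(obs))] = CELL_NONE
                else:
                    cells[(section, str(obs))] = CELL_SOME
    return ComparisonTable(
        sections=tuple(members),
        groups={c: tuple(obs) for c, obs in observation_groups.items()},
        cells=cells,
    )


def write_section_summaries(summaries: Iterable[SectionSummary], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "section",
                "n_species",
                "total_observations",
                "total_different_functions",
                "function_overlap_between_families",
                "shared_observations",
                "absent_observations",
                "present_absent_ratio",
                "profile_type",
            ]
        )
        for s in summaries:
            ratio = "inf" if math.isinf(s.present_absent_ratio) else f"{s.present_absent_ratio:.6g}"
            writer.writerow(
                [
                    s.section,
                    s.n_species,
                    s.total_observations,
                    s.total_different_functions,
                    s.function_overlap_between_families,
                    s.shared_observations,
                    s.absent_observations,
                    ratio,
                    s.profile_type,
                ]
            )


def write_comparison(table: ComparisonTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "observation", *table.sections])
        for category, obs_list in table.groups.items():
            for obs in obs_list:
                writer.writerow(
                    [category, str(obs)]
                    + [table.cells[(s, str(obs))] for s in table.sections]
                )
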