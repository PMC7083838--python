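"""Consensus secretion calling and genome-level quality filtering.

A protein counts as secreted when at least two of the three prediction
tools vote positive.  Genomes are excluded when (a) the assembly is marked
partial, (b) their genus has fewer than four assemblies in the input set,
(c) they carry fewer than 40 distinct Function;Family observations, or
(d) they are not placed next to at least three congeners in the reference
tree.  Genus counts are taken on the full input set in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

from epr.annot_io import GenomeMetadata, SecretionCalls

REASON_PARTIAL = "partial_assembly"
REASON_GENUS = "genus_lt_4"
REASON_OBS = "obs_lt_40"
REASON_TREE = "tree_placement_fail"

MIN_GENUS_ASSEMBLIES = 4
MIN_OBSERVATIONS = 40


@dataclass(frozen=True)
class GenomeFilterReport:
    genome_id: str
    retained: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.retained != (len(self.reasons) == 0):
            raise ValueError("retained must hold exactly when there are no reasons")


def consensus_secreted(calls: SecretionCalls | Iterable[bool]) -> bool:
    """True iff at least 2 of the 3 tool votes are positive."""
    votes = tuple(calls.calls if isinstance(calls, SecretionCalls) else calls)
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 calls, got {len(votes)}")
    return sum(bool(v) for v in votes) >= 2


def secreted_protein_ids(calls: Mapping[str, SecretionCalls]) -> set[str]:
    return {pid for pid, c in calls.items() if consensus_secreted(c)}


def filter_genomes(
    metadata: Iterable[GenomeMetadata],
    obs_counts: Mapping[str, int],
    tree_flags: Mapping[str, bool] | None = None,
) -> list[GenomeFilterReport]:
    """Apply all exclusion rules independently; every violated rule is listed."""
    meta = list(metadata)
    missing = [m.genome_id for m in meta if m.genome_id not in obs_counts]
    if missing:
        raise ValueError(f"genomes missing from obs_counts: {missing}")
    genus_counts: dict[str, int] = {}
    for m in meta:
        genus_counts[m.genus] = genus_counts.get(m.genus, 0) + 1
    reports = []
    for m in meta:
        reasons = []
        if m.assembly_status == "partial":
            reasons.append(REASON_PARTIAL)
        if genus_counts[m.genus] < MIN_GENUS_ASSEMBLIES:
            reasons.append(REASON_GENUS)
        if obs_counts[m.genome_id] < MIN_OBSERVATIONS:
            reasons.append(REASON_OBS)
        if tree_flags is not None and not tree_flags.get(m.genome_id, True):
            reasons.append(REASON_TREE)
        reports.append(
            GenomeFilterReport(
                genome_id=m.genome_id, retained=not reasons, reasons=tuple(reasons)
            )
        )
    return reports


def tree_placement_check(
    tree: "dendropy.Tree | str | Path", metadata: Iterable[GenomeMetadata]
) -> dict[str, bool]:
    """Flag leaves placed among at least 3 congeners.

    For each leaf, the smallest enclosing clade with >= 4 leaves must contain
    at least 3 OTHER leaves of the same genus.  Polytomies are allowed; if no
    ancestor reaches 4 leaves the root clade is used.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(path=str(tree), schema="newick")
    genus_of = {m.genome_id: m.genus for m in metadata}
    flags: dict[str, bool] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label is None or label not in genus_of:
            raise ValueError(f"tree leaf {label!r} has no metadata entry")
        node = leaf
        while node.parent_node is not None:
            node = node.parent_node
            clade_leaves = node.leaf_nodes()
            if len(clade_leaves) >= 4:
                break
        genus = genus_of[label]
        mates = sum(
            1
            for other in node.leaf_nodes()
            if other is not leaf and genus_of.get(other.taxon.label) == genus
        )
        flags[label] = mates >= 3
    return flags


def write_filter_report(reports: Iterable[GenomeFilterReport], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "retained", "reasons"])
        for r in reports:
            writer.writerow([r.genome_id, int(r.retained), ";".join(r.reasons)])
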