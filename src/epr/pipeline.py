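"""End-to-end convenience: annotation + vote tables -> matrix -> distances."""

from __future__ import annotations

from typing import Iterable, Mapping

from epr.annot_io import AnnotationRecord, SecretionCalls
from epr.distance import DistanceMatrix, distance_matrix
from epr.observations import (
    ObservationMatrix,
    build_matrix,
    filter_singletons,
    genome_presence_sets,
)
from epr.secretome import secreted_protein_ids

PROFILES = ("dikarya", "genus")


def observation_matrix(
    annotations: Iterable[AnnotationRecord],
    secretion_calls: Mapping[str, SecretionCalls],
    profile: str = "genus",
    collapse_subfamily: bool = True,
    include_cbm: bool = True,
) -> ObservationMatrix:
    """Consensus gate, score accumulation, binarization and matrix assembly.

    The singleton-column filter is applied only for the broad "dikarya"
    profile; the within-genus profile keeps every column.
    """
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")
    records = list(annotations)
    if not include_cbm:
        records = [r for r in records if not r.family.startswith("CBM")]
    secreted = secreted_protein_ids(secretion_calls)
    presence, provenance = genome_presence_sets(records, secreted, collapse=collapse_subfamily)
    matrix = build_matrix(presence, provenance=provenance)
    if profile == "dikarya":
        matrix = filter_singletons(matrix)
    return matrix


def epr_distances(
    annotations: Iterable[AnnotationRecord],
    secretion_calls: Mapping[str, SecretionCalls],
    profile: str = "genus",
    **kwargs,
) -> DistanceMatrix:
    return distance_matrix(observation_matrix(annotations, secretion_calls, profile, **kwargs))
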