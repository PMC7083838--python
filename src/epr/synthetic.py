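"""Seeded generator of annotation / secretion / taxonomy tables.

Planted structure: a global core of observations shared by every genome,
one signature block per taxonomic section (signatures are sampled without
overlap, so each section also structurally shares the *absence* of every
other section's block), per-species Bernoulli extras, and optional
Bernoulli presence/absence flip noise.  Each planted presence is realized
as 1-3 protein records; a configurable fraction of records is made
indecisive (two paired half-count calls, so the intended presence still
reaches a full score), and decoy proteins with failing secretion votes
exercise the consensus gate.

Everything is reproducible from ``SyntheticConfig.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from epr.annot_io import (
    UNKNOWN_FUNCTION,
    AnnotationRecord,
    GenomeMetadata,
    SecretionCalls,
    write_annotations,
    write_matrix,
    write_metadata,
    write_secretion_calls,
)
from epr.observations import ObservationId, build_matrix

_POSITIVE_VOTES = ((True, True, False), (True, False, True), (False, True, True), (True, True, True))
_NEGATIVE_VOTES = ((False, False, False), (True, False, False), (False, True, False), (False, False, True))
_HABITATS = ("soil", "wood", "cereal", "fruit", "dung", "compost", "cheese", "leaf litter")

_FAMILY_POOL = tuple(
    [f"GH{i}" for i in range(1, 131)]
    + [f"GT{i}" for i in range(1, 41)]
    + [f"PL{i}" for i in range(1, 31)]
    + [f"CE{i}" for i in range(1, 17)]
    + [f"AA{i}" for i in range(1, 18)]
    + [f"CBM{i}" for i in range(1, 41)]
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_phyla: int = 2
    genera_per_phylum: int = 2
    sections_per_genus: int = 3
    species_per_section: int = 4
    universe_size: int = 295
    core_size: int = 24
    section_signature_size: int = 15
    species_extra_rate: float = 0.02
    noise_flip_prob: float = 0.0
    indecisive_fraction: float = 0.0
    nonsecreted_fraction: float = 0.0
    seed: int = 0

    @property
    def n_sections(self) -> int:
        return self.n_phyla * self.genera_per_phylum * self.sections_per_genus

    @property
    def n_genomes(self) -> int:
        return self.n_sections * self.species_per_section

    def validate(self) -> None:
        for name in ("n_phyla", "genera_per_phylum", "sections_per_genus", "species_per_section"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.core_size < 0 or self.section_signature_size < 0:
            raise ValueError("sizes must be non-negative")
        if self.core_size + self.n_sections * self.section_signature_size > self.universe_size:
            raise ValueError(
                "infeasible: core_size + n_sections * section_signature_size exceeds universe_size"
            )
        for name in (
            "species_extra_rate",
            "noise_flip_prob",
            "indecisive_fraction",
            "nonsecreted_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthTables:
    core: frozenset[ObservationId]
    signatures: dict[str, frozenset[ObservationId]]
    intended: dict[str, frozenset[ObservationId]]
    presence: dict[str, frozenset[ObservationId]]
    sections: dict[str, str]
    genera: dict[str, str]
    phyla: dict[str, str]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    annotations: list[AnnotationRecord]
    secretion_calls: dict[str, SecretionCalls]
    metadata: list[GenomeMetadata]
    truth: TruthTables


def _make_universe(rng: np.random.Generator, size: int) -> list[ObservationId]:
    """Well-formed Family:EC ids; ~10% of ECs live in two families, a few are
    unknown-function observations."""
    obs: list[ObservationId] = []
    seen: set[ObservationId] = set()
    unknown_families: set[str] = set()
    ec_serial = 0
    while len(obs) < size:
        if rng.random() < 0.05:
            fam = str(rng.choice(_FAMILY_POOL))
            if fam in unknown_families:
                continue
            unknown_families.add(fam)
            candidate = ObservationId(family=fam, function=UNKNOWN_FUNCTION)
            if candidate not in seen:
                seen.add(candidate)
                obs.append(candidate)
            continue
        ec_serial += 1
        ec = f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 30))}.{int(rng.integers(1, 30))}.{ec_serial}"
        n_fams = 2 if rng.random() < 0.1 else 1
        fams = rng.choice(len(_FAMILY_POOL), size=n_fams, replace=False)
        for f in fams:
            candidate = ObservationId(family=_FAMILY_POOL[int(f)], function=ec)
            if candidate not in seen and len(obs) < size:
                seen.add(candidate)
                obs.append(candidate)
    return obs


def _partner_ecs() -> Iterator[str]:
    i = 0
    while True:
        i += 1
        yield f"7.7.7.{i}"


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset (annotations, votes, taxonomy, ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = _make_universe(rng, config.universe_size)
    n = config.universe_size

    order = rng.permutation(n)
    core_idx = np.sort(order[: config.core_size])
    sig_slices = [
        np.sort(order[config.core_size + k * config.section_signature_size :
                      config.core_size + (k + 1) * config.section_signature_size])
        for k in range(config.n_sections)
    ]

    # taxonomy scaffold
    metadata: list[GenomeMetadata] = []
    sections: dict[str, str] = {}
    genera: dict[str, str] = {}
    phyla: dict[str, str] = {}
    section_of_idx: list[int] = []
    gid_counter = 0
    section_names: list[str] = []
    for p in range(config.n_phyla):
        phylum = f"Phylum{p + 1}"
        for g in range(config.genera_per_phylum):
            genus = f"Genus{p + 1}_{g + 1}"
            for s in range(config.sections_per_genus):
                section = f"{genus}_sec{s + 1}"
                k = len(section_names)
                section_names.append(section)
                for sp in range(config.species_per_section):
                    gid_counter += 1
                    gid = f"g{gid_counter:04d}"
                    metadata.append(
                        GenomeMetadata(
                            genome_id=gid,
                            species=f"{genus} species {s + 1}-{sp + 1}",
                            section=section,
                            genus=genus,
                            phylum=phylum,
                            assembly_status="full",
                            habitat=str(rng.choice(_HABITATS)),
                        )
                    )
                    sections[gid] = section
                    genera[gid] = genus
                    phyla[gid] = phylum
                    section_of_idx.append(k)

    core_mask = np.zeros(n, dtype=bool)
    core_mask[core_idx] = True
    sig_masks = []
    for idx in sig_slices:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        sig_masks.append(mask)

    intended: dict[str, frozenset[ObservationId]] = {}
    presence: dict[str, frozenset[ObservationId]] = {}
    annotations: list[AnnotationRecord] = []
    secretion_calls: dict[str, SecretionCalls] = {}
    partners = _partner_ecs()

    for m, k in zip(metadata, section_of_idx):
        gid = m.genome_id
        base = core_mask | sig_masks[k]
        extras = (rng.random(n) < config.species_extra_rate) & ~base
        realized = base | extras
        if config.noise_flip_prob > 0:
            flips = rng.random(n) < config.noise_flip_prob
            realized = realized ^ flips
        intended[gid] = frozenset(universe[i] for i in np.flatnonzero(base))
        realized_obs = [universe[i] for i in np.flatnonzero(realized)]
        presence[gid] = frozenset(realized_obs)

        pid_serial = 0
        for obs in realized_obs:
            indecisive = (
                obs.function != UNKNOWN_FUNCTION
                and config.indecisive_fraction > 0
                and rng.random() < config.indecisive_fraction
            )
            if indecisive:
                # two paired half-count calls: the target observation reaches a
                # full score, each decoy partner function stays at 0.5
                for _ in range(2):
                    pid_serial += 1
                    pid = f"{gid}_p{pid_serial:05d}"
                    annotations.append(
                        AnnotationRecord.make(gid, pid, obs.family, [obs.function, next(partners)])
                    )
                    secretion_calls[pid] = SecretionCalls(
                        pid, _POSITIVE_VOTES[int(rng.integers(len(_POSITIVE_VOTES)))]
                    )
            else:
                for _ in range(int(rng.integers(1, 4))):
                    pid_serial += 1
                    pid = f"{gid}_p{pid_serial:05d}"
                    annotations.append(
                        AnnotationRecord.make(gid, pid, obs.family, [obs.function])
                    )
                    secretion_calls[pid] = SecretionCalls(
                        pid, _POSITIVE_VOTES[int(rng.integers(len(_POSITIVE_VOTES)))]
                    )
        n_decoys = int(round(config.nonsecreted_fraction * pid_serial))
        for _ in range(n_decoys):
            pid_serial += 1
            pid = f"{gid}_p{pid_serial:05d}"
            obs = universe[int(rng.integers(n))]
            functions = [obs.function] if obs.function != UNKNOWN_FUNCTION else [UNKNOWN_FUNCTION]
            annotations.append(AnnotationRecord.make(gid, pid, obs.family, functions))
            secretion_calls[pid] = SecretionCalls(
                pid, _NEGATIVE_VOTES[int(rng.integers(len(_NEGATIVE_VOTES)))]
            )

    truth = TruthTables(
        core=frozenset(universe[i] for i in core_idx),
        signatures={
            name: frozenset(universe[i] for i in idx)
            for name, idx in zip(section_names, sig_slices)
        },
        intended=intended,
        presence=presence,
        sections=sections,
        genera=genera,
        phyla=phyla,
    )
    return SyntheticDataset(
        config=config,
        annotations=annotations,
        secretion_calls=secretion_calls,
        metadata=metadata,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Emit annot.tsv, calls.tsv, meta.tsv and the truth/ tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotations(dataset.annotations, out / "annot.tsv")
    write_secretion_calls(dataset.secretion_calls, out / "calls.tsv")
    write_metadata(dataset.metadata, out / "meta.tsv")
    truth_report(dataset, out / "truth")


def truth_report(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the ground-truth presence matrix and taxonomy labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = build_matrix({gid: set(obs) for gid, obs in dataset.truth.presence.items()})
    write_matrix(matrix, out / "presence.tsv")
    import csv

    with open(out / "labels.tsv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "section", "genus", "phylum"])
        for gid in sorted(dataset.truth.sections):
            writer.writerow(
                [gid, dataset.truth.sections[gid], dataset.truth.genera[gid], dataset.truth.phyla[gid]]
            )
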