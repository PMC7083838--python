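from __future__ import annotations

import filecmp

import numpy as np
import pytest

from epr.distance import distance_matrix
from epr.grouping import complete_linkage, congruence, flat_clusters
from epr.observations import build_matrix
from epr.pipeline import observation_matrix
from epr.profiling import shared_across_all
from epr.secretome import consensus_secreted
from epr.synthetic import SyntheticConfig, generate, truth_report, write_dataset


def best_section_ari(dataset):
    matrix = observation_matrix(dataset.annotations, dataset.secretion_calls)
    den = complete_linkage(distance_matrix(matrix))
    heights = sorted({h for _, _, h in den.merges})
    thresholds = [0.0] + [h + 1e-9 for h in heights]
    return max(
        congruence(flat_clusters(den, t), dataset.truth.sections) for t in thresholds
    )


class TestConfig:
    def test_infeasible_sizes_rejected(self):
        cfg = SyntheticConfig(universe_size=50, core_size=24, section_signature_size=15)
        with pytest.raises(ValueError, match="infeasible"):
            cfg.validate()

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="noise_flip_prob"):
            SyntheticConfig(noise_flip_prob=1.5).validate()

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text("seed: 42\nuniverse_size: 100\ncore_size: 10\nsection_signature_size: 5\n")
        cfg = SyntheticConfig.from_yaml(p)
        assert cfg.seed == 42 and cfg.universe_size == 100


class TestGenerate:
    def test_well_formed_universe(self, small_dataset):
        for rec in small_dataset.annotations:
            assert rec.family[0] in "GPCA"  # GH/GT/PL/CE/AA/CBM prefixes

    def test_metadata_consistent_with_truth(self, small_dataset):
        for m in small_dataset.metadata:
            assert small_dataset.truth.sections[m.genome_id] == m.section
            assert small_dataset.truth.genera[m.genome_id] == m.genus
            assert small_dataset.truth.phyla[m.genome_id] == m.phylum

    def test_zero_noise_sections_have_identical_presence(self, clean_dataset):
        by_section: dict[str, list[frozenset]] = {}
        for gid, section in clean_dataset.truth.sections.items():
            by_section.setdefault(section, []).append(clean_dataset.truth.presence[gid])
        for sets in by_section.values():
            assert len(set(sets)) == 1

    def test_zero_noise_within_section_distance_zero(self, clean_dataset):
        matrix = observation_matrix(clean_dataset.annotations, clean_dataset.secretion_calls)
        d = distance_matrix(matrix)
        idx = {g: i for i, g in enumerate(d.labels)}
        for g1, s1 in clean_dataset.truth.sections.items():
            for g2, s2 in clean_dataset.truth.sections.items():
                if s1 == s2:
                    assert d.values[idx[g1], idx[g2]] == 0.0

    def test_round_trip_presence(self, clean_dataset):
        matrix = observation_matrix(clean_dataset.annotations, clean_dataset.secretion_calls)
        for gid in matrix.genome_ids:
            assert matrix.presence_set(gid) == set(clean_dataset.truth.presence[gid])

    def test_round_trip_presence_with_corruption(self, small_dataset):
        # truth.presence records the realized sets, so the round trip holds
        # even with extras switched on
        matrix = observation_matrix(small_dataset.annotations, small_dataset.secretion_calls)
        for gid in matrix.genome_ids:
            assert matrix.presence_set(gid) == set(small_dataset.truth.presence[gid])

    def test_core_recovery_zero_noise(self, clean_dataset):
        matrix = observation_matrix(clean_dataset.annotations, clean_dataset.secretion_calls)
        assert shared_across_all(matrix) == set(clean_dataset.truth.core)

    def test_signatures_disjoint_within_genus(self, small_dataset):
        genus_of_section = {}
        for m in small_dataset.metadata:
            genus_of_section[m.section] = m.genus
        sigs = small_dataset.truth.signatures
        sections = list(sigs)
        for i, s1 in enumerate(sections):
            for s2 in sections[i + 1 :]:
                if genus_of_section[s1] == genus_of_section[s2]:
                    assert not (sigs[s1] & sigs[s2])

    def test_indecisive_pairing_preserves_truth(self):
        cfg = SyntheticConfig(
            n_phyla=1, genera_per_phylum=1, sections_per_genus=2, species_per_section=3,
            universe_size=60, core_size=6, section_signature_size=10,
            species_extra_rate=0.0, indecisive_fraction=0.5, seed=21,
        )
        ds = generate(cfg)
        assert any(rec.indecisive for rec in ds.annotations)
        matrix = observation_matrix(ds.annotations, ds.secretion_calls)
        for gid in matrix.genome_ids:
            assert matrix.presence_set(gid) == set(ds.truth.presence[gid])

    def test_decoys_blocked_by_consensus_gate(self):
        cfg = SyntheticConfig(
            n_phyla=1, genera_per_phylum=1, sections_per_genus=2, species_per_section=3,
            universe_size=60, core_size=6, section_signature_size=10,
            species_extra_rate=0.0, nonsecreted_fraction=0.3, seed=22,
        )
        ds = generate(cfg)
        n_failing = sum(
            1 for c in ds.secretion_calls.values() if not consensus_secreted(c)
        )
        assert n_failing > 0
        matrix = observation_matrix(ds.annotations, ds.secretion_calls)
        for gid in matrix.genome_ids:
            assert matrix.presence_set(gid) == set(ds.truth.presence[gid])

    def test_per_genome_counts_in_configured_band(self, small_dataset):
        cfg = small_dataset.config
        low = cfg.core_size  # noise/extras can only add here (noise off)
        for gid, presence in small_dataset.truth.presence.items():
            assert low <= len(presence) <= cfg.universe_size


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        cfg = SyntheticConfig(
            n_phyla=1, genera_per_phylum=2, sections_per_genus=2, species_per_section=2,
            universe_size=70, core_size=6, section_signature_size=8,
            species_extra_rate=0.05, noise_flip_prob=0.01, indecisive_fraction=0.2,
            nonsecreted_fraction=0.1, seed=77,
        )
        for sub in ("a", "b"):
            write_dataset(generate(cfg), tmp_path / sub)
        for name in ("annot.tsv", "calls.tsv", "meta.tsv", "truth/presence.tsv", "truth/labels.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_different_seeds_differ(self):
        base = SyntheticConfig(universe_size=70, core_size=6, section_signature_size=4,
                               n_phyla=1, genera_per_phylum=1, sections_per_genus=2,
                               species_per_section=2, species_extra_rate=0.05)
        d1 = generate(SyntheticConfig(**{**base.__dict__, "seed": 1}))
        d2 = generate(SyntheticConfig(**{**base.__dict__, "seed": 2}))
        assert d1.truth.presence != d2.truth.presence


class TestRecovery:
    def test_section_recovery_clean(self, clean_dataset):
        assert best_section_ari(clean_dataset) == 1.0

    def test_monotone_degradation_in_noise(self):
        base = dict(
            n_phyla=1, genera_per_phylum=2, sections_per_genus=3, species_per_section=4,
            universe_size=200, core_size=12, section_signature_size=15,
            species_extra_rate=0.02,
        )
        medians = []
        for noise in (0.0, 0.05, 0.2):
            scores = [
                best_section_ari(generate(SyntheticConfig(**base, noise_flip_prob=noise, seed=s)))
                for s in range(6)
            ]
            medians.append(float(np.median(scores)))
        assert medians[0] >= medians[1] >= medians[2]


class TestTruthReport:
    def test_report_round_trip(self, clean_dataset, tmp_path):
        from epr.annot_io import read_observation_matrix

        truth_report(clean_dataset, tmp_path)
        truth_matrix = read_observation_matrix(tmp_path / "presence.tsv")
        pipeline_matrix = observation_matrix(
            clean_dataset.annotations, clean_dataset.secretion_calls
        )
        for gid in pipeline_matrix.genome_ids:
            assert truth_matrix.presence_set(gid) == pipeline_matrix.presence_set(gid)

    def test_labels_match_metadata(self, clean_dataset, tmp_path):
        truth_report(clean_dataset, tmp_path)
        lines = (tmp_path / "labels.tsv").read_text().splitlines()[1:]
        sections = {line.split("\t")[0]: line.split("\t")[1] for line in lines}
        for m in clean_dataset.metadata:
            assert sections[m.genome_id] == m.section
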