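"""Determinism, planted-truth placement and recovery of the generator."""

import numpy as np
import pandas as pd
import pytest

from mirlink.errors import ParameterError, PlacementError
from mirlink.expression import (
    ExpressionMatrix,
    normalize_to_control,
    select_differential,
    summarize_directions,
)
from mirlink.seqio import fasta_bytes
from mirlink.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    default_config,
    gen_expression_timecourse,
    gen_genesets,
    gen_mirnas,
    gen_target_trajectories,
    gen_utrs_with_sites,
)
from mirlink.target_prediction import MatureMiRNA, UTRRecord, scan_sites


class TestConfigValidation:
    def test_up_down_overlap_rejected(self):
        with pytest.raises(ParameterError, match="both up and down"):
            SimulationConfig(planted_up=(("mir-001", 8.0),), planted_down=(("mir-001", 0.2),))

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(noise_sigma=-0.1)

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(timepoints=("control", "d4", "d4"))

    def test_link_strength_bounds(self):
        with pytest.raises(ParameterError):
            SimulationConfig(planted_links=(("mir-001", "gene-001", -1, 1.5),))


class TestGenMirnas:
    def test_count_and_length(self):
        mirnas = gen_mirnas(SimulationConfig(n_mirna=5))
        assert len(mirnas) == 5
        assert all(len(seq) == 22 and set(seq) <= set("ACGU") for _, seq in mirnas)

    def test_seed_determinism_byte_identical(self):
        a = gen_mirnas(SimulationConfig(rng_seed=3))
        b = gen_mirnas(SimulationConfig(rng_seed=3))
        assert fasta_bytes(a) == fasta_bytes(b)

    def test_different_seeds_differ(self):
        a = gen_mirnas(SimulationConfig(rng_seed=1))
        b = gen_mirnas(SimulationConfig(rng_seed=2))
        assert {s for _, s in a} != {s for _, s in b}

    def test_zero_mirnas_rejected(self):
        with pytest.raises(ParameterError):
            gen_mirnas(SimulationConfig(n_mirna=0))


class TestGenUtrs:
    def _cfg(self, **kw):
        base = dict(
            rng_seed=5,
            n_mirna=4,
            n_genes=6,
            utr_length=400,
            planted_sites=(("mir-001", "gene-001", "8mer"), ("mir-002", "gene-002", "7mer-m8")),
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_planted_site_recovered_by_scanner_at_recorded_coords(self):
        cfg = self._cfg()
        mirnas = gen_mirnas(cfg)
        utrs, truth_sites = gen_utrs_with_sites(cfg, mirnas)
        seqs = dict(utrs)
        mirna_map = dict(mirnas)
        for mid, gid, start, end, stype in truth_sites:
            sites = scan_sites(MatureMiRNA(mid, mirna_map[mid]), UTRRecord(gid, seqs[gid]))
            assert (start, end, stype) in {(s.start, s.end, s.site_type) for s in sites}

    def test_clean_background_has_no_unplanted_sites(self):
        cfg = self._cfg(planted_sites=(), clean_background=True)
        mirnas = gen_mirnas(cfg)
        utrs, _ = gen_utrs_with_sites(cfg, mirnas)
        for mid, mseq in mirnas:
            for gid, useq in utrs:
                found = scan_sites(MatureMiRNA(mid, mseq), UTRRecord(gid, useq))
                assert [s for s in found if s.site_type != "6mer"] == []

    def test_clean_background_scanner_finds_exactly_the_plants(self):
        cfg = self._cfg(clean_background=True)
        mirnas = gen_mirnas(cfg)
        utrs, truth_sites = gen_utrs_with_sites(cfg, mirnas)
        mirna_map = dict(mirnas)
        found = set()
        for gid, useq in utrs:
            for mid, mseq in mirnas:
                for s in scan_sites(MatureMiRNA(mid, mseq), UTRRecord(gid, useq)):
                    if s.site_type != "6mer":
                        found.add((mid, gid, s.start, s.end, s.site_type))
        assert found == set(truth_sites)

    def test_same_seed_identical_fasta(self):
        cfg = self._cfg()
        mirnas = gen_mirnas(cfg)
        a, _ = gen_utrs_with_sites(cfg, mirnas)
        b, _ = gen_utrs_with_sites(cfg, mirnas)
        assert fasta_bytes(a) == fasta_bytes(b)

    def test_unplaceable_sites_raise(self):
        many = tuple(("mir-001", "gene-001", "8mer") for _ in range(40))
        cfg = self._cfg(utr_length=60, planted_sites=many)
        mirnas = gen_mirnas(cfg)
        with pytest.raises(PlacementError):
            gen_utrs_with_sites(cfg, mirnas)


class TestExpressionTimecourse:
    def test_noise_free_planted_fold_exact(self):
        cfg = SimulationConfig(
            rng_seed=2, n_mirna=5, noise_sigma=0.0, planted_up=(("mir-001", 8.0),)
        )
        matrix, _ = gen_expression_timecourse(cfg)
        em = ExpressionMatrix(matrix, "control")
        fc = normalize_to_control(em)
        assert fc.loc["mir-001", "d14"] == pytest.approx(8.0)

    def test_noise_free_null_flat(self):
        cfg = SimulationConfig(rng_seed=2, n_mirna=5, noise_sigma=0.0)
        matrix, _ = gen_expression_timecourse(cfg)
        fc = normalize_to_control(ExpressionMatrix(matrix, "control"))
        assert np.allclose(fc.to_numpy(), 1.0)

    def test_truth_sidecar_matches_plants(self):
        cfg = default_config(rng_seed=4)
        _, truth = gen_expression_timecourse(cfg)
        assert truth.differential_up == sorted(m for m, _ in cfg.planted_up)
        assert truth.differential_down == sorted(m for m, _ in cfg.planted_down)

    def test_selection_monte_carlo_sensitivity_and_specificity(self):
        """Planted 8-fold effects among 50 nulls at sigma 0.2: the 5-fold
        filter recovers the plants exactly in >= 95 of 100 seeds."""
        successes = 0
        for seed in range(100):
            cfg = SimulationConfig(
                rng_seed=seed,
                n_mirna=56,
                noise_sigma=0.2,
                planted_up=tuple((f"mir-{i:03d}", 8.0) for i in (1, 2, 3)),
                planted_down=tuple((f"mir-{i:03d}", 0.125) for i in (4, 5, 6)),
            )
            matrix, truth = gen_expression_timecourse(cfg)
            fc = normalize_to_control(ExpressionMatrix(matrix, "control"))
            calls = select_differential(fc, 5.0)
            up = {c.entity_id for c in calls if c.direction == "up"}
            down = {c.entity_id for c in calls if c.direction == "down"}
            if up == set(truth.differential_up) and down == set(truth.differential_down):
                successes += 1
        assert successes >= 95


class TestTargetTrajectories:
    def test_noise_free_planted_link_perfectly_anticorrelated(self):
        cfg = SimulationConfig(
            rng_seed=6,
            n_mirna=3,
            n_genes=4,
            noise_sigma=0.0,
            trajectory_noise_sigma=0.0,
            planted_up=(("mir-001", 8.0),),
            planted_links=(("mir-001", "gene-001", -1, 1.0),),
        )
        matrix, _ = gen_expression_timecourse(cfg)
        trajs = gen_target_trajectories(cfg, matrix)
        fc = normalize_to_control(ExpressionMatrix(matrix, "control"))
        r = np.corrcoef(np.log2(fc.loc["mir-001"]), np.log2(trajs.loc["gene-001"]))[0, 1]
        assert r == pytest.approx(-1.0)

    def test_unlinked_genes_mean_r_near_zero(self):
        rs = []
        for seed in range(200):
            cfg = SimulationConfig(
                rng_seed=seed,
                n_mirna=2,
                n_genes=2,
                planted_up=(("mir-001", 8.0),),
                trajectory_noise_sigma=0.2,
            )
            matrix, _ = gen_expression_timecourse(cfg)
            trajs = gen_target_trajectories(cfg, matrix)
            fc = normalize_to_control(ExpressionMatrix(matrix, "control"))
            rs.append(
                np.corrcoef(np.log2(fc.loc["mir-001"]), np.log2(trajs.loc["gene-002"]))[0, 1]
            )
        assert abs(np.mean(rs)) < 0.1

    def test_same_seed_identical_table(self):
        cfg = default_config(rng_seed=9)
        matrix, _ = gen_expression_timecourse(cfg)
        a = gen_target_trajectories(cfg, matrix)
        b = gen_target_trajectories(cfg, matrix)
        pd.testing.assert_frame_equal(a, b)


class TestGenesets:
    def test_planted_overlap_is_exact(self):
        cfg = default_config(rng_seed=8)
        annotation, pathways, enriched_id = gen_genesets(cfg)
        query = {g for _, g, _ in cfg.planted_sites}
        assert len(pathways[enriched_id] & query) == cfg.enriched_pathway_overlap

    def test_fraction_zero_annotates_nothing(self):
        cfg = default_config(rng_seed=8, annotated_fraction=0.0)
        annotation, _, _ = gen_genesets(cfg)
        from mirlink.annotation_filter import DEFAULT_TERMS

        folded = {t.casefold() for t in DEFAULT_TERMS}
        assert not any(t in folded for t in annotation["term"].str.casefold())

    def test_overlap_exceeding_pathway_size_rejected(self):
        import dataclasses

        bad = dataclasses.replace(
            default_config(rng_seed=8),
            pathway_size_range=(2, 3),
            enriched_pathway_overlap=5,
        )
        with pytest.raises(ParameterError, match="overlap"):
            gen_genesets(bad)

    def test_same_seed_identical_annotation(self):
        cfg = default_config(rng_seed=8)
        a, pa, _ = gen_genesets(cfg)
        b, pb, _ = gen_genesets(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert pa == pb


def test_truth_json_roundtrip(tmp_path):
    truth = GroundTruth(
        differential_up=["mir-001"],
        differential_down=["mir-002"],
        true_sites=[("mir-001", "gene-001", 10, 18, "8mer")],
        true_links=[("mir-001", "gene-001", -1)],
        enriched_pathway="path-01",
    )
    truth.to_json(tmp_path / "truth.json")
    assert GroundTruth.from_json(tmp_path / "truth.json") == truth
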