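"""Synthetic screen generator: determinism, calibration, recovery."""

import numpy as np
import pytest

from folliclescreen.io import write_screen_table
from folliclescreen.scoring import score_screen
from folliclescreen.simulate import (
    CalibrationError,
    GenotypeSpec,
    SimScreenConfig,
    binomial_floor,
    calibrate_tau,
    planted_genotype,
    recovery_experiment,
    simulate_included_screen,
    simulate_screen,
)


def _control_only(n_experiments, seed=0, tau=0.0, **kw):
    return SimScreenConfig(
        genotypes=(GenotypeSpec("nullg"),),
        n_experiments=n_experiments,
        seed=seed,
        tau=tau,
        **kw,
    )


class TestSimulateScreen:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = _control_only(10, seed=42, tau=0.3)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_screen_table(simulate_screen(cfg), p1)
        write_screen_table(simulate_screen(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_screen(_control_only(5, seed=1))
        b = simulate_screen(_control_only(5, seed=2))
        assert a.records != b.records

    def test_well_sizes_within_configured_range(self):
        table = simulate_screen(_control_only(30, seed=3))
        sizes = [r.tally.total() for r in table.records]
        assert min(sizes) >= 20 and max(sizes) <= 30

    def test_every_experiment_carries_its_control(self):
        table = simulate_screen(_control_only(8, seed=4))
        assert table.validate() == []

    def test_no_drug_effect_concentrates_index_at_one(self):
        """With the aspirin response calibrated to equal the vehicle response
        the dumping index has expectation ~1."""
        cfg = _control_only(500, seed=5, aspirin_target=0.92)
        assert cfg.beta_control == pytest.approx(0.0)
        scores = score_screen(simulate_screen(cfg))
        dis = [s.dumping_index for s in scores if s.genotype == "yw"]
        assert np.mean(dis) == pytest.approx(1.0, abs=0.02)

    def test_control_index_expectation_matches_calibration(self):
        """Control calibration 0.92 vehicle / 0.50 aspirin gives a pre-QC
        expected dumping index of about 0.50/0.92 = 0.543."""
        cfg = _control_only(2000, seed=6)
        scores = score_screen(simulate_screen(cfg))
        dis = [s.dumping_index for s in scores if s.genotype == "yw"]
        assert np.mean(dis) == pytest.approx(0.50 / 0.92, abs=0.01)

    def test_pooled_layout_shares_experiments(self):
        cfg = SimScreenConfig(
            genotypes=(GenotypeSpec("a"), GenotypeSpec("b")),
            n_experiments=3,
            seed=7,
            layout="pooled",
        )
        table = simulate_screen(cfg)
        assert len(table.experiment_ids()) == 3
        assert len(table) == 3 * 3 * 2  # 3 experiments x 3 genotypes x 2 wells

    def test_extreme_beta_is_clamped_not_crashing(self):
        cfg = SimScreenConfig(
            genotypes=(GenotypeSpec("extreme", beta=40.0, direction=1),),
            n_experiments=2,
            seed=8,
        )
        table = simulate_screen(cfg)
        mutant_aspirin = [
            r for r in table.records if r.genotype == "extreme" and r.treatment == "aspirin"
        ]
        assert all(r.tally.dumped() == 0 for r in mutant_aspirin)


class TestPlantedGenotype:
    def test_enhancer_direction_and_magnitude(self):
        g = planted_genotype("enh", 0.192)
        assert g.direction == 1
        assert g.beta > 0

    def test_suppressor_direction(self):
        g = planted_genotype("sup", 0.85)
        assert g.direction == -1

    def test_planted_index_recovered_in_expectation(self):
        cfg = SimScreenConfig(
            genotypes=(planted_genotype("enh", 0.192),), n_experiments=800, seed=9
        )
        scores = score_screen(simulate_screen(cfg))
        dis = [s.dumping_index for s in scores if s.genotype == "enh"]
        assert np.mean(dis) == pytest.approx(0.192, abs=0.01)


class TestCalibration:
    def test_floor_reflects_binomial_noise_after_qc_truncation(self):
        floor = binomial_floor(_control_only(1), n_experiments=20000)
        # QC truncation to [0.4, 0.6] caps what 20-30-follicle binomial
        # sampling spreads to; the floor sits a little above 0.05
        assert 0.045 < floor < 0.065

    def test_target_below_floor_is_error(self):
        with pytest.raises(CalibrationError, match="floor"):
            calibrate_tau(0.001, _control_only(1))

    def test_target_above_truncation_ceiling_is_error(self):
        with pytest.raises(CalibrationError, match="ceiling"):
            calibrate_tau(0.5, _control_only(1))

    def test_qc_exclusion_rate_increases_with_tau(self):
        rates = []
        for tau in (0.0, 0.4, 0.8):
            cfg = _control_only(600, seed=10, tau=tau)
            scores = score_screen(simulate_screen(cfg))
            ctl = [s for s in scores if s.genotype == "yw"]
            rates.append(sum(not s.qc_pass for s in ctl) / len(ctl))
        assert rates[0] < rates[1] < rates[2]
        assert rates[0] > 0  # strictly positive even without jitter


class TestBalancedDesignIdentity:
    def test_mean_normalized_equals_difference_of_means(self):
        """With one paired control per experiment, the mean normalized index
        equals mean(DI_genotype) - mean(DI_control) exactly."""
        cfg = SimScreenConfig(
            genotypes=(planted_genotype("enh", 0.3), GenotypeSpec("nullg")),
            n_experiments=6,
            seed=11,
            tau=0.2,
        )
        scores = score_screen(simulate_screen(cfg))
        for genotype in ("enh", "nullg"):
            g_scores = [s for s in scores if s.genotype == genotype]
            exps = {s.experiment_id for s in g_scores}
            c_scores = [
                s for s in scores if s.genotype == "yw" and s.experiment_id in exps
            ]
            lhs = np.mean([s.normalized_index for s in g_scores])
            rhs = np.mean([s.dumping_index for s in g_scores]) - np.mean(
                [s.dumping_index for s in c_scores]
            )
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestRecovery:
    def test_direction_never_inverted_for_planted_effects(self):
        cfg = SimScreenConfig(
            genotypes=(planted_genotype("enh", 0.192), planted_genotype("sup", 0.90)),
            n_experiments=5,
            seed=12,
        )
        rec = recovery_experiment(cfg, 200, seed=13)
        assert rec.calls["enh"]["strong suppressor"] == 0
        assert rec.calls["enh"]["weak suppressor"] == 0
        assert rec.calls["sup"]["strong enhancer"] == 0
        assert rec.rate("enh", "strong enhancer") > 0.9
        assert rec.band_rate("sup", "strong") + rec.band_rate("sup", "weak") > 0.9

    def test_zero_repetitions_empty_matrix(self):
        cfg = SimScreenConfig(genotypes=(GenotypeSpec("g"),), n_experiments=2, seed=1)
        rec = recovery_experiment(cfg, 0)
        assert sum(rec.calls["g"].values()) == 0

    def test_included_screen_has_requested_replicates_all_passing(self):
        cfg = SimScreenConfig(genotypes=(GenotypeSpec("g"),), n_experiments=4, seed=14)
        scores = score_screen(simulate_included_screen(cfg))
        g = [s for s in scores if s.genotype == "g"]
        assert len(g) == 4
        assert all(s.qc_pass for s in g)
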