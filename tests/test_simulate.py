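import math

import numpy as np
import pytest

from ripdecay.decay import make_scanning_panel
from ripdecay.ripqpcr import compute_binding
from ripdecay.seqfeatures import count_overlapping
from ripdecay.simulate import (
    SimulationConfig,
    generate_transcripts,
    simulate_decay_panel,
    simulate_rip_intensities,
    simulate_rip_qpcr,
)


class TestGenerateTranscripts:
    def test_planted_records_carry_motif_copies(self, small_config, small_records):
        planted = [r for r in small_records if r.is_planted_target]
        assert len(planted) == round(
            small_config.n_transcripts * small_config.planted_fraction
        )
        for r in planted:
            assert count_overlapping(r.utr3, small_config.motif) >= small_config.motif_copies
            assert r.planted_motif == small_config.motif

    def test_same_seed_is_byte_identical(self, small_config):
        a = generate_transcripts(small_config)
        b = generate_transcripts(small_config)
        assert [(r.transcript_id, r.sequence, r.cds) for r in a] == [
            (r.transcript_id, r.sequence, r.cds) for r in b
        ]

    def test_gc_content_matches_request(self):
        cfg = SimulationConfig(n_transcripts=300, gc_content=0.4, seed=11)
        records = generate_transcripts(cfg)
        seqs = "".join(r.sequence for r in records)
        gc = (seqs.count("G") + seqs.count("C")) / len(seqs)
        assert abs(gc - 0.40) < 0.02

    def test_motif_too_long_for_utr_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            SimulationConfig(utr_length_range=(10, 20), motif="U" * 11)

    def test_non_acgu_motif_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            SimulationConfig(motif="UUXAA")


class TestRipIntensities:
    def test_neutral_gain_gives_unit_expected_ratio(self, small_records):
        cfg = SimulationConfig(
            n_transcripts=20, binding_gain_per_copy=1.0, noise_cv=0.0, seed=7
        )
        sim = simulate_rip_intensities(small_records, cfg)
        plus = sim.intensities[["ip_plus_1", "ip_plus_2"]].mean(axis=1)
        minus = sim.intensities[["ip_minus_1", "ip_minus_2"]].mean(axis=1)
        assert np.allclose(plus / minus, 1.0)

    def test_noise_free_ratio_is_gain_power_copies(self, small_records):
        cfg = SimulationConfig(n_transcripts=20, noise_cv=0.0, seed=7)
        sim = simulate_rip_intensities(small_records, cfg)
        ratio = sim.intensities["ip_plus_1"] / sim.intensities["ip_minus_1"]
        expected = np.where(
            sim.truth["is_planted_target"], cfg.binding_gain_per_copy ** cfg.motif_copies, 1.0
        )
        assert np.allclose(ratio, expected)

    def test_planted_ratio_monte_carlo_near_closed_form(self, small_records):
        # gain 1.6 with 3 copies -> expected IP+/IP- ratio 1.6^3 ~ 4.1
        cfg = SimulationConfig(n_transcripts=20, noise_cv=0.15, seed=3)
        sim = simulate_rip_intensities(
            small_records, cfg, n_reps_ip_plus=200, n_reps_ip_minus=200
        )
        plus_cols = [c for c in sim.intensities if c.startswith("ip_plus")]
        minus_cols = [c for c in sim.intensities if c.startswith("ip_minus")]
        ratio = sim.intensities[plus_cols].mean(axis=1) / sim.intensities[minus_cols].mean(axis=1)
        planted = sim.truth["is_planted_target"].to_numpy()
        assert np.all(np.abs(ratio[planted] / 1.6 ** 3 - 1) < 0.10)

    def test_truth_table_is_emitted(self, small_records, small_config):
        sim = simulate_rip_intensities(small_records, small_config)
        assert {"abundance", "true_enrichment", "is_planted_target"} <= set(sim.truth.columns)

    def test_requires_two_replicates(self, small_records, small_config):
        with pytest.raises(ValueError, match=">= 2 replicates"):
            simulate_rip_intensities(small_records, small_config, n_reps_ip_plus=1)


class TestDecayPanel:
    def test_noise_free_closed_form(self):
        panel = make_scanning_panel("utr", 100, 1, 0)
        series, truth = simulate_decay_panel(
            400, [], panel, [0, 120], n_pools=1, noise_cv=0.0, seed=0
        )
        # stable reporter: abundance at 120 min = 100 * 2^(-120/400) ~ 81.2%
        assert series[0].abundances[0] == pytest.approx(100.0)
        assert series[0].abundances[1] == pytest.approx(100 * 2 ** (-120 / 400), abs=1e-9)
        assert truth.loc["wt", "t_half"] == pytest.approx(400.0)

    def test_single_deletions_are_intermediate(self):
        # two elements inside scans 1 and 2; deleting one element gives a
        # half-life strictly between the full construct and the empty one
        panel = make_scanning_panel("utr", 100, 1, 2)
        lam_el = 0.004
        elements = [((1, 15), lam_el), ((16, 30), lam_el)]
        _, truth = simulate_decay_panel(
            400, elements, panel, [0, 60, 120], n_pools=1, noise_cv=0.0, seed=0
        )
        full = truth.loc["wt", "t_half"]
        single = truth.loc["scan_1_15", "t_half"]
        assert full < single < 400

    def test_noise_free_curves_start_at_100(self):
        panel = make_scanning_panel("utr", 100, 1, 1)
        series, _ = simulate_decay_panel(
            60, [], panel, [8, 68, 128], n_pools=2, noise_cv=0.0, seed=5
        )
        for s in series:
            assert s.abundances[np.argmin(s.times)] == pytest.approx(100.0)

    def test_deterministic_under_seed(self):
        panel = make_scanning_panel("utr", 100, 1, 1)
        a, _ = simulate_decay_panel(60, [], panel, [0, 60], noise_cv=0.2, seed=9)
        b, _ = simulate_decay_panel(60, [], panel, [0, 60], noise_cv=0.2, seed=9)
        assert all(x.points == y.points for x, y in zip(a, b))

    def test_empty_timepoints_rejected(self):
        panel = make_scanning_panel("utr", 100, 1, 0)
        with pytest.raises(ValueError, match="empty timepoints"):
            simulate_decay_panel(60, [], panel, [], seed=0)

    def test_negative_times_rejected(self):
        panel = make_scanning_panel("utr", 100, 1, 0)
        with pytest.raises(ValueError, match="negative"):
            simulate_decay_panel(60, [], panel, [-5, 60], seed=0)


class TestRipQpcr:
    def test_material_conservation_when_noise_free(self):
        for m in simulate_rip_qpcr(0.3, 0.03, recovery=0.7, noise_cv=0.0, n=3, seed=1):
            assert m.target_pellet + m.target_supernatant == pytest.approx(
                m.target_input * 0.7
            )

    def test_symmetric_bound_fractions_give_unit_enrichment(self):
        for m in simulate_rip_qpcr(0.5, 0.5, noise_cv=0.0, n=2, seed=1):
            assert compute_binding(m).relative_enrichment == pytest.approx(1.0)

    def test_noise_free_enrichment_is_fraction_ratio(self):
        m = simulate_rip_qpcr(0.30, 0.03, noise_cv=0.0, n=1, seed=1)[0]
        assert compute_binding(m).relative_enrichment == pytest.approx(10.0)

    def test_mean_enrichment_recovered_under_noise(self):
        vals = []
        for seed in range(200):
            ms = simulate_rip_qpcr(0.30, 0.03, noise_cv=0.15, n=5, seed=seed)
            vals.append(np.mean([compute_binding(m).relative_enrichment for m in ms]))
        assert abs(np.mean(vals) / 10.0 - 1) < 0.20

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_rip_qpcr(1.5, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_rip_qpcr(0.5, 0.1, recovery=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_rip_qpcr(0.5, 0.1, n=0, seed=0)
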