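"""Simulator contracts: lead algebra, rhythm statistics, class features."""

from dataclasses import replace

import numpy as np
import pytest

from ecgsynth.leads import LEAD_NAMES
from ecgsynth.sim import (
    SimulatorConfig,
    SimulatorConfigError,
    corrupt_record,
    default_presets,
    simulate_cohort,
    simulate_record,
)

from conftest import detect_r_peaks


def normal_config(**overrides) -> SimulatorConfig:
    base = next(p for p in default_presets() if p.label == "normal_sinus_rhythm")
    return replace(base.config, **overrides)


class TestSimulateRecord:
    def test_r_peak_count_matches_heart_rate(self):
        """60 bpm over 10 s must produce 10 ± 1 detectable R peaks."""
        cfg = normal_config(heart_rate_mean=60.0, noise_sd=0.0, seed=3)
        rec = simulate_record(cfg, "s1")
        peaks = detect_r_peaks(rec.leads["II"], cfg.sampling_rate)
        assert abs(len(peaks) - 10) <= 1

    def test_mean_rr_tracks_configured_rate(self):
        cfg = normal_config(heart_rate_mean=80.0, noise_sd=0.0, seed=9, duration=20.0)
        rec = simulate_record(cfg, "s1")
        peaks = detect_r_peaks(rec.leads["II"], cfg.sampling_rate)
        mean_rr = np.mean(np.diff(peaks)) / cfg.sampling_rate
        assert mean_rr == pytest.approx(60.0 / 80.0, rel=0.05)

    @pytest.mark.parametrize("label", [p.label for p in default_presets()])
    def test_limb_lead_identities_exact_when_noiseless(self, label):
        preset = next(p for p in default_presets() if p.label == label)
        cfg = replace(preset.config, noise_sd=0.0, seed=21, duration=2.0, sampling_rate=250.0)
        r = simulate_record(cfg, "s1").leads
        assert np.abs(r["III"] - (r["II"] - r["I"])).max() == 0.0
        assert np.abs(r["aVR"] + (r["I"] + r["II"]) / 2).max() == 0.0
        assert np.abs(r["aVL"] - (r["I"] - r["II"] / 2)).max() == 0.0
        assert np.abs(r["aVF"] - (r["II"] - r["I"] / 2)).max() == 0.0

    def test_deterministic_given_seed(self):
        cfg = normal_config(seed=77, duration=2.0)
        a = simulate_record(cfg, "s1")
        b = simulate_record(cfg, "s1")
        for name in LEAD_NAMES:
            np.testing.assert_array_equal(a.leads[name], b.leads[name])

    def test_frame_count_is_rate_times_duration(self):
        cfg = normal_config(sampling_rate=500.0, duration=10.0)
        assert simulate_record(cfg, "s1").n_frames == 5000

    @pytest.mark.parametrize(
        "bad", [{"heart_rate_mean": 0.0}, {"pr_interval": -5.0}, {"noise_sd": -1.0},
                {"qt_interval": 0.0}, {"duration": 0.0}]
    )
    def test_invalid_config_names_field(self, bad):
        cfg = normal_config(**bad)
        with pytest.raises(SimulatorConfigError, match=next(iter(bad))):
            simulate_record(cfg, "s1")


class TestClassFeatures:
    def test_af_rr_variability_exceeds_normal_and_p_absent(self):
        af = next(p for p in default_presets() if p.label == "atrial_fibrillation")
        nl = next(p for p in default_presets() if p.label == "normal_sinus_rhythm")

        def rr_cv(cfg):
            cfg = replace(cfg, noise_sd=0.0, seed=5, duration=30.0)
            rec = simulate_record(cfg, "s")
            peaks = detect_r_peaks(rec.leads["II"], cfg.sampling_rate)
            rr = np.diff(peaks) / cfg.sampling_rate
            return np.std(rr) / np.mean(rr)

        assert rr_cv(af.config) > rr_cv(nl.config)
        assert af.config.p_wave_amplitude_scale == 0.0

    def test_av_block_p_to_qrs_onset_spacing_exceeds_200ms(self):
        avb = next(p for p in default_presets() if p.label == "first_degree_av_block")
        cfg = replace(avb.config, noise_sd=0.0, seed=2)
        rec = simulate_record(cfg, "s")
        spacing = rec.annotations["qrs_onset_times"] - rec.annotations["p_onset_times"]
        assert (spacing > 0.200).all()
        # and the normal preset stays below the block threshold
        nl = normal_config(noise_sd=0.0, seed=2)
        rec_nl = simulate_record(nl, "s")
        spacing_nl = (
            rec_nl.annotations["qrs_onset_times"] - rec_nl.annotations["p_onset_times"]
        )
        assert (spacing_nl < 0.200).all()

    def test_left_axis_preset_flips_limb_lead_balance(self):
        """At -45° the QRS projects negatively on aVF and strongly on aVL."""
        lad = next(p for p in default_presets() if p.label == "left_axis_deviation")
        cfg = replace(lad.config, noise_sd=0.0, seed=4)
        nl = normal_config(noise_sd=0.0, seed=4)
        r_lad = simulate_record(cfg, "s").leads
        r_nl = simulate_record(nl, "s").leads
        assert r_lad["aVF"].min() < -0.5 * r_lad["aVF"].max()  # dominant negative QRS
        assert r_nl["aVF"].max() > abs(r_nl["aVF"].min())

    def test_presets_unique_and_complete(self, presets):
        assert len(presets) == 6
        assert len({p.label for p in presets}) == 6


class TestSimulateCohort:
    def test_counts_and_unique_subjects(self, presets):
        records = simulate_cohort(presets, 5, seed=1, sampling_rate=125, duration=2)
        assert len(records) == 30
        labels = [r.diagnosis_label for r in records]
        assert all(labels.count(p.label) == 5 for p in presets)
        assert len({r.subject_id for r in records}) == 30

    def test_statement_carries_diagnosis(self, presets):
        records = simulate_cohort(presets[:1], 2, seed=1, sampling_rate=125, duration=2)
        assert records[0].statements == ["Normal sinus rhythm"]

    def test_zero_records_rejected(self, presets):
        with pytest.raises(ValueError):
            simulate_cohort(presets, 0, seed=1)

    def test_duplicate_presets_rejected(self, presets):
        with pytest.raises(SimulatorConfigError, match="duplicate"):
            simulate_cohort([presets[0], presets[0]], 2, seed=1)


class TestCorruptRecord:
    @pytest.fixture()
    def record(self):
        return simulate_record(normal_config(duration=2.0, seed=8), "s1")

    def test_zero_lead_sets_exactly_one_lead_to_zero(self, record):
        out = corrupt_record(record, "zero_lead", seed=3)
        zeroed = [n for n in LEAD_NAMES if (out.leads[n] == 0).all()]
        assert len(zeroed) == 1

    def test_truncate_shortens_all_leads_equally(self, record):
        out = corrupt_record(record, "truncate", seed=3)
        lengths = {len(v) for v in out.leads.values()}
        assert len(lengths) == 1
        assert lengths.pop() < record.n_frames

    def test_bad_statement_appends_exclusion_statement(self, record):
        from ecgsynth.quality import load_rules

        out = corrupt_record(record, "bad_statement", seed=3)
        added = out.statements[-1]
        assert load_rules().match(added) is not None

    def test_unknown_mode_rejected(self, record):
        with pytest.raises(ValueError, match="unknown corruption mode"):
            corrupt_record(record, "scramble", seed=0)

    def test_deterministic(self, record):
        a = corrupt_record(record, "zero_lead", seed=5)
        b = corrupt_record(record, "zero_lead", seed=5)
        for n in LEAD_NAMES:
            np.testing.assert_array_equal(a.leads[n], b.leads[n])
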