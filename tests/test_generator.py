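"""Generator model: pair construction, tiny-set overfitting, determinism,
dataset assembly and its privacy contract."""

import numpy as np
import pytest

from ecgsynth.combos import LeadCombination
from ecgsynth.generator import (
    GeneratorSpec,
    build_training_pairs,
    generate_dataset,
    generate_lead,
    load_generator,
    save_generator,
    train_generator,
)
from ecgsynth.leads import LEAD_NAMES

#: Reduced architecture for fast unit tests (overrides are part of the spec
#: surface and logged in provenance).
TINY = dict(
    bilstm_feature_widths=(8, 8),
    cnn_channels=(8, 8),
    fusion_widths=(8,),
    validation_fraction=0.0,
)


@pytest.fixture(scope="module")
def einthoven_combo():
    return LeadCombination(target="III", inputs=("I", "II", "aVR"), score=0.0)


@pytest.fixture(scope="module")
def pairs(normalized_cohort, einthoven_combo):
    return build_training_pairs(normalized_cohort[:8], einthoven_combo)


class TestBuildTrainingPairs:
    def test_shapes_and_count(self, pairs, normalized_cohort):
        frames = normalized_cohort[0].n_frames
        assert len(pairs) == 8
        for x, y in pairs:
            assert x.shape == (frames, 3)
            assert y.shape == (frames, 1)

    def test_column_order_follows_combo(self, normalized_cohort):
        combo = LeadCombination(target="V1", inputs=("I", "aVR", "V2"), score=0.0)
        (x, _), = build_training_pairs(normalized_cohort[:1], combo)
        np.testing.assert_array_equal(x[:, 0], normalized_cohort[0].leads["I"])
        np.testing.assert_array_equal(x[:, 1], normalized_cohort[0].leads["aVR"])
        np.testing.assert_array_equal(x[:, 2], normalized_cohort[0].leads["V2"])

    def test_empty_list_rejected(self, einthoven_combo):
        with pytest.raises(ValueError, match="empty"):
            build_training_pairs([], einthoven_combo)

    def test_unnormalized_record_rejected(self, noisy_cohort, einthoven_combo):
        with pytest.raises(ValueError, match="not normalized"):
            build_training_pairs(noisy_cohort[:2], einthoven_combo)


class TestTraining:
    def test_overfits_tiny_set(self, pairs, einthoven_combo):
        frames = pairs[0][0].shape[0]
        spec = GeneratorSpec(frames=frames, epochs=25, batch_size=8, seed=1,
                             learning_rate=1e-3, **TINY)
        model = train_generator(pairs, spec, combo=einthoven_combo)
        h = model.history["train_loss"]
        assert h[-1] < 0.5 * h[0]

    def test_deterministic_history_given_seed(self, pairs, einthoven_combo):
        frames = pairs[0][0].shape[0]
        spec = GeneratorSpec(frames=frames, epochs=3, batch_size=4, seed=9, **TINY)
        a = train_generator(pairs, spec, combo=einthoven_combo)
        b = train_generator(pairs, spec, combo=einthoven_combo)
        assert a.history == b.history

    def test_zero_epochs_returns_untrained_flagged(self, pairs, einthoven_combo):
        frames = pairs[0][0].shape[0]
        spec = GeneratorSpec(frames=frames, epochs=0, **TINY)
        model = train_generator(pairs, spec, combo=einthoven_combo)
        assert model.history["train_loss"] == []
        assert model.provenance["trained"] is False

    def test_frames_mismatch_rejected(self, pairs, einthoven_combo):
        spec = GeneratorSpec(frames=64, **TINY)
        with pytest.raises(ValueError, match="frames"):
            train_generator(pairs, spec, combo=einthoven_combo)

    def test_architecture_override_logged(self, pairs, einthoven_combo):
        frames = pairs[0][0].shape[0]
        spec = GeneratorSpec(frames=frames, epochs=1, **TINY)
        model = train_generator(pairs, spec, combo=einthoven_combo)
        assert model.provenance["architecture_default"] is False
        assert GeneratorSpec().is_default_architecture()


class TestInference:
    @pytest.fixture(scope="class")
    def model(self, pairs, einthoven_combo):
        frames = pairs[0][0].shape[0]
        spec = GeneratorSpec(frames=frames, epochs=2, batch_size=8, seed=2, **TINY)
        return train_generator(pairs, spec, combo=einthoven_combo)

    def test_output_in_unit_interval(self, model, pairs):
        out = generate_lead(model, pairs[0][0])
        assert out.shape == (pairs[0][0].shape[0], 1)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_repeated_calls_identical(self, model, pairs):
        a = generate_lead(model, pairs[0][0])
        b = generate_lead(model, pairs[0][0])
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            generate_lead(model, np.zeros((10, 3)))

    def test_save_load_round_trip(self, model, pairs, tmp_path):
        save_generator(model, tmp_path / "gen_III")
        back = load_generator(tmp_path / "gen_III")
        np.testing.assert_array_equal(
            generate_lead(back, pairs[0][0]), generate_lead(model, pairs[0][0])
        )
        assert back.combo.inputs == model.combo.inputs


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def models(self, normalized_cohort):
        frames = normalized_cohort[0].n_frames
        models = {}
        table = {
            name: LeadCombination(
                target=name,
                inputs=tuple(n for n in LEAD_NAMES[:4] if n != name)[:3],
                score=0.0,
            )
            for name in LEAD_NAMES
        }
        for i, name in enumerate(LEAD_NAMES):
            spec = GeneratorSpec(frames=frames, epochs=1, batch_size=8, seed=i, **TINY)
            pairs = build_training_pairs(normalized_cohort[:4], table[name])
            models[name] = train_generator(pairs, spec, combo=table[name])
        return models

    def test_counts_per_label(self, models, normalized_cohort):
        sources = normalized_cohort[:12]
        ds = generate_dataset(models, sources)
        assert len(ds.records) == 12
        assert sum(ds.label_counts().values()) == 12

    def test_privacy_no_subject_no_params(self, models, normalized_cohort):
        ds = generate_dataset(models, normalized_cohort[:3])
        for rec in ds.records:
            assert rec.subject_id is None
            assert "normalization" not in rec.annotations
            assert rec.normalized is True

    def test_samples_in_unit_interval(self, models, normalized_cohort):
        ds = generate_dataset(models, normalized_cohort[:3])
        for rec in ds.records:
            m = rec.lead_matrix()
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_missing_model_rejected(self, models, normalized_cohort):
        incomplete = {k: v for k, v in models.items() if k != "V5"}
        with pytest.raises(ValueError, match="V5"):
            generate_dataset(incomplete, normalized_cohort[:2])

    def test_missing_label_rejected(self, models, normalized_cohort):
        src = [r.copy(diagnosis_label=None) for r in normalized_cohort[:2]]
        with pytest.raises(ValueError, match="label"):
            generate_dataset(models, src)

    def test_provenance_records_source(self, models, normalized_cohort):
        ds = generate_dataset(models, normalized_cohort[:2])
        prov = ds.records[0].annotations["provenance"]
        assert prov["source_record_id"] == normalized_cohort[0].record_id
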