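"""Five-stage pipeline: simulate/ingest → filter → preprocess → train → validate.

``run_pipeline`` wires the stages end to end with deterministic seeding,
per-stage record-count accounting, and disk caching of intermediates keyed
by a hash of the stage-relevant configuration (re-running with the same
config skips completed stages; changing any upstream parameter invalidates
the cache).  The emitted run manifest logs seeds, configs, and per-stage
counts; synthetic outputs never contain subject identifiers or
normalization parameters unless ``include_private`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .combos import ComboTable, select_combinations, reference_table
from .generator import (
    GeneratorSpec,
    SyntheticDataset,
    build_training_pairs,
    generate_dataset,
    load_generator,
    save_generator,
    train_generator,
)
from .preprocess import FilterConfig, preprocess_record, save_params
from .quality import decisions_frame, load_rules, run_filter
from .record_io import read_dataset, write_dataset
from .records import ECGRecord
from .sim import default_presets, simulate_cohort
from .validation import (
    ClassifierSpec,
    ExperimentReport,
    compare_real_vs_synthetic,
    cross_domain_test,
    fit_single_classifier,
    similarity_report,
    train_classifier,
)

logger = logging.getLogger("ecgsynth.pipeline")


@dataclass
class PipelineConfig:
    work_dir: str = "work"
    out_dir: str = "out"
    raw_dir: str | None = None          # ingest instead of simulating if set
    n_per_class: int = 50
    sampling_rate: float = 125.0
    duration: float = 4.0
    noise_sd: float = 8.0
    min_frames: int | None = None       # default: expected frame count
    filter_low: float = 0.05
    filter_high: float = 40.0
    filter_order: int = 4
    combo_source: str = "searched"      # or "reference"
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    gen_train_fraction: float = 0.4     # records reserved for generator training
    normal_label: str = "normal_sinus_rhythm"
    abnormal_label: str = "sinus_bradycardia"
    include_private: bool = False
    seed: int = 0

    @property
    def frames(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def effective_min_frames(self) -> int:
        return self.min_frames if self.min_frames is not None else self.frames


def _hash(obj) -> str:
    def default(o):
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=default).encode()
    ).hexdigest()[:16]


class _StageCache:
    def __init__(self, work_dir: Path):
        self.work_dir = work_dir
        self.events: list[dict] = []

    def run(self, name: str, key: str, compute, save, load):
        stage_dir = self.work_dir / name
        marker = stage_dir / "stage.json"
        if marker.exists():
            meta = json.loads(marker.read_text())
            if meta.get("key") == key:
                logger.info("stage %s: cached (key %s)", name, key)
                self.events.append({"stage": name, "key": key, "cached": True})
                return load(stage_dir)
        logger.info("stage %s: computing (key %s)", name, key)
        result = compute()
        stage_dir.mkdir(parents=True, exist_ok=True)
        save(stage_dir, result)
        marker.write_text(json.dumps({"key": key, "version": __version__}))
        self.events.append({"stage": name, "key": key, "cached": False})
        return result


def _save_records(stage_dir: Path, records: list[ECGRecord]) -> None:
    write_dataset(records, stage_dir / "records")


def _load_records(stage_dir: Path) -> list[ECGRecord]:
    return read_dataset(stage_dir / "records")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full factory; returns the run manifest dictionary."""
    work = Path(config.work_dir)
    out = Path(config.out_dir)
    work.mkdir(parents=True, exist_ok=True)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(work)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "counts": {},
        "stages": cache.events,
    }

    # -- stage 1: simulate or ingest ---------------------------------------
    sim_key = _hash(
        {
            "n": config.n_per_class,
            "rate": config.sampling_rate,
            "dur": config.duration,
            "noise": config.noise_sd,
            "seed": config.seed,
            "raw": config.raw_dir,
        }
    )

    def _simulate():
        if config.raw_dir is not None:
            return read_dataset(config.raw_dir)
        return simulate_cohort(
            default_presets(),
            config.n_per_class,
            seed=config.seed,
            sampling_rate=config.sampling_rate,
            duration=config.duration,
            noise_sd=config.noise_sd,
        )

    raw_records = cache.run("simulate", sim_key, _simulate, _save_records, _load_records)
    manifest["counts"]["raw"] = len(raw_records)

    # -- stage 2: quality filter -------------------------------------------
    filt_key = _hash({"sim": sim_key, "min_frames": config.effective_min_frames()})

    def _filter():
        survivors, decisions = run_filter(
            raw_records, load_rules(), config.effective_min_frames()
        )
        return survivors, decisions

    def _save_filter(stage_dir, result):
        survivors, decisions = result
        _save_records(stage_dir, survivors)
        decisions_frame(decisions).to_csv(stage_dir / "decisions.tsv", sep="\t", index=False)

    def _load_filter(stage_dir):
        return _load_records(stage_dir), None

    clean_records, _decisions = cache.run(
        "filter", filt_key, _filter, _save_filter, _load_filter
    )
    manifest["counts"]["after_filter"] = len(clean_records)
    manifest["counts"]["excluded"] = len(raw_records) - len(clean_records)

    # -- stage 3: preprocess ------------------------------------------------
    pre_key = _hash(
        {
            "filter": filt_key,
            "low": config.filter_low,
            "high": config.filter_high,
            "order": config.filter_order,
        }
    )
    fconfig = FilterConfig(
        low_cutoff=config.filter_low,
        high_cutoff=config.filter_high,
        order=config.filter_order,
    )

    def _preprocess():
        processed, params = [], []
        for r in clean_records:
            p, pr = preprocess_record(r, fconfig)
            processed.append(p)
            params.append(pr)
        return processed, params

    def _save_pre(stage_dir, result):
        processed, params = result
        _save_records(stage_dir, processed)
        save_params(params, stage_dir / "normalization_params.tsv")

    def _load_pre(stage_dir):
        from .preprocess import load_params

        processed = _load_records(stage_dir)
        params = load_params(stage_dir / "normalization_params.tsv")
        return processed, [params[r.record_id] for r in processed]

    norm_records, norm_params = cache.run(
        "preprocess", pre_key, _preprocess, _save_pre, _load_pre
    )
    manifest["counts"]["preprocessed"] = len(norm_records)
    params_by_id = {p.record_id: p for p in norm_params}

    # -- split: generator-training vs source records (per class, by subject)
    rng = np.random.default_rng(config.seed + 1)
    by_label: dict[str, list[ECGRecord]] = {}
    for r in norm_records:
        by_label.setdefault(r.diagnosis_label or "unlabeled", []).append(r)
    gen_train: list[ECGRecord] = []
    sources: list[ECGRecord] = []
    for label in sorted(by_label):
        recs = by_label[label]
        n_train = max(2, int(round(config.gen_train_fraction * len(recs)))) if len(recs) > 4 else max(1, len(recs) // 2)
        idx = rng.permutation(len(recs))
        gen_train.extend(recs[i] for i in idx[:n_train])
        sources.extend(recs[i] for i in idx[n_train:])
    manifest["counts"]["generator_training"] = len(gen_train)
    manifest["counts"]["synthesis_sources"] = len(sources)

    # -- stage 4a: combination search ----------------------------------------
    combo_key = _hash({"pre": pre_key, "source": config.combo_source, "seed": config.seed})

    def _combos():
        if config.combo_source == "reference":
            return reference_table()
        return select_combinations(gen_train)

    def _save_combos(stage_dir, table):
        table.save(stage_dir / "combos.tsv")

    def _load_combos(stage_dir):
        return ComboTable.load(stage_dir / "combos.tsv")

    combo_table = cache.run("combos", combo_key, _combos, _save_combos, _load_combos)

    # -- stage 4b: train the 12 generators -----------------------------------
    gen_key = _hash({"combos": combo_key, "spec": asdict(config.generator)})

    def _train_models():
        models = {}
        for i, lead in enumerate(combo_table.combos):
            combo = combo_table.combos[lead]
            pairs = build_training_pairs(gen_train, combo)
            spec = GeneratorSpec(
                **{
                    **asdict(config.generator),
                    "frames": config.frames,
                    "seed": config.seed * 100 + i,
                }
            )
            models[lead] = train_generator(pairs, spec, combo=combo)
            logger.info(
                "trained generator for %s (final loss %.5f)",
                lead,
                models[lead].history["train_loss"][-1]
                if models[lead].history["train_loss"]
                else float("nan"),
            )
        return models

    def _save_models(stage_dir, models):
        for lead, m in models.items():
            save_generator(m, stage_dir / f"gen_{lead}")

    def _load_models(stage_dir):
        out_models = {}
        for lead in combo_table.combos:
            out_models[lead] = load_generator(stage_dir / f"gen_{lead}")
        return out_models

    models = cache.run("generators", gen_key, _train_models, _save_models, _load_models)

    # -- stage 5: generate the synthetic dataset -----------------------------
    synthetic = generate_dataset(models, sources)
    manifest["counts"]["synthetic"] = len(synthetic.records)
    manifest["counts"]["synthetic_by_label"] = synthetic.label_counts()
    write_dataset(
        synthetic.records,
        out / "synthetic_dataset",
        provenance={"seed": config.seed, "tool_version": __version__},
    )
    if config.include_private:
        save_params(norm_params, out / "normalization_params.tsv")

    # -- validation ----------------------------------------------------------
    sim_table = similarity_report(synthetic.records, sources, params_by_id)
    sim_table.rmse_norm.to_csv(out / "similarity_rmse_normalized.tsv", sep="\t")
    sim_table.cosine.to_csv(out / "similarity_cosine.tsv", sep="\t")
    if sim_table.rmse_uv is not None:
        sim_table.rmse_uv.to_csv(out / "similarity_rmse_uV.tsv", sep="\t")
    manifest["similarity"] = {
        "grand_mean_rmse_normalized": sim_table.grand_mean("rmse_norm"),
        "grand_mean_cosine": sim_table.grand_mean("cosine"),
        "group_means_rmse_normalized": sim_table.group_means("rmse_norm"),
    }
    if sim_table.rmse_uv is not None:
        manifest["similarity"]["grand_mean_rmse_uV"] = sim_table.grand_mean("rmse_uv")

    report = run_classification_experiment(
        real_records=[r for r in sources if r.diagnosis_label in (config.normal_label, config.abnormal_label)],
        synthetic=synthetic,
        config=config,
    )
    report.summary_frame().to_csv(out / "classifier_comparison.tsv", sep="\t", index=False)
    manifest["classification"] = {
        "abnormal_label": config.abnormal_label,
        "real_mean_accuracy": float(report.real_folds["accuracy"].mean()),
        "synthetic_mean_accuracy": float(report.synth_folds["accuracy"].mean()),
        "ttest_min_p": float(min(r.p for r in report.ttests)),
        "cross_domain": report.cross_domain,
    }

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_classification_experiment(
    real_records: list[ECGRecord],
    synthetic: SyntheticDataset,
    config: PipelineConfig,
) -> ExperimentReport:
    """Paired real-vs-synthetic classifier arms plus the cross-domain block."""
    cls_spec = ClassifierSpec(
        **{**asdict(config.classifier), "frames": config.frames, "seed": config.seed}
    )
    normal, abnormal = config.normal_label, config.abnormal_label

    def labelled(records):
        recs = [r for r in records if r.diagnosis_label in (normal, abnormal)]
        y = np.array([1 if r.diagnosis_label == abnormal else 0 for r in recs])
        return recs, y

    real, y_real = labelled(real_records)
    synth, y_synth = labelled(synthetic.records)

    _, real_folds = train_classifier(real, y_real, cls_spec)
    _, synth_folds = train_classifier(synth, y_synth, cls_spec)
    ttests = compare_real_vs_synthetic(real_folds, synth_folds, alpha=0.01)

    # cross-domain: train on synthetic derived from 80% of real subjects,
    # test on the held-out 20% of real records.
    rng = np.random.default_rng(config.seed + 7)
    idx = rng.permutation(len(real))
    n_test = max(1, int(round(0.2 * len(real))))
    test_idx = set(idx[:n_test].tolist())
    held_out = [real[i] for i in sorted(test_idx)]
    held_ids = {r.record_id for r in held_out}
    synth_train = [
        s
        for s in synth
        if s.annotations.get("provenance", {}).get("source_record_id") not in held_ids
    ]
    y_st = np.array([1 if s.diagnosis_label == abnormal else 0 for s in synth_train])
    cross_model = fit_single_classifier(synth_train, y_st, cls_spec, seed=config.seed + 11)
    y_ho = np.array([1 if r.diagnosis_label == abnormal else 0 for r in held_out])
    cross = cross_domain_test(cross_model, held_out, y_ho)

    return ExperimentReport(
        abnormal_label=abnormal,
        real_folds=real_folds,
        synth_folds=synth_folds,
        ttests=ttests,
        cross_domain=cross,
    )
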