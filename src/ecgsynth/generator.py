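"""The 3-lead → 1-lead generation model and synthetic-dataset assembly.

One model is trained per target lead.  Its input is a (frames × 3) matrix of
three real leads (the target's selected combination) on the normalized [0, 1]
scale; its output is the (frames × 1) synthetic target lead.  The network has
two feature branches whose per-frame outputs are concatenated and decoded:

* a temporal branch of four stacked bidirectional LSTM layers with
  per-direction hidden widths 256, 128, 64, 32 (so the concatenated
  bidirectional output of the last layer is 64 wide);
* a spatial branch of four length-preserving 1-D convolutions with channels
  256, 128, 64, 32, each followed by ReLU;
* a fusion head of two further bidirectional LSTM layers and one per-frame
  fully connected layer producing the single output channel.

Training minimizes MSE (RMSE being the fidelity metric of record) with Adam
at learning rate 1e-4.  A full 12-model bank applied to a cohort of source
records yields a SyntheticDataset: normalized 12-lead records that carry the
source's diagnosis label and model provenance but no subject identity and no
normalization parameters — the privacy boundary of the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np

from . import nn
from .combos import LeadCombination
from .leads import LEAD_NAMES
from .records import DIAGNOSIS_STATEMENTS, ECGRecord, make_record


class TrainingDivergenceError(RuntimeError):
    def __init__(self, message: str, history: dict):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture and training settings for one lead-generation model."""

    frames: int = 5000
    bilstm_feature_widths: tuple[int, ...] = (256, 128, 64, 32)
    cnn_channels: tuple[int, ...] = (256, 128, 64, 32)
    fusion_widths: tuple[int, ...] = (32, 32)
    kernel_size: int = 7
    learning_rate: float = 1e-4
    loss: str = "mse"
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0
    validation_fraction: float = 0.2
    early_stopping_patience: int = 5

    def validate(self) -> "GeneratorSpec":
        if self.frames < 16:
            raise ValueError(f"frames must be >= 16, got {self.frames}")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"loss must be 'mse' or 'mae', got {self.loss!r}")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        return self

    def is_default_architecture(self) -> bool:
        d = GeneratorSpec()
        return (
            self.bilstm_feature_widths == d.bilstm_feature_widths
            and self.cnn_channels == d.cnn_channels
            and self.fusion_widths == d.fusion_widths
        )


class GeneratorNet(nn.Layer):
    """Two-branch Bi-LSTM+CNN network; (B, T, 3) -> (B, T, 1)."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        lstm_layers: list[nn.Layer] = []
        width = 3
        for h in spec.bilstm_feature_widths:
            lstm_layers.append(nn.BiLSTM(width, h, rng, dtype=dtype))
            width = 2 * h
        self.branch_lstm = nn.Sequential(lstm_layers)
        self._lstm_out = width

        conv_layers: list[nn.Layer] = []
        cin = 3
        for c in spec.cnn_channels:
            conv_layers.append(nn.Conv1D(cin, c, spec.kernel_size, rng, dtype=dtype))
            conv_layers.append(nn.ReLU())
            cin = c
        self.branch_cnn = nn.Sequential(conv_layers)
        self._cnn_out = cin

        fusion_layers: list[nn.Layer] = []
        width = self._lstm_out + self._cnn_out
        for h in spec.fusion_widths:
            fusion_layers.append(nn.BiLSTM(width, h, rng, dtype=dtype))
            width = 2 * h
        head = nn.Dense(width, 1, rng, dtype=dtype)
        # start the output at the center of the [0, 1] target range so an
        # untrained model is not clipped to a degenerate constant lead
        head.b[:] = 0.5
        fusion_layers.append(head)
        self.fusion = nn.Sequential(fusion_layers)

    def params(self):
        out = {}
        for prefix, sub in (
            ("lstm", self.branch_lstm),
            ("cnn", self.branch_cnn),
            ("fusion", self.fusion),
        ):
            for k, v in sub.params().items():
                out[f"{prefix}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for prefix, sub in (
            ("lstm", self.branch_lstm),
            ("cnn", self.branch_cnn),
            ("fusion", self.fusion),
        ):
            for k, v in sub.grads().items():
                out[f"{prefix}.{k}"] = v
        return out

    def forward(self, x):
        a = self.branch_lstm.forward(x)
        b = self.branch_cnn.forward(x)
        return self.fusion.forward(np.concatenate([a, b], axis=2))

    def backward(self, dy):
        dz = self.fusion.backward(dy)
        da = dz[:, :, : self._lstm_out]
        db = dz[:, :, self._lstm_out :]
        return self.branch_lstm.backward(da) + self.branch_cnn.backward(db)


@dataclass
class TrainedGenerator:
    target: str
    combo: LeadCombination
    spec: GeneratorSpec
    net: GeneratorNet
    history: dict[str, list[float]]
    provenance: dict = field(default_factory=dict)


def build_training_pairs(
    records: list[ECGRecord], combo: LeadCombination
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (frames×3 input, frames×1 target) pair per normalized record.

    Input columns follow ``combo.inputs`` order.
    """
    if not records:
        raise ValueError("empty record list")
    frames = records[0].n_frames
    pairs = []
    for r in records:
        if not r.normalized:
            raise ValueError(f"record {r.record_id!r} is not normalized")
        if r.n_frames != frames:
            raise ValueError(
                f"record {r.record_id!r} has {r.n_frames} frames, expected {frames}"
            )
        x = np.column_stack([r.leads[name] for name in combo.inputs])
        y = r.leads[combo.target].reshape(-1, 1)
        pairs.append((x, y))
    return pairs


def _loss_fn(name: str):
    if name == "mse":
        return nn.mse_loss

    def mae(pred, target):
        diff = pred - target
        return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size

    return mae


def train_generator(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    spec: GeneratorSpec,
    *,
    combo: LeadCombination | None = None,
) -> TrainedGenerator:
    """Train one generation model; deterministic given ``spec.seed``."""
    spec.validate()
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    for x, y in pairs:
        if x.shape != (spec.frames, 3) or y.shape != (spec.frames, 1):
            raise ValueError(
                f"pair shapes {x.shape}/{y.shape} do not match frames={spec.frames}"
            )

    rng = np.random.default_rng(spec.seed)
    net = GeneratorNet(spec, rng)
    X = np.stack([p[0] for p in pairs]).astype(np.float32)
    Y = np.stack([p[1] for p in pairs]).astype(np.float32)

    n = len(pairs)
    n_val = int(round(spec.validation_fraction * n))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order[:0]

    loss_fn = _loss_fn(spec.loss)
    optimizer = nn.Adam(net, learning_rate=spec.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    target = combo.target if combo is not None else "?"
    best_val = np.inf
    stale = 0

    for _ in range(spec.epochs):
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(perm), spec.batch_size):
            sel = train_idx[perm[start : start + spec.batch_size]]
            pred = net.forward(X[sel])
            loss, dpred = loss_fn(pred, Y[sel])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss for target {target}", history
                )
            net.backward(dpred.astype(np.float32))
            optimizer.step()
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if len(val_idx):
            val_pred = net.forward(X[val_idx])
            val_loss, _ = loss_fn(val_pred, Y[val_idx])
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-12:
                best_val, stale = val_loss, 0
            else:
                stale += 1
                if stale >= spec.early_stopping_patience:
                    break

    prov = {
        "seed": spec.seed,
        "n_pairs": n,
        "trained": spec.epochs > 0,
        "architecture_default": spec.is_default_architecture(),
    }
    return TrainedGenerator(
        target=target,
        combo=combo
        if combo is not None
        else LeadCombination(target="I", inputs=("II", "III", "aVR"), score=float("nan")),
        spec=spec,
        net=net,
        history=history,
        provenance=prov,
    )


def generate_lead(model: TrainedGenerator, inputs: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; output clipped to [0, 1], shape frames×1."""
    single = inputs.ndim == 2
    batch = inputs[None] if single else inputs
    if batch.shape[1:] != (model.spec.frames, 3):
        raise ValueError(
            f"input shape {inputs.shape} does not match (frames={model.spec.frames}, 3)"
        )
    out = model.net.forward(batch.astype(np.float32))
    out = np.clip(out.astype(float), 0.0, 1.0)
    return out[0] if single else out


@dataclass
class SyntheticDataset:
    """Per-diagnosis collections of generated normalized records."""

    records_by_label: dict[str, list[ECGRecord]]
    provenance: dict = field(default_factory=dict)

    @property
    def records(self) -> list[ECGRecord]:
        return [r for recs in self.records_by_label.values() for r in recs]

    def label_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.records_by_label.items()}


def generate_dataset(
    models: dict[str, TrainedGenerator],
    source_records: list[ECGRecord],
    *,
    batch_size: int = 32,
) -> SyntheticDataset:
    """Generate one synthetic 12-lead record per source record.

    Every synthetic lead is produced from the source's *real* leads (never
    from previously generated ones).  Output records are anonymous: no
    subject_id, a fixed placeholder timestamp, and no normalization metadata.
    """
    missing = [n for n in LEAD_NAMES if n not in models]
    if missing:
        raise ValueError(f"missing generator model(s) for leads: {missing}")
    for r in source_records:
        if r.diagnosis_label is None:
            raise ValueError(f"source record {r.record_id!r} has no diagnosis label")
        if not r.normalized:
            raise ValueError(f"source record {r.record_id!r} is not normalized")

    n = len(source_records)
    synth_leads: dict[str, np.ndarray] = {}
    for name in LEAD_NAMES:
        model = models[name]
        X = np.stack(
            [
                np.column_stack([r.leads[ln] for ln in model.combo.inputs])
                for r in source_records
            ]
        ).astype(np.float32)
        outs = []
        for start in range(0, n, batch_size):
            outs.append(generate_lead(model, X[start : start + batch_size]))
        synth_leads[name] = np.concatenate(outs, axis=0)[:, :, 0]

    by_label: dict[str, list[ECGRecord]] = {}
    for i, src in enumerate(source_records):
        rec = make_record(
            record_id=f"syn-{i:05d}",
            subject_id=None,
            acquisition_time=datetime(2000, 1, 1),
            sampling_rate=src.sampling_rate,
            leads={name: synth_leads[name][i] for name in LEAD_NAMES},
            statements=[DIAGNOSIS_STATEMENTS.get(src.diagnosis_label, src.diagnosis_label)],
            diagnosis_label=src.diagnosis_label,
            normalized=True,
        )
        rec.annotations["provenance"] = {
            "source_record_id": src.record_id,
            "models": {name: models[name].combo.inputs for name in LEAD_NAMES},
        }
        by_label.setdefault(src.diagnosis_label, []).append(rec)
    return SyntheticDataset(
        records_by_label=by_label,
        provenance={"n_sources": n, "targets": list(LEAD_NAMES)},
    )


def save_generator(model: TrainedGenerator, path: str | Path) -> None:
    """Persist weights (.npz) plus a JSON sidecar with spec and provenance."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.params())
    meta = {
        "target": model.target,
        "combo": {"target": model.combo.target, "inputs": list(model.combo.inputs)},
        "spec": asdict(model.spec),
        "history": model.history,
        "provenance": {
            k: v for k, v in model.provenance.items() if not isinstance(v, np.ndarray)
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_generator(path: str | Path) -> TrainedGenerator:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_dict = dict(meta["spec"])
    for key in ("bilstm_feature_widths", "cnn_channels", "fusion_widths"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = GeneratorSpec(**spec_dict).validate()
    rng = np.random.default_rng(spec.seed)
    net = GeneratorNet(spec, rng)
    stored = np.load(path.with_suffix(".npz"))
    params = net.params()
    for k, v in params.items():
        v[...] = stored[k]
    combo = LeadCombination(
        target=meta["combo"]["target"],
        inputs=tuple(meta["combo"]["inputs"]),
        score=float("nan"),
    )
    return TrainedGenerator(
        target=meta["target"],
        combo=combo,
        spec=spec,
        net=net,
        history=meta["history"],
        provenance=meta["provenance"],
    )
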