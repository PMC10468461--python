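"""Technical validation of a synthetic ECG dataset.

Two complementary checks mirror how synthetic biosignal datasets are vetted:

1. **Signal fidelity** — per-lead RMSE and cosine similarity between each
   synthetic record and its matched source record, aggregated into a
   lead × diagnosis table with lead-group means (standard I–III, extremity
   aVR/aVL/aVF, precordial V1–V6).  RMSE is reported on the normalized [0, 1]
   scale and additionally in µV when the (private) normalization parameters
   are supplied.

2. **Downstream utility** — paired binary classification experiments: the
   same 1-D CNN abnormality classifier is trained once on real records and
   once on synthetic records, each evaluated over five seeded stratified
   6:2:2 train/validation/test splits, and the per-metric fold vectors are
   compared with an independent two-sample t-test (significance level 0.01).
   A cross-domain block tests the synthetic-trained model on held-out real
   records, the decisive check that synthetic data carries real-world signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedShuffleSplit

from . import nn
from .leads import LEAD_GROUPS, LEAD_NAMES
from .preprocess import NormalizationParams, denormalize
from .records import ECGRecord


# ---------------------------------------------------------------------------
# similarity metrics

def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error between two equal-length signals."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos angle between two signals viewed as vectors; in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class SimilarityTable:
    """Lead × diagnosis fidelity grid with means, SDs, and group summaries."""

    rmse_norm: pd.DataFrame        # 12 leads × diagnoses, normalized scale
    cosine: pd.DataFrame           # 12 leads × diagnoses
    rmse_uv: pd.DataFrame | None   # µV scale, present iff params supplied
    n_records: pd.DataFrame        # per-cell record counts

    def lead_means(self, which: str = "rmse_norm") -> pd.Series:
        return getattr(self, which).mean(axis=1)

    def group_means(self, which: str = "rmse_norm") -> dict[str, float]:
        frame = getattr(self, which)
        counts = self.n_records
        out = {}
        for group, leads in LEAD_GROUPS.items():
            vals = frame.loc[list(leads)].to_numpy()
            w = counts.loc[list(leads)].to_numpy()
            out[group] = float((vals * w).sum() / w.sum())
        return out

    def grand_mean(self, which: str = "rmse_norm") -> float:
        vals = getattr(self, which).to_numpy()
        w = self.n_records.to_numpy()
        return float((vals * w).sum() / w.sum())

    def grand_sd(self, which: str = "rmse_norm") -> float:
        # SD across cells weighted by record counts
        vals = getattr(self, which).to_numpy().ravel()
        w = self.n_records.to_numpy().ravel().astype(float)
        mean = (vals * w).sum() / w.sum()
        return float(np.sqrt(((vals - mean) ** 2 * w).sum() / w.sum()))


def similarity_report(
    synthetic: list[ECGRecord],
    reference: list[ECGRecord],
    params: dict[str, NormalizationParams] | None = None,
) -> SimilarityTable:
    """Per-cell mean of per-record metrics; cells are (lead, diagnosis).

    ``synthetic`` and ``reference`` must be matched pairwise (same order,
    same diagnosis per pair).  µV-scale RMSE is computed by denormalizing
    both members of each pair with the reference record's parameters.
    """
    if len(synthetic) != len(reference) or not synthetic:
        raise ValueError(
            f"record lists must be non-empty and matched 1:1 "
            f"({len(synthetic)} vs {len(reference)})"
        )
    labels = []
    for s, r in zip(synthetic, reference):
        if s.diagnosis_label != r.diagnosis_label:
            raise ValueError(
                f"label mismatch: {s.record_id} has {s.diagnosis_label!r}, "
                f"{r.record_id} has {r.diagnosis_label!r}"
            )
        labels.append(r.diagnosis_label)
    diagnoses = list(dict.fromkeys(labels))

    acc_rmse = {d: {n: [] for n in LEAD_NAMES} for d in diagnoses}
    acc_cos = {d: {n: [] for n in LEAD_NAMES} for d in diagnoses}
    acc_uv = {d: {n: [] for n in LEAD_NAMES} for d in diagnoses}
    use_uv = params is not None
    for s, r, d in zip(synthetic, reference, labels):
        s_uv = r_uv = None
        if use_uv:
            p = params.get(r.record_id)
            if p is None:
                raise ValueError(f"no normalization params for {r.record_id!r}")
            s_uv = denormalize(s, p)
            r_uv = denormalize(r, p)
        for name in LEAD_NAMES:
            acc_rmse[d][name].append(rmse(s.leads[name], r.leads[name]))
            acc_cos[d][name].append(cosine_similarity(s.leads[name], r.leads[name]))
            if use_uv:
                acc_uv[d][name].append(rmse(s_uv.leads[name], r_uv.leads[name]))

    def table(acc):
        return pd.DataFrame(
            {d: [float(np.mean(acc[d][n])) for n in LEAD_NAMES] for d in diagnoses},
            index=list(LEAD_NAMES),
        )

    counts = pd.DataFrame(
        {d: [len(acc_rmse[d][n]) for n in LEAD_NAMES] for d in diagnoses},
        index=list(LEAD_NAMES),
    )
    return SimilarityTable(
        rmse_norm=table(acc_rmse),
        cosine=table(acc_cos),
        rmse_uv=table(acc_uv) if use_uv else None,
        n_records=counts,
    )


# ---------------------------------------------------------------------------
# classifier harness

@dataclass(frozen=True)
class ClassifierSpec:
    """1-D CNN binary abnormality classifier over all 12 leads."""

    frames: int = 5000
    conv_channels: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    kernel_size: int = 7
    pool: int = 2
    dense_width: int = 64
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    folds: int = 5
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> "ClassifierSpec":
        if len(self.conv_channels) != 6:
            raise ValueError("classifier uses exactly 6 convolution layers")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        return self


def build_classifier_net(spec: ClassifierSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin, t = 12, spec.frames
    for c in spec.conv_channels:
        layers.append(nn.Conv1D(cin, c, spec.kernel_size, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(spec.pool))
        cin = c
        t = t // spec.pool
    layers.append(nn.Flatten())
    layers.append(nn.Dense(t * cin, spec.dense_width, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(spec.dense_width, 1, rng))
    return nn.Sequential(layers)


@dataclass
class FittedClassifier:
    net: nn.Sequential
    spec: ClassifierSpec
    history: list[float]
    train_subjects: set = field(default_factory=set)
    train_record_ids: set = field(default_factory=set)

    def scores(self, X: np.ndarray) -> np.ndarray:
        logits = []
        for start in range(0, len(X), 64):
            logits.append(self.net.forward(X[start : start + 64].astype(np.float32)))
        return nn.sigmoid(np.concatenate(logits)[:, 0].astype(float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


def records_to_tensor(records: list[ECGRecord]) -> np.ndarray:
    """(n_records, frames, 12) design tensor in canonical lead order."""
    return np.stack([r.lead_matrix() for r in records])


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    seed: int,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> FittedClassifier:
    rng = np.random.default_rng(seed)
    net = build_classifier_net(spec, rng)
    optimizer = nn.Adam(net, learning_rate=spec.learning_rate)
    history = []
    for _ in range(spec.epochs):
        perm = rng.permutation(len(X))
        losses = []
        for start in range(0, len(perm), spec.batch_size):
            sel = perm[start : start + spec.batch_size]
            logits = net.forward(X[sel].astype(np.float32))
            loss, dlogits = nn.bce_with_logits_loss(logits, y[sel].reshape(-1, 1))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite classifier loss (history={history})")
            net.backward(dlogits.astype(np.float32))
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return FittedClassifier(net=net, spec=spec, history=history)


class TrainingError(RuntimeError):
    pass


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "auc": float(roc_auc_score(y_true, scores)) if len(set(y_true)) == 2 else float("nan"),
    }


def train_classifier(
    records: list[ECGRecord],
    labels: np.ndarray,
    spec: ClassifierSpec,
) -> tuple[list[FittedClassifier], pd.DataFrame]:
    """Five seeded stratified 6:2:2 shuffle-splits; metrics per fold.

    Each fold holds out 20% for test, trains on 60% and reserves 20% as
    validation.  Returns the per-fold fitted models and a DataFrame with one
    row per fold (accuracy, precision, recall, f1, auc).
    """
    spec.validate()
    labels = np.asarray(labels, dtype=int)
    if set(labels) != {0, 1}:
        raise ValueError("binary labels 0/1 with both classes present are required")
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 examples per class")
    X = records_to_tensor(records)

    rows = []
    models = []
    for fold in range(spec.folds):
        fold_seed = spec.seed * 1000 + fold
        outer = StratifiedShuffleSplit(
            n_splits=1, test_size=spec.test_fraction, random_state=fold_seed
        )
        (dev_idx, test_idx), = outer.split(X, labels)
        val_share = spec.val_fraction / (spec.train_fraction + spec.val_fraction)
        inner = StratifiedShuffleSplit(
            n_splits=1, test_size=val_share, random_state=fold_seed
        )
        (train_rel, val_rel), = inner.split(X[dev_idx], labels[dev_idx])
        train_idx = dev_idx[train_rel]
        val_idx = dev_idx[val_rel]

        model = _fit(
            X[train_idx], labels[train_idx], spec, fold_seed,
            X[val_idx], labels[val_idx],
        )
        model.train_subjects = {
            records[i].subject_id for i in np.concatenate([train_idx, val_idx])
        } | {records[i].annotations.get("provenance", {}).get("source_record_id")
             for i in np.concatenate([train_idx, val_idx])}
        model.train_subjects.discard(None)
        model.train_record_ids = {records[i].record_id for i in train_idx}
        scores = model.scores(X[test_idx])
        preds = (scores >= 0.5).astype(int)
        rows.append({"fold": fold, **_binary_metrics(labels[test_idx], preds, scores)})
        models.append(model)
    return models, pd.DataFrame(rows)


def fit_single_classifier(
    records: list[ECGRecord],
    labels: np.ndarray,
    spec: ClassifierSpec,
    seed: int,
) -> FittedClassifier:
    """Fit one classifier on all given records (no fold structure)."""
    spec.validate()
    labels = np.asarray(labels, dtype=int)
    model = _fit(records_to_tensor(records), labels, spec, seed)
    model.train_subjects = {r.subject_id for r in records} | {
        r.annotations.get("provenance", {}).get("source_record_id") for r in records
    }
    model.train_subjects.discard(None)
    model.train_record_ids = {r.record_id for r in records}
    return model


METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class TTestResult:
    metric: str
    t: float
    p: float
    significant: bool
    degenerate: bool = False


def compare_real_vs_synthetic(
    real_metrics: pd.DataFrame,
    synth_metrics: pd.DataFrame,
    alpha: float = 0.01,
    *,
    welch: bool = False,
) -> list[TTestResult]:
    """Independent two-sample t-test per metric across fold vectors.

    Student's equal-variance test by default; ``welch=True`` switches to the
    unequal-variance form.  Degenerate zero-variance cases are flagged rather
    than raising.
    """
    if len(real_metrics) != len(synth_metrics) or len(real_metrics) < 2:
        raise ValueError("fold metric tables must have equal length >= 2")
    results = []
    for metric in METRIC_NAMES:
        a = real_metrics[metric].to_numpy(dtype=float)
        b = synth_metrics[metric].to_numpy(dtype=float)
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            if np.allclose(a.mean(), b.mean()):
                results.append(TTestResult(metric, 0.0, 1.0, False, degenerate=True))
            else:
                results.append(
                    TTestResult(metric, float("inf"), 0.0, True, degenerate=True)
                )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        results.append(TTestResult(metric, float(t), float(p), bool(p < alpha)))
    return results


def cross_domain_test(
    model: FittedClassifier,
    real_test: list[ECGRecord],
    labels: np.ndarray,
) -> dict:
    """Evaluate a synthetic-trained classifier on held-out real records.

    Raises if any test record's subject (or provenance source) overlaps the
    classifier's training sources — the subject-level leakage guard.
    """
    labels = np.asarray(labels, dtype=int)
    leaked = sorted(
        r.record_id
        for r in real_test
        if (r.subject_id in model.train_subjects and r.subject_id is not None)
        or r.record_id in model.train_subjects
    )
    if leaked:
        raise ValueError(f"subject leakage between training and test sets: {leaked}")
    X = records_to_tensor(real_test)
    scores = model.scores(X)
    preds = (scores >= 0.5).astype(int)
    return _binary_metrics(labels, preds, scores)


@dataclass
class ExperimentReport:
    """Full paired-arm validation result for one abnormality."""

    abnormal_label: str
    real_folds: pd.DataFrame
    synth_folds: pd.DataFrame
    ttests: list[TTestResult]
    cross_domain: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.ttests:
            rows.append(
                {
                    "metric": res.metric,
                    "real_mean": float(self.real_folds[res.metric].mean()),
                    "synthetic_mean": float(self.synth_folds[res.metric].mean()),
                    "t": res.t,
                    "p": res.p,
                    "significant_at_0.01": res.significant,
                }
            )
        return pd.DataFrame(rows)
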