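"""In-memory containers for 12-lead ECG records and dataset manifests."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Any, Iterable, Mapping

import numpy as np

from .leads import LEAD_NAMES

#: The six diagnosis categories this artifact works with.
DIAGNOSIS_LABELS: tuple[str, ...] = (
    "normal_sinus_rhythm",
    "sinus_bradycardia",
    "left_axis_deviation",
    "atrial_fibrillation",
    "first_degree_av_block",
    "prolonged_qt",
)

#: Vendor-style interpretation statement emitted for each diagnosis category.
DIAGNOSIS_STATEMENTS: dict[str, str] = {
    "normal_sinus_rhythm": "Normal sinus rhythm",
    "sinus_bradycardia": "Sinus bradycardia",
    "left_axis_deviation": "Left axis deviation",
    "atrial_fibrillation": "Atrial fibrillation",
    "first_degree_av_block": "First degree AV block",
    "prolonged_qt": "Prolonged QT interval",
}


class RecordValidationError(ValueError):
    """Raised when an ECGRecord violates its structural invariants."""


@dataclass
class ECGRecord:
    """One subject's 12-lead waveform set with statements and metadata.

    Amplitudes are in µV unless the record has passed min–max normalization,
    in which case they lie in [0, 1] (the ``normalized`` flag tracks this).
    """

    record_id: str
    subject_id: str | None
    acquisition_time: datetime
    vendor: str
    sampling_rate: float
    leads: dict[str, np.ndarray]
    statements: list[str] = field(default_factory=list)
    diagnosis_label: str | None = None
    normalized: bool = False
    #: Optional simulator/provenance bookkeeping; never serialized to disk.
    annotations: dict[str, Any] = field(default_factory=dict, repr=False)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.leads.values())))

    def lead_matrix(self) -> np.ndarray:
        """Stack the 12 leads into an (n_frames, 12) array in canonical order."""
        return np.column_stack([self.leads[name] for name in LEAD_NAMES])

    def validate(self) -> "ECGRecord":
        """Check structural invariants; return self or raise RecordValidationError."""
        names = list(self.leads)
        if names != list(LEAD_NAMES):
            missing = [n for n in LEAD_NAMES if n not in self.leads]
            extra = [n for n in names if n not in LEAD_NAMES]
            raise RecordValidationError(
                f"record {self.record_id!r}: leads must be exactly the 12 canonical "
                f"leads in canonical order (missing={missing}, unexpected={extra})"
            )
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise RecordValidationError(
                f"record {self.record_id!r}: leads have unequal lengths {sorted(lengths)}"
            )
        if not self.sampling_rate > 0:
            raise RecordValidationError(
                f"record {self.record_id!r}: sampling_rate must be > 0, "
                f"got {self.sampling_rate}"
            )
        for name, samples in self.leads.items():
            arr = np.asarray(samples, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise RecordValidationError(
                    f"record {self.record_id!r}: non-finite amplitude in lead {name}"
                )
        return self

    def copy(self, **changes: Any) -> "ECGRecord":
        new = replace(self, **changes)
        if "leads" not in changes:
            new.leads = {k: v.copy() for k, v in self.leads.items()}
        if "annotations" not in changes:
            new.annotations = dict(self.annotations)
        if "statements" not in changes:
            new.statements = list(self.statements)
        return new


def make_record(
    record_id: str,
    subject_id: str | None,
    acquisition_time: datetime,
    sampling_rate: float,
    leads: Mapping[str, np.ndarray],
    *,
    vendor: str = "ecgsynth",
    statements: Iterable[str] = (),
    diagnosis_label: str | None = None,
    normalized: bool = False,
) -> ECGRecord:
    """Build a validated ECGRecord with leads re-ordered to canonical order."""
    ordered = {}
    for name in LEAD_NAMES:
        if name not in leads:
            raise RecordValidationError(
                f"record {record_id!r}: missing lead {name!r}"
            )
        ordered[name] = np.asarray(leads[name], dtype=float)
    extra = set(leads) - set(LEAD_NAMES)
    if extra:
        raise RecordValidationError(
            f"record {record_id!r}: unexpected lead names {sorted(extra)}"
        )
    rec = ECGRecord(
        record_id=record_id,
        subject_id=subject_id,
        acquisition_time=acquisition_time,
        vendor=vendor,
        sampling_rate=float(sampling_rate),
        leads=ordered,
        statements=list(statements),
        diagnosis_label=diagnosis_label,
        normalized=normalized,
    )
    return rec.validate()


@dataclass
class ManifestEntry:
    record_id: str
    subject_id: str | None
    acquisition_time: datetime
    diagnosis_label: str | None
    path: str
    quality_status: str = "unchecked"


@dataclass
class DatasetManifest:
    """Index of a directory of record files plus free-text provenance."""

    entries: list[ManifestEntry]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.record_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValidationError(f"duplicate record_ids in manifest: {dupes}")
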