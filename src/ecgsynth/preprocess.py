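"""Signal conditioning: Butterworth band-pass and invertible min–max scaling.

The band-pass (default 0.05–150 Hz) removes baseline drift from subject
movement and high-frequency muscle/electrode noise while leaving the
ST segment and QRS late potentials intact.  It is realized as a single
second-order-section Butterworth cascade applied forward and backward
(zero net phase, squared magnitude response), which keeps wave morphology
unshifted in time.

Min–max normalization maps each lead to [0, 1].  The per-lead (min, max)
pairs are returned as a separate NormalizationParams object and are never
embedded in emitted records: withholding them is the privacy mechanism that
makes normalized synthetic signals untraceable to original µV amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .leads import LEAD_NAMES
from .records import ECGRecord


class FilterConfigError(ValueError):
    pass


class DegenerateSignalError(ValueError):
    """A lead is constant, so min–max normalization is undefined."""


@dataclass(frozen=True)
class FilterConfig:
    """Band-pass settings; cutoffs in Hz."""

    low_cutoff: float = 0.05
    high_cutoff: float = 150.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> "FilterConfig":
        nyquist = sampling_rate / 2.0
        if not 0 < self.low_cutoff < self.high_cutoff:
            raise FilterConfigError(
                f"need 0 < low_cutoff < high_cutoff, got "
                f"({self.low_cutoff}, {self.high_cutoff})"
            )
        if self.high_cutoff >= nyquist:
            raise FilterConfigError(
                f"high_cutoff {self.high_cutoff} Hz >= Nyquist {nyquist} Hz "
                f"at sampling rate {sampling_rate} Hz"
            )
        if self.order < 1:
            raise FilterConfigError(f"order must be >= 1, got {self.order}")
        return self


def _sos(config: FilterConfig, sampling_rate: float) -> np.ndarray:
    return sps.butter(
        config.order,
        [config.low_cutoff, config.high_cutoff],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass_array(x: np.ndarray, sampling_rate: float, config: FilterConfig) -> np.ndarray:
    """Filter one signal; zero-phase mode uses forward–backward application."""
    config.validate(sampling_rate)
    sos = _sos(config, sampling_rate)
    if config.zero_phase:
        # Reflect padding of one filter length handles edge transients at the
        # very low 0.05 Hz corner.
        padlen = min(len(x) - 1, 3 * (2 * config.order + 1))
        return sps.sosfiltfilt(sos, x, padlen=padlen)
    return sps.sosfilt(sos, x)


def bandpass(record: ECGRecord, config: FilterConfig | None = None) -> ECGRecord:
    """Band-pass every lead independently; output length equals input length."""
    config = config or FilterConfig()
    out = record.copy()
    out.leads = {
        name: bandpass_array(samples, record.sampling_rate, config)
        for name, samples in record.leads.items()
    }
    return out


@dataclass
class NormalizationParams:
    """Per-lead (min, max) in µV recorded at normalization time."""

    record_id: str
    bounds: dict[str, tuple[float, float]]

    def validate(self) -> "NormalizationParams":
        missing = [n for n in LEAD_NAMES if n not in self.bounds]
        if missing:
            raise ValueError(
                f"params for record {self.record_id!r} missing leads {missing}"
            )
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise ValueError(
                    f"record {self.record_id!r} lead {name}: max {hi} <= min {lo}"
                )
        return self


def normalize(
    record: ECGRecord, *, per_record: bool = False
) -> tuple[ECGRecord, NormalizationParams]:
    """Map each lead affinely to [0, 1]; return the scaled record and params.

    Per-lead scaling is the default (each of the 12 signals uses its own
    min/max); ``per_record=True`` uses one global (min, max) over all leads.
    """
    bounds: dict[str, tuple[float, float]] = {}
    if per_record:
        stacked = record.lead_matrix()
        lo, hi = float(stacked.min()), float(stacked.max())
        if not hi > lo:
            raise DegenerateSignalError(
                f"record {record.record_id!r}: all leads constant"
            )
        bounds = {name: (lo, hi) for name in LEAD_NAMES}
    else:
        for name in LEAD_NAMES:
            x = record.leads[name]
            lo, hi = float(x.min()), float(x.max())
            if not hi > lo:
                raise DegenerateSignalError(
                    f"record {record.record_id!r}: lead {name} is constant"
                )
            bounds[name] = (lo, hi)
    out = record.copy()
    out.leads = {
        name: (record.leads[name] - bounds[name][0])
        / (bounds[name][1] - bounds[name][0])
        for name in LEAD_NAMES
    }
    out.normalized = True
    params = NormalizationParams(record_id=record.record_id, bounds=bounds).validate()
    return out, params


def denormalize(record: ECGRecord, params: NormalizationParams) -> ECGRecord:
    """Exact inverse affine map back to µV using the stored per-lead bounds."""
    params.validate()
    out = record.copy()
    out.leads = {
        name: record.leads[name] * (params.bounds[name][1] - params.bounds[name][0])
        + params.bounds[name][0]
        for name in LEAD_NAMES
    }
    out.normalized = False
    return out


def preprocess_record(
    record: ECGRecord, config: FilterConfig | None = None, *, per_record: bool = False
) -> tuple[ECGRecord, NormalizationParams]:
    """Band-pass then normalize, the standard conditioning for model input."""
    return normalize(bandpass(record, config), per_record=per_record)


def params_to_frame(params: list[NormalizationParams]) -> pd.DataFrame:
    rows = [
        {"record_id": p.record_id, "lead": name, "min_uV": lo, "max_uV": hi}
        for p in params
        for name, (lo, hi) in p.bounds.items()
    ]
    return pd.DataFrame(rows, columns=["record_id", "lead", "min_uV", "max_uV"])


def save_params(params: list[NormalizationParams], path: str | Path) -> None:
    params_to_frame(params).to_csv(path, sep="\t", index=False)


def load_params(path: str | Path) -> dict[str, NormalizationParams]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, NormalizationParams] = {}
    for record_id, group in frame.groupby("record_id", sort=False):
        bounds = {
            row["lead"]: (float(row["min_uV"]), float(row["max_uV"]))
            for _, row in group.iterrows()
        }
        out[str(record_id)] = NormalizationParams(str(record_id), bounds).validate()
    return out
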