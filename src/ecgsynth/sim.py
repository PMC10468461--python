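"""Structured 12-lead ECG simulator for six diagnosis classes.

The simulator exists so the whole factory — filtering, preprocessing,
combination search, generation, validation — can be exercised without access
to hospital data.  Each beat is a sum of Gaussian-shaped wavelets (P, Q, R, S,
T) placed on an RR-interval sequence drawn from a configured heart-rate
distribution.  The frontal-plane components are synthesized as a 2-D dipole
and projected onto leads I and II; the remaining four limb leads are then
derived through the exact Einthoven/Goldberger identities, so the limb-lead
algebra holds to machine precision on noiseless output.  Precordial leads use
a fixed anterior-to-lateral weight progression (net-negative QRS in V1 to
net-positive in V6).

Class-defining features are encoded at the signal level:

* sinus bradycardia — low mean heart rate;
* left axis deviation — frontal QRS axis rotated to -45 degrees;
* atrial fibrillation — i.i.d. uniform RR intervals (coefficient of
  variation about 0.2) and absent P waves;
* first-degree AV block — PR interval > 200 ms;
* prolonged QT — long QT interval (wide, late T wave).

The model is deliberately controllable rather than clinically validated: its
purpose is to give downstream stages known ground truth (beat times, exact
lead algebra, separable classes), not to reproduce hospital morphology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta

import numpy as np

from .leads import LEAD_NAMES, PRECORDIAL_LEADS
from .records import DIAGNOSIS_LABELS, DIAGNOSIS_STATEMENTS, ECGRecord, make_record


class SimulatorConfigError(ValueError):
    """Raised when a SimulatorConfig violates one of its invariants."""


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of one simulated recording condition.

    Units: heart rate in beats/min, intervals in ms, amplitudes scale factors
    dimensionless, noise in µV, sampling_rate in Hz, duration in seconds.
    ``rr_irregularity`` is the coefficient of variation of the RR intervals.
    """

    diagnosis_label: str = "normal_sinus_rhythm"
    heart_rate_mean: float = 75.0
    heart_rate_sd: float = 5.0
    rr_irregularity: float = 0.02
    pr_interval: float = 160.0
    qt_interval: float = 400.0
    frontal_axis: float = 60.0
    p_wave_amplitude_scale: float = 1.0
    noise_sd: float = 8.0
    sampling_rate: float = 500.0
    duration: float = 10.0
    seed: int = 0
    #: RR intervals are Gaussian for sinus rhythms; atrial fibrillation uses
    #: i.i.d. uniform draws (irregularly irregular rhythm).
    rr_distribution: str = "gaussian"

    @property
    def n_frames(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def validate(self) -> "SimulatorConfig":
        if self.diagnosis_label not in DIAGNOSIS_LABELS:
            raise SimulatorConfigError(
                f"diagnosis_label: unknown label {self.diagnosis_label!r}"
            )
        if not self.heart_rate_mean > 0:
            raise SimulatorConfigError("heart_rate_mean: must be > 0")
        if not self.pr_interval > 0:
            raise SimulatorConfigError("pr_interval: must be > 0")
        if not self.qt_interval > 0:
            raise SimulatorConfigError("qt_interval: must be > 0")
        if self.noise_sd < 0:
            raise SimulatorConfigError("noise_sd: must be >= 0")
        if not self.sampling_rate > 0:
            raise SimulatorConfigError("sampling_rate: must be > 0")
        if not self.duration > 0:
            raise SimulatorConfigError("duration: must be > 0")
        if self.rr_irregularity < 0:
            raise SimulatorConfigError("rr_irregularity: must be >= 0")
        if self.rr_distribution not in ("gaussian", "uniform"):
            raise SimulatorConfigError(
                f"rr_distribution: unknown mode {self.rr_distribution!r}"
            )
        return self


@dataclass(frozen=True)
class DiagnosisPreset:
    """A diagnosis label bound to its class-characteristic simulator config."""

    label: str
    config: SimulatorConfig


def default_presets() -> list[DiagnosisPreset]:
    """One preset per diagnosis class, mutually distinguishable by design."""
    base = SimulatorConfig()
    table = {
        "normal_sinus_rhythm": base,
        "sinus_bradycardia": replace(base, heart_rate_mean=45.0),
        "left_axis_deviation": replace(base, frontal_axis=-45.0),
        "atrial_fibrillation": replace(
            base,
            heart_rate_mean=95.0,
            rr_irregularity=0.2,
            rr_distribution="uniform",
            p_wave_amplitude_scale=0.0,
        ),
        "first_degree_av_block": replace(base, pr_interval=280.0),
        "prolonged_qt": replace(base, qt_interval=520.0),
    }
    return [
        DiagnosisPreset(label=lbl, config=replace(cfg, diagnosis_label=lbl))
        for lbl, cfg in table.items()
    ]


# Wavelet catalogue: (delay from R center [s], width sigma [s], dipole
# amplitude [µV], frontal orientation mode).  The P delay and T delay are
# overridden per config from pr_interval / qt_interval.  Amplitudes are chosen
# so the R peak on lead II is ~1000 µV at a frontal axis of 60 degrees.
_COMPONENTS = ("P", "Q", "R", "S", "T")
_SIGMA = {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.012, "T": 0.050}
_AMPL = {"P": 150.0, "Q": -100.0, "R": 1000.0, "S": -250.0, "T": 350.0}

# Precordial weight progression (dimensionless multipliers of the component
# amplitude): deep S/small R anteriorly (V1) rotating to dominant R laterally.
_PRECORDIAL_W = {
    "P": [0.5, 0.6, 0.7, 0.8, 0.7, 0.6],
    "Q": [0.0, 0.0, 0.1, 0.2, 0.4, 0.5],
    "R": [0.2, 0.4, 0.8, 1.2, 1.1, 0.9],
    "S": [1.6, 1.4, 1.0, 0.6, 0.35, 0.2],
    "T": [0.3, 0.8, 1.0, 1.0, 0.9, 0.8],
}


def _component_geometry(config: SimulatorConfig) -> dict[str, tuple[float, float, float, float]]:
    """Per-component (delay, sigma, amplitude, frontal angle in degrees)."""
    pr_s = config.pr_interval / 1000.0
    qt_s = config.qt_interval / 1000.0
    axis = config.frontal_axis
    return {
        "P": (-pr_s, _SIGMA["P"], _AMPL["P"] * config.p_wave_amplitude_scale, 60.0),
        "Q": (-0.04, _SIGMA["Q"], _AMPL["Q"], axis),
        "R": (0.0, _SIGMA["R"], _AMPL["R"], axis),
        "S": (0.04, _SIGMA["S"], _AMPL["S"], axis),
        # T center placed so the T wave ends roughly qt after QRS onset.
        "T": (qt_s - 0.12, _SIGMA["T"], _AMPL["T"], axis - 10.0),
    }


def _rr_sequence(config: SimulatorConfig, rng: np.random.Generator) -> np.ndarray:
    """Enough RR intervals to tile the recording, never shorter than 250 ms."""
    mean_rr = 60.0 / config.heart_rate_mean
    n = int(math.ceil(config.duration / mean_rr)) + 4
    if config.rr_distribution == "uniform":
        # uniform on mean*(1 ± sqrt(3)*cv) has coefficient of variation cv
        half = math.sqrt(3.0) * config.rr_irregularity * mean_rr
        rr = rng.uniform(mean_rr - half, mean_rr + half, size=n)
    else:
        rr = rng.normal(mean_rr, config.rr_irregularity * mean_rr, size=n)
    return np.maximum(rr, 0.25)


def simulate_record(
    config: SimulatorConfig,
    subject_id: str,
    *,
    record_id: str | None = None,
    acquisition_time: datetime | None = None,
) -> ECGRecord:
    """Synthesize one 12-lead record; deterministic given ``config.seed``.

    The record's ``annotations`` carry the simulator's wavelet-placement
    bookkeeping (R-peak times, P/QRS onsets) for use as ground truth in tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    t = np.arange(n) / config.sampling_rate

    rr = _rr_sequence(config, rng)
    # Random phase so beats fall anywhere in the window; first beat may be
    # partially clipped, matching real acquisition.
    t0 = rng.uniform(0.15, 0.15 + rr[0])
    beat_times = np.cumsum(np.concatenate([[t0], rr]))
    beat_times = beat_times[beat_times < config.duration + 0.5]

    geometry = _component_geometry(config)
    # Shared per-component time courses: every lead is a linear combination
    # of these, which is what makes limb-lead regression exact.
    courses = {}
    for comp in _COMPONENTS:
        delay, sigma, ampl, _ = geometry[comp]
        if ampl == 0.0:
            courses[comp] = np.zeros(n)
            continue
        u = np.zeros(n)
        for tb in beat_times:
            center = tb + delay
            if center < -0.3 or center > config.duration + 0.3:
                continue
            u += np.exp(-0.5 * ((t - center) / sigma) ** 2)
        courses[comp] = u

    lead_i = np.zeros(n)
    lead_ii = np.zeros(n)
    for comp in _COMPONENTS:
        _, _, ampl, theta = geometry[comp]
        rad = math.radians(theta)
        lead_i += ampl * math.cos(rad) * courses[comp]
        lead_ii += ampl * math.cos(rad - math.radians(60.0)) * courses[comp]

    leads: dict[str, np.ndarray] = {
        "I": lead_i,
        "II": lead_ii,
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }
    for j, name in enumerate(PRECORDIAL_LEADS):
        v = np.zeros(n)
        for comp in _COMPONENTS:
            _, _, ampl, _ = geometry[comp]
            v += ampl * _PRECORDIAL_W[comp][j] * courses[comp]
        leads[name] = v

    if config.noise_sd > 0:
        for name in LEAD_NAMES:
            leads[name] = leads[name] + rng.normal(0.0, config.noise_sd, size=n)

    rec = make_record(
        record_id=record_id or f"rec-{subject_id}",
        subject_id=subject_id,
        acquisition_time=acquisition_time or datetime(2020, 1, 1, 9, 0, 0),
        sampling_rate=config.sampling_rate,
        leads=leads,
        statements=[DIAGNOSIS_STATEMENTS[config.diagnosis_label]],
        diagnosis_label=config.diagnosis_label,
    )
    pr_s = config.pr_interval / 1000.0
    rec.annotations.update(
        {
            "r_peak_times": beat_times,
            # onsets under the wavelet model: two sigma before the center
            "p_onset_times": beat_times - pr_s - 2.0 * _SIGMA["P"],
            "qrs_onset_times": beat_times - 0.04 - 2.0 * _SIGMA["Q"],
            "config": config,
        }
    )
    return rec


def simulate_cohort(
    presets: list[DiagnosisPreset],
    n_per_class: int,
    seed: int,
    *,
    sampling_rate: float | None = None,
    duration: float | None = None,
    noise_sd: float | None = None,
) -> list[ECGRecord]:
    """Simulate ``n_per_class`` subjects per preset with jittered parameters.

    Subject-level variation: heart rate drawn from N(mean, sd); PR, QT and
    axis jittered slightly around the preset.  Optional keyword overrides
    apply one recording condition to every preset (e.g. short records for
    fast tests).
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    labels = [p.label for p in presets]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise SimulatorConfigError(f"duplicate labels in presets: {dupes}")

    master = np.random.default_rng(seed)
    records: list[ECGRecord] = []
    base_time = datetime(2019, 6, 1, 8, 0, 0)
    for preset in presets:
        cfg0 = preset.config
        overrides: dict[str, float] = {}
        if sampling_rate is not None:
            overrides["sampling_rate"] = sampling_rate
        if duration is not None:
            overrides["duration"] = duration
        if noise_sd is not None:
            overrides["noise_sd"] = noise_sd
        for i in range(n_per_class):
            hr = max(25.0, master.normal(cfg0.heart_rate_mean, cfg0.heart_rate_sd))
            pr = max(80.0, cfg0.pr_interval + master.normal(0.0, 8.0))
            if cfg0.pr_interval > 200.0:
                pr = max(pr, 210.0)  # preserve the class-defining block
            qt = max(250.0, cfg0.qt_interval + master.normal(0.0, 12.0))
            if cfg0.qt_interval > 480.0:
                qt = max(qt, 490.0)
            axis = cfg0.frontal_axis + master.normal(0.0, 8.0)
            cfg = replace(
                cfg0,
                heart_rate_mean=hr,
                pr_interval=pr,
                qt_interval=qt,
                frontal_axis=axis,
                seed=int(master.integers(0, 2**31 - 1)),
                **overrides,
            )
            subject = f"S-{preset.label}-{i:04d}"
            records.append(
                simulate_record(
                    cfg,
                    subject_id=subject,
                    record_id=f"R-{preset.label}-{i:04d}",
                    acquisition_time=base_time + timedelta(minutes=len(records)),
                )
            )
    return records


#: Concrete statements from the low-quality / lead-reversal exclusion
#: vocabulary, used to inject statement defects.
_BAD_STATEMENTS = (
    "Poor data quality",
    "Baseline wander",
    "Electrode noise",
    "Right and left arm electrode reversal",
    "Artifact in leads V1, V2",
)

CORRUPTION_MODES = ("zero_lead", "truncate", "bad_statement")


def corrupt_record(record: ECGRecord, mode: str, seed: int) -> ECGRecord:
    """Inject exactly one quality defect; deterministic given seed."""
    rng = np.random.default_rng(seed)
    out = record.copy()
    if mode == "zero_lead":
        lead = LEAD_NAMES[int(rng.integers(0, len(LEAD_NAMES)))]
        out.leads[lead] = np.zeros_like(out.leads[lead])
    elif mode == "truncate":
        n = record.n_frames
        keep = int(rng.integers(int(0.5 * n), int(0.9 * n)))
        out.leads = {k: v[:keep].copy() for k, v in out.leads.items()}
    elif mode == "bad_statement":
        stmt = _BAD_STATEMENTS[int(rng.integers(0, len(_BAD_STATEMENTS)))]
        out.statements = list(record.statements) + [stmt]
    else:
        raise ValueError(
            f"unknown corruption mode {mode!r}; expected one of {CORRUPTION_MODES}"
        )
    return out
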