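"""Reading and writing 12-lead records in a documented ECG-XML dialect.

Vendor ECG XML dialects are proprietary; this package defines its own
minimal, human-readable dialect instead::

    <ecg_record version="1">
      <meta>
        <record_id>R-0001</record_id>
        <subject_id>S-0001</subject_id>            <!-- optional -->
        <acquisition_time>2020-01-01T09:00:00</acquisition_time>
        <vendor>ecgsynth</vendor>
        <sampling_rate unit="Hz">500</sampling_rate>
        <frames>5000</frames>
        <diagnosis_label>normal_sinus_rhythm</diagnosis_label>  <!-- optional -->
        <normalized>false</normalized>
      </meta>
      <statements>
        <statement>Normal sinus rhythm</statement>
      </statements>
      <waveforms unit="uV">
        <lead name="I">12.5 13.0 ...</lead>   <!-- space-separated decimals -->
        ... (exactly 12 leads)
      </waveforms>
    </ecg_record>

Amplitudes are stored as decimal µV with six digits after the point, which
makes writing deterministic (identical records yield identical bytes) and
round-trips exactly at that precision.  Lead order in a file is arbitrary on
read and canonical on write.
"""

from __future__ import annotations

import io
import os
from datetime import datetime
from pathlib import Path
from typing import BinaryIO, Iterable
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .leads import LEAD_NAMES
from .records import (
    DatasetManifest,
    ECGRecord,
    ManifestEntry,
    RecordValidationError,
    make_record,
)


class ECGParseError(ValueError):
    """Raised when an ECG-XML document cannot be parsed into a valid record."""


def _require(parent: ET.Element, tag: str) -> ET.Element:
    el = parent.find(tag)
    if el is None:
        raise ECGParseError(f"missing element <{tag}> under <{parent.tag}>")
    return el


def read_record(source: BinaryIO | str | os.PathLike) -> ECGRecord:
    """Parse one ECG-XML document into a validated ECGRecord.

    Lead order is normalized to canonical order regardless of file order.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise ECGParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "ecg_record":
        raise ECGParseError(f"unexpected root element <{root.tag}>")

    meta = _require(root, "meta")
    record_id = (_require(meta, "record_id").text or "").strip()
    if not record_id:
        raise ECGParseError("empty <record_id>")
    subject_el = meta.find("subject_id")
    subject_id = subject_el.text.strip() if subject_el is not None and subject_el.text else None
    time_text = (_require(meta, "acquisition_time").text or "").strip()
    try:
        acquisition_time = datetime.fromisoformat(time_text)
    except ValueError as exc:
        raise ECGParseError(f"bad <acquisition_time> {time_text!r}: {exc}") from exc
    vendor = (_require(meta, "vendor").text or "").strip()
    rate_text = (_require(meta, "sampling_rate").text or "").strip()
    try:
        sampling_rate = float(rate_text)
    except ValueError as exc:
        raise ECGParseError(f"non-numeric <sampling_rate> {rate_text!r}") from exc
    frames_decl = int((_require(meta, "frames").text or "0").strip())
    label_el = meta.find("diagnosis_label")
    diagnosis_label = (
        label_el.text.strip() if label_el is not None and label_el.text else None
    )
    norm_el = meta.find("normalized")
    normalized = norm_el is not None and (norm_el.text or "").strip() == "true"

    statements: list[str] = []
    st_parent = root.find("statements")
    if st_parent is not None:
        for st in st_parent.findall("statement"):
            statements.append((st.text or "").strip())

    waveforms = _require(root, "waveforms")
    leads: dict[str, np.ndarray] = {}
    for lead_el in waveforms.findall("lead"):
        name = lead_el.get("name")
        if name is None:
            raise ECGParseError("<lead> element without name attribute")
        if name not in LEAD_NAMES:
            raise ECGParseError(f"unknown lead name {name!r}")
        if name in leads:
            raise ECGParseError(f"duplicate lead {name!r}")
        text = lead_el.text or ""
        try:
            samples = np.fromiter((float(x) for x in text.split()), dtype=float)
        except ValueError as exc:
            raise ECGParseError(f"non-numeric sample in lead {name}: {exc}") from exc
        leads[name] = samples
    missing = [n for n in LEAD_NAMES if n not in leads]
    if missing:
        raise ECGParseError(f"missing lead element(s): {missing}")

    lengths = {len(v) for v in leads.values()}
    if len(lengths) != 1:
        raise ECGParseError(f"leads have unequal lengths {sorted(lengths)}")
    n = lengths.pop()
    if frames_decl != n:
        raise ECGParseError(f"declared frames={frames_decl} but leads have {n} samples")

    try:
        return make_record(
            record_id=record_id,
            subject_id=subject_id,
            acquisition_time=acquisition_time,
            sampling_rate=sampling_rate,
            leads=leads,
            vendor=vendor,
            statements=statements,
            diagnosis_label=diagnosis_label,
            normalized=normalized,
        )
    except RecordValidationError as exc:
        raise ECGParseError(str(exc)) from exc


def _format_samples(samples: np.ndarray) -> str:
    return " ".join(f"{x:.6f}" for x in samples)


def write_record(record: ECGRecord, sink: BinaryIO | str | os.PathLike) -> None:
    """Serialize a record deterministically (fixed element order and formats)."""
    record.validate()

    root = ET.Element("ecg_record", attrib={"version": "1"})
    meta = ET.SubElement(root, "meta")
    ET.SubElement(meta, "record_id").text = record.record_id
    if record.subject_id is not None:
        ET.SubElement(meta, "subject_id").text = record.subject_id
    ET.SubElement(meta, "acquisition_time").text = record.acquisition_time.isoformat()
    ET.SubElement(meta, "vendor").text = record.vendor
    rate = record.sampling_rate
    rate_text = f"{int(rate)}" if float(rate).is_integer() else f"{rate:.6f}"
    ET.SubElement(meta, "sampling_rate", attrib={"unit": "Hz"}).text = rate_text
    ET.SubElement(meta, "frames").text = str(record.n_frames)
    if record.diagnosis_label is not None:
        ET.SubElement(meta, "diagnosis_label").text = record.diagnosis_label
    ET.SubElement(meta, "normalized").text = "true" if record.normalized else "false"

    st_parent = ET.SubElement(root, "statements")
    for st in record.statements:
        ET.SubElement(st_parent, "statement").text = st

    unit = "normalized" if record.normalized else "uV"
    waveforms = ET.SubElement(root, "waveforms", attrib={"unit": unit})
    for name in LEAD_NAMES:
        lead_el = ET.SubElement(waveforms, "lead", attrib={"name": name})
        lead_el.text = _format_samples(record.leads[name])

    ET.indent(root, space="  ")
    payload = ET.tostring(root, encoding="utf-8", xml_declaration=True)
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_bytes(payload)
    else:
        sink.write(payload)


def record_to_bytes(record: ECGRecord) -> bytes:
    buf = io.BytesIO()
    write_record(record, buf)
    return buf.getvalue()


def record_from_bytes(payload: bytes) -> ECGRecord:
    return read_record(io.BytesIO(payload))


_MANIFEST_COLUMNS = (
    "record_id",
    "subject_id",
    "acquisition_time",
    "diagnosis_label",
    "path",
    "quality_status",
)


def write_dataset(
    records: Iterable[ECGRecord],
    directory: str | os.PathLike,
    manifest_name: str = "manifest.tsv",
    *,
    provenance: dict | None = None,
) -> DatasetManifest:
    """Write one XML file per record plus a TSV manifest; atomic on id clashes."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty dataset")
    ids = [r.record_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise RecordValidationError(f"duplicate record_ids: {dupes}")
    for r in records:
        r.validate()  # fail before any file is written

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    for r in records:
        fname = f"{r.record_id}.xml"
        write_record(r, directory / fname)
        entries.append(
            ManifestEntry(
                record_id=r.record_id,
                subject_id=r.subject_id,
                acquisition_time=r.acquisition_time,
                diagnosis_label=r.diagnosis_label,
                path=fname,
                quality_status="unchecked",
            )
        )
    manifest = DatasetManifest(entries=entries, provenance=dict(provenance or {}))
    frame = pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "subject_id": e.subject_id if e.subject_id is not None else "",
                "acquisition_time": e.acquisition_time.isoformat(),
                "diagnosis_label": e.diagnosis_label or "",
                "path": e.path,
                "quality_status": e.quality_status,
            }
            for e in entries
        ],
        columns=list(_MANIFEST_COLUMNS),
    )
    frame.to_csv(directory / manifest_name, sep="\t", index=False)
    return manifest


def read_dataset(directory: str | os.PathLike, manifest_name: str = "manifest.tsv") -> list[ECGRecord]:
    """Load every record listed in a dataset manifest."""
    directory = Path(directory)
    frame = pd.read_csv(directory / manifest_name, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in frame.iterrows():
        records.append(read_record(directory / row["path"]))
    return records
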