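"""Record types and readers/writers for note corpora, observations, and labels.

The note corpus is JSONL (one note object per line); observations, reference
labels, and the status table are UTF-8 CSV with a header row.  Dates are
ISO-8601 calendar dates: PAC logic is day-granular, so note timestamps are
truncated to dates.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "CorpusFormatError",
    "Section",
    "ClinicalNote",
    "StructuredObservation",
    "PatientRecord",
    "read_corpus",
    "read_observations",
    "attach_observations",
    "read_reference_labels",
    "write_status_table",
    "read_status_table",
    "OBSERVATION_KINDS",
    "NUMERIC_KINDS",
    "PERCENT_PREDICTED_KINDS",
]


class CorpusFormatError(ValueError):
    """Raised when an input file violates the corpus/observation contracts."""


#: observation kinds carrying a plain numeric value
PERCENT_PREDICTED_KINDS = frozenset(
    {"fev1_pct_pred", "fvc_pct_pred", "fev1_post_bd_pct_pred"}
)
NUMERIC_KINDS = PERCENT_PREDICTED_KINDS | {
    "eosinophil_count",       # cells/uL
    "igg",                    # mg/mL
    "fev1_bd_improvement",    # percent improvement after bronchodilator
    "methacholine_fev1_decline",  # percent decline on challenge
}
SMOKING_LEVELS = ("never", "current", "former", "unknown")
CATEGORICAL_KINDS = {
    "diffusion_capacity": ("normal", "diminished"),
    "smoking_status": SMOKING_LEVELS,
}
#: serum IgE may arrive either as an elevated/normal flag or as a numeric kU/L value
OBSERVATION_KINDS = frozenset(NUMERIC_KINDS) | frozenset(CATEGORICAL_KINDS) | {"serum_ige"}


@dataclass(frozen=True)
class Section:
    """A labelled half-open character span ``[start, end)`` of a note."""

    label: str
    start: int
    end: int


@dataclass
class ClinicalNote:
    """One dated free-text document for one patient, optionally pre-sectioned."""

    patient_id: str
    note_id: str
    note_date: dt.date
    text: str
    provider_type: Optional[str] = None
    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.note_date, dt.date):
            raise CorpusFormatError(f"note {self.note_id}: note_date must be a date")
        prev_end = 0
        for sec in self.sections:
            if not (0 <= sec.start < sec.end <= len(self.text)):
                raise CorpusFormatError(
                    f"note {self.note_id}: section {sec.label} out of bounds"
                )
            if sec.start < prev_end:
                raise CorpusFormatError(
                    f"note {self.note_id}: overlapping/unordered sections"
                )
            prev_end = sec.end


@dataclass(frozen=True)
class StructuredObservation:
    """A dated lab/PFT/smoking-status value for one patient."""

    patient_id: str
    obs_date: dt.date
    kind: str
    value: Union[float, str]

    def __post_init__(self) -> None:
        if self.kind not in OBSERVATION_KINDS:
            raise CorpusFormatError(f"unknown observation kind {self.kind!r}")
        if self.kind in NUMERIC_KINDS:
            v = float(self.value)
            if not (v == v and abs(v) != float("inf")) or v < 0:
                raise CorpusFormatError(f"{self.kind}: value must be finite and non-negative")
            if self.kind in PERCENT_PREDICTED_KINDS and not (0 < v <= 200):
                raise CorpusFormatError(f"{self.kind}: percent-predicted must lie in (0, 200]")
            object.__setattr__(self, "value", v)
        elif self.kind in CATEGORICAL_KINDS:
            if self.value not in CATEGORICAL_KINDS[self.kind]:
                raise CorpusFormatError(f"{self.kind}: invalid level {self.value!r}")
        else:  # serum_ige: flag or numeric
            if isinstance(self.value, str):
                if self.value not in ("elevated", "normal"):
                    raise CorpusFormatError("serum_ige: flag must be elevated/normal")
            else:
                object.__setattr__(self, "value", float(self.value))


@dataclass
class PatientRecord:
    """All notes and observations for one patient."""

    patient_id: str
    birth_date: Optional[dt.date] = None
    notes: list[ClinicalNote] = field(default_factory=list)
    observations: list[StructuredObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for n in self.notes:
            if n.patient_id != self.patient_id:
                raise CorpusFormatError("note patient_id mismatch inside record")
        for o in self.observations:
            if o.patient_id != self.patient_id:
                raise CorpusFormatError("observation patient_id mismatch inside record")
        self.notes.sort(key=lambda n: (n.note_date, n.note_id))


def _parse_date(raw: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(raw)[:10])
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"{where}: invalid date {raw!r}") from exc


def read_corpus(path: Union[str, Path]) -> list[PatientRecord]:
    """Read a JSONL note corpus into per-patient records.

    Each line is one JSON object with required keys ``patient_id``, ``note_id``,
    ``note_date``, ``text`` and optional ``provider_type``, ``sections``
    (list of ``[label, start, end]``) and ``birth_date``.  Notes are grouped by
    patient and sorted by ``(note_date, note_id)``; patients are returned in
    ``patient_id`` order, so the result is independent of input line order.
    """
    path = Path(path)
    notes_by_pid: dict[str, list[ClinicalNote]] = {}
    birth_by_pid: dict[str, dt.date] = {}
    seen: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON") from exc
            for name in ("patient_id", "note_id", "note_date", "text"):
                if obj.get(name) in (None, ""):
                    raise CorpusFormatError(f"line {lineno}: missing field {name!r}")
            pid, nid = str(obj["patient_id"]), str(obj["note_id"])
            if (pid, nid) in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate note ({pid}, {nid})")
            seen.add((pid, nid))
            sections = [
                Section(str(lab), int(s), int(e)) for lab, s, e in obj.get("sections") or []
            ]
            note = ClinicalNote(
                patient_id=pid,
                note_id=nid,
                note_date=_parse_date(obj["note_date"], f"line {lineno}: note_date"),
                text=str(obj["text"]),
                provider_type=obj.get("provider_type"),
                sections=sections,
            )
            notes_by_pid.setdefault(pid, []).append(note)
            if obj.get("birth_date") and pid not in birth_by_pid:
                birth_by_pid[pid] = _parse_date(obj["birth_date"], f"line {lineno}: birth_date")
    return [
        PatientRecord(patient_id=pid, birth_date=birth_by_pid.get(pid), notes=notes)
        for pid, notes in sorted(notes_by_pid.items())
    ]


def read_observations(path: Union[str, Path]) -> list[StructuredObservation]:
    """Read the structured-observation CSV (patient_id, obs_date, kind, value)."""
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "obs_date", "kind", "value"}
    if not required.issubset(df.columns):
        raise CorpusFormatError(
            f"observation table must have columns {sorted(required)}"
        )
    out: list[StructuredObservation] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        kind = str(row.kind)
        if kind not in OBSERVATION_KINDS:
            raise CorpusFormatError(f"row {idx}: unknown observation kind {kind!r}")
        raw = str(row.value)
        value: Union[float, str]
        if kind in NUMERIC_KINDS:
            try:
                value = float(raw)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"row {idx}: non-numeric value {raw!r} for kind {kind!r}"
                ) from exc
        elif kind == "serum_ige":
            try:
                value = float(raw)
            except ValueError:
                value = raw
        else:
            value = raw
        out.append(
            StructuredObservation(
                patient_id=str(row.patient_id),
                obs_date=_parse_date(row.obs_date, f"row {idx}: obs_date"),
                kind=kind,
                value=value,
            )
        )
    return out


def attach_observations(
    records: Iterable[PatientRecord], observations: Iterable[StructuredObservation]
) -> list[PatientRecord]:
    """Attach observations to their patients' records (in place; returns records).

    Observations for patients with no notes produce new note-less records.
    """
    records = list(records)
    by_pid = {r.patient_id: r for r in records}
    for obs in observations:
        rec = by_pid.get(obs.patient_id)
        if rec is None:
            rec = PatientRecord(patient_id=obs.patient_id)
            by_pid[obs.patient_id] = rec
            records.append(rec)
        rec.observations.append(obs)
    for rec in records:
        rec.observations.sort(key=lambda o: (o.obs_date, o.kind, str(o.value)))
    records.sort(key=lambda r: r.patient_id)
    return records


def read_reference_labels(path: Union[str, Path]) -> pd.DataFrame:
    """Read a reference-standard label CSV (patient_id, granular[, index_date]).

    Returns a DataFrame indexed by patient_id with columns ``granular``,
    ``asthma`` (bool) and ``index_date`` (date or None).
    """
    df = pd.read_csv(path, dtype=str)
    if not {"patient_id", "granular"}.issubset(df.columns):
        raise CorpusFormatError("label table must have columns patient_id, granular")
    bad = set(df["granular"]) - {"definite", "probable", "none", "excluded"}
    if bad:
        raise CorpusFormatError(f"invalid granular labels: {sorted(bad)}")
    out = pd.DataFrame(
        {
            "granular": df["granular"].values,
            "asthma": df["granular"].isin(["definite", "probable"]).values,
            "index_date": [
                _parse_date(v, "index_date") if isinstance(v, str) and v else None
                for v in (df["index_date"] if "index_date" in df.columns else [""] * len(df))
            ],
        },
        index=pd.Index(df["patient_id"].astype(str), name="patient_id"),
    )
    if out.index.has_duplicates:
        raise CorpusFormatError("duplicate patient_id in label table")
    return out


def write_status_table(statuses, path: Union[str, Path]) -> None:
    """Write one AsthmaStatus row per patient; round-trips via read_status_table."""
    rows = []
    seen: set[str] = set()
    for st in statuses:
        if st.patient_id in seen:
            raise CorpusFormatError(f"duplicate patient_id {st.patient_id!r}")
        seen.add(st.patient_id)
        rows.append(
            {
                "patient_id": st.patient_id,
                "granular": st.granular,
                "asthma": int(st.asthma),
                "index_date": st.index_date.isoformat() if st.index_date else "",
            }
        )
    pd.DataFrame(rows, columns=["patient_id", "granular", "asthma", "index_date"]).to_csv(
        path, index=False
    )


def read_status_table(path: Union[str, Path]) -> list:
    """Read back a status table written by :func:`write_status_table`."""
    from .pac_engine import AsthmaStatus  # local import avoids a module cycle

    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            AsthmaStatus(
                patient_id=str(row["patient_id"]),
                granular=str(row["granular"]),
                asthma=bool(int(row["asthma"])),
                index_date=_parse_date(row["index_date"], "index_date")
                if row["index_date"]
                else None,
            )
        )
    return out
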