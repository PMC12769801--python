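"""Seeded generator of labelled synthetic patient corpora.

Emulates the evidence structure the phenotype pipeline consumes: multi-note
patient timelines carrying canonical criterion sentences, negation and
family-history distractors, threshold-straddling laboratory/PFT observations,
exclusion conditions, and exact ground-truth labels with planted index dates.
The planted index date is set analytically (the date the last required
component appears), so index-date recovery is an exact end-to-end test.

The text is deliberately templated, not realistic prose: what the generator
controls is the *evidence logic* (assertion, experiencer, sections, dates,
thresholds), which is what the downstream rule engine keys on.
"""
from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .corpus_io import ClinicalNote, PatientRecord, StructuredObservation
import json

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticCorpus",
    "generate",
    "perturb_negate_all",
    "write_corpus_files",
    "canonical_config",
]

# canonical affirmed sentence -> negated rewrite (used by perturb_negate_all)
AFFIRM_TO_NEGATED: dict[str, str] = {
    "Patient reports persistent cough.": "Patient denies persistent cough.",
    "Patient had wheezing overnight.": "Patient denied wheezing overnight.",
    "Complains of dyspnea on exertion.": "Denies dyspnea on exertion.",
    "Wheezing on exam today.": "No wheezing on exam today.",
    "Substantial variability in symptoms from visit to visit.":
        "Denies substantial variability in symptoms from visit to visit.",
    "Symptom free for weeks at a time.": "Never symptom free for weeks at a time.",
    "Sleep disturbance by nocturnal cough and wheeze.":
        "Denies sleep disturbance by nocturnal cough and wheeze.",
    "Nasal polyps seen on rhinoscopy.": "No nasal polyps seen on rhinoscopy.",
    "History of hay fever.": "No history of hay fever.",
    "Infantile eczema in childhood.": "No infantile eczema in childhood.",
    "Cough, dyspnea, and wheezing regularly on exposure to an antigen.":
        "Denies cough, dyspnea, and wheezing regularly on exposure to an antigen.",
    "Positive wheal and flare skin tests.": "No positive wheal and flare skin tests.",
    "Favorable clinical response to bronchodilator therapy.":
        "No favorable clinical response to bronchodilator therapy.",
    "DIAGNOSIS:\nAsthma.": "DIAGNOSIS:\nNo evidence of asthma.",
}

_SENTENCE = {
    "cough": "Patient reports persistent cough.",
    "wheezing": "Patient had wheezing overnight.",
    "dyspnea": "Complains of dyspnea on exertion.",
    "wheeze_on_exam": "Wheezing on exam today.",
    "symptom_variability": "Substantial variability in symptoms from visit to visit.",
    "symptom_free_weeks": "Symptom free for weeks at a time.",
    "nocturnal": "Sleep disturbance by nocturnal cough and wheeze.",
    "nasal_polyps": "Nasal polyps seen on rhinoscopy.",
    "hay_fever": "History of hay fever.",
    "infantile_eczema": "Infantile eczema in childhood.",
    "antigen": "Cough, dyspnea, and wheezing regularly on exposure to an antigen.",
    "atopy_test": "Positive wheal and flare skin tests.",
    "bronchodilator": "Favorable clinical response to bronchodilator therapy.",
}

_EXCLUSION_SENTENCE = {
    "fev1_lt50_consistent_or_low_dlco": "FEV1 consistently below 50% predicted.",
    "foreign_body_near_index": "Tracheobronchial foreign body removed.",
    "hypogammaglobulinemia_or_immunodeficiency": "Hypogammaglobulinemia noted on workup.",
    "wheeze_only_anesthesia_meds": "Wheezing only in response to anesthesia.",
    "bullous_emphysema_or_fibrosis": "Bullous emphysema on chest imaging.",
    "pizz_a1at": "PiZZ phenotype confirmed.",
    "cystic_fibrosis": "Cystic fibrosis followed by pulmonology.",
    "other_major_chest_disease": "Bronchiectasis on CT chest.",
}

_NEGATION_DISTRACTORS = (
    "Denies wheezing.",
    "No cough today.",
    "Without dyspnea at rest.",
    "Negative for wheezing on exam.",
)
_FAMILY_DISTRACTORS = (
    "FAMILY HISTORY:\nAsthma in mother.",
    "FAMILY HISTORY:\nBrother with wheezing as a child.",
)
_FILLERS = (
    "Vital signs stable.",
    "Medication list reviewed.",
    "Patient doing well overall.",
    "Discussed diet and exercise.",
    "Labs reviewed with patient.",
)
_BOILERPLATE = "Seen in clinic for routine follow up."

# minor criteria the generator can plant, with their planting channel
_TEXT_MINORS = {
    "nocturnal_symptoms": "nocturnal",
    "nasal_polyps": "nasal_polyps",
    "atopy_test_positive": "atopy_test",
    "bronchodilator_response": "bronchodilator",
}
_ATOPY_HISTORY_CHOICES = ("hay_fever", "infantile_eczema", "antigen")
_PLANTABLE_MINORS = (
    "nocturnal_symptoms",
    "nasal_polyps",
    "atopy_test_positive",
    "bronchodilator_response",
    "atopy_history",
    "eosinophilia_gt300",
    "pft_criterion",
    "nonsmoker_14plus",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror a validation-style cohort: asthma prevalence around 5%,
    a handful of notes per adult patient over a decade of follow-up, and
    moderate documentation noise.
    """

    n_patients: int = 500
    prevalence: float = 0.051
    p_definite_given_asthma: float = 0.6
    notes_per_patient: tuple[int, int] = (2, 5)
    date_range: tuple[dt.date, dt.date] = (dt.date(2000, 1, 1), dt.date(2009, 12, 31))
    p_negation_distractor: float = 0.3
    p_family_distractor: float = 0.3
    p_exclusion: float = 0.02
    p_minor_criterion: float = 0.5  # per-criterion chance of a third minor
    p_benign_observation: float = 0.3
    template_noise: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "prevalence",
            "p_definite_given_asthma",
            "p_negation_distractor",
            "p_family_distractor",
            "p_exclusion",
            "p_minor_criterion",
            "p_benign_observation",
            "template_noise",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"generator config: {name} must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("generator config: n_patients must be >= 1")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("generator config: invalid notes_per_patient range")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("generator config: empty date_range")


@dataclass(frozen=True)
class GroundTruth:
    """Planted label, index date, and criteria list for one patient."""

    patient_id: str
    granular: str
    index_date: Optional[dt.date]
    criteria: tuple[str, ...]

    @property
    def asthma(self) -> bool:
        return self.granular in ("definite", "probable")


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    records: list[PatientRecord]
    truths: list[GroundTruth]


def canonical_config() -> GeneratorConfig:
    """The versioned fixture configuration (the canonical test corpus)."""
    path = resources.files("pacpheno").joinpath("data/canonical_corpus.yaml")
    with resources.as_file(path) as p:
        raw = yaml.safe_load(Path(p).read_text())
    raw["notes_per_patient"] = tuple(raw["notes_per_patient"])
    raw["date_range"] = tuple(dt.date.fromisoformat(d) for d in raw["date_range"])
    return GeneratorConfig(**raw)


def _pick_dates(rng: random.Random, config: GeneratorConfig, k: int) -> list[dt.date]:
    start, end = config.date_range
    span = (end - start).days
    ordinals = rng.sample(range(span + 1), k=min(k, span + 1))
    return sorted(start + dt.timedelta(days=o) for o in ordinals)


def _plant_case(
    rng: random.Random,
    config: GeneratorConfig,
    note_dates: list[dt.date],
    definite: bool,
) -> tuple[dict[dt.date, list[str]], list[tuple[dt.date, str, object]], Optional[dt.date], list[str], Optional[dt.date]]:
    """Plan sentences/observations for a case; returns (sentences-by-date,
    observations, dx_date, criteria list, planted index date)."""
    sentences: dict[dt.date, list[str]] = {d: [] for d in note_dates}
    observations: list[tuple[dt.date, str, object]] = []
    criteria: list[str] = []

    combo = rng.choice(
        [("cough", "wheezing"), ("cough", "dyspnea"), ("cough", "wheeze_on_exam"),
         ("dyspnea", "wheeze_on_exam")]
    )
    d_a, d_b = rng.choice(note_dates), rng.choice(note_dates)
    sentences[d_a].append(_SENTENCE[combo[0]])
    sentences[d_b].append(_SENTENCE[combo[1]])
    c1_date = max(d_a, d_b)
    criteria.append("cond1")

    cond2 = rng.choice(("symptom_variability", "symptom_free_weeks"))
    d_c2 = rng.choice(note_dates)
    sentences[d_c2].append(_SENTENCE[cond2])
    c2_date = d_c2
    criteria.append("cond2")

    dx_date: Optional[dt.date] = None
    minor_dates: list[dt.date] = []
    if definite:
        if rng.random() < 0.5:
            dx_date = rng.choice(note_dates)
            criteria.append("physician_dx")
        else:
            n_minors = 3 if rng.random() < config.p_minor_criterion else 2
            chosen = rng.sample(_PLANTABLE_MINORS, k=n_minors)
            for minor in chosen:
                d = rng.choice(note_dates)
                if minor in _TEXT_MINORS:
                    sentences[d].append(_SENTENCE[_TEXT_MINORS[minor]])
                    minor_dates.append(d)
                elif minor == "atopy_history":
                    sentences[d].append(_SENTENCE[rng.choice(_ATOPY_HISTORY_CHOICES)])
                    minor_dates.append(d)
                elif minor == "eosinophilia_gt300":
                    observations.append((d, "eosinophil_count", rng.randint(320, 900)))
                    minor_dates.append(d)
                elif minor == "nonsmoker_14plus":
                    observations.append((d, "smoking_status", "never"))
                    minor_dates.append(d)
                else:  # pft_criterion: a low reading, then a qualifying improvement
                    others = [x for x in note_dates if x >= d] or [d]
                    d2 = rng.choice(others)
                    observations.append((d, "fev1_pct_pred", rng.randint(45, 69)))
                    observations.append((d2, "fev1_bd_improvement", rng.randint(20, 40)))
                    observations.append((d2, "fev1_post_bd_pct_pred", rng.randint(71, 95)))
                    minor_dates.append(max(d, d2))
                criteria.append(minor)

    routes = [max(c1_date, c2_date)]
    if dx_date is not None:
        routes.append(dx_date)
    if len(minor_dates) >= 2:
        routes.append(max(c1_date, c2_date, sorted(minor_dates)[1]))
    return sentences, observations, dx_date, criteria, min(routes)


def generate(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a labelled corpus; identical config+seed gives identical output."""
    config.validate()
    rng = random.Random(config.seed)
    records: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    start, end = config.date_range

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        age = rng.randint(25, 85)
        birth = end - dt.timedelta(days=age * 365 + rng.randint(0, 364))
        n_notes = rng.randint(*config.notes_per_patient)
        note_dates = _pick_dates(rng, config, n_notes)

        excluded = rng.random() < config.p_exclusion
        is_case = (not excluded) and rng.random() < config.prevalence
        definite = is_case and rng.random() < config.p_definite_given_asthma

        sentences: dict[dt.date, list[str]] = {d: [] for d in note_dates}
        blocks: dict[dt.date, list[str]] = {d: [] for d in note_dates}
        obs_plan: list[tuple[dt.date, str, object]] = []
        criteria: list[str] = []
        index_date: Optional[dt.date] = None

        if excluded or is_case:
            # exclusions carry full definite-style evidence plus the exclusion
            s, o, dx_date, criteria, index_date = _plant_case(
                rng, config, note_dates, definite or excluded
            )
            for d, ss in s.items():
                sentences[d].extend(ss)
            obs_plan.extend(o)
            if dx_date is not None:
                blocks[dx_date].append("DIAGNOSIS:\nAsthma.")
        if excluded:
            excl = rng.choice(list(_EXCLUSION_SENTENCE))
            if excl == "foreign_body_near_index":
                d_ex = index_date  # always within the +/-365-day window
            else:
                d_ex = rng.choice(note_dates)
            sentences[d_ex].append(_EXCLUSION_SENTENCE[excl])
            criteria = list(criteria) + [f"exclusion:{excl}"]
            granular, index_out = "excluded", None
        elif is_case:
            granular, index_out = ("definite" if definite else "probable"), index_date
        else:
            granular, index_out = "none", None
            for d in note_dates:
                if rng.random() < config.p_negation_distractor:
                    sentences[d].append(rng.choice(_NEGATION_DISTRACTORS))
                if rng.random() < config.p_family_distractor:
                    blocks[d].append(rng.choice(_FAMILY_DISTRACTORS))
            if rng.random() < config.p_benign_observation:
                d = rng.choice(note_dates)
                obs_plan.append((d, "eosinophil_count", rng.randint(50, 300)))
                obs_plan.append((d, "smoking_status", rng.choice(("former", "current", "unknown"))))

        notes = []
        for j, d in enumerate(note_dates):
            lines = [_BOILERPLATE] + sentences[d]
            if rng.random() < config.template_noise:
                lines.append(rng.choice(_FILLERS))
            text = "\n".join(lines)
            for block in blocks[d]:
                text += "\n" + block
            notes.append(
                ClinicalNote(
                    patient_id=pid,
                    note_id=f"{pid}-N{j:02d}",
                    note_date=d,
                    text=text,
                    provider_type=rng.choice(("physician", "nurse")),
                )
            )
        observations = [
            StructuredObservation(patient_id=pid, obs_date=d, kind=k, value=v)
            for d, k, v in sorted(obs_plan, key=lambda t: (t[0], t[1], str(t[2])))
        ]
        records.append(
            PatientRecord(patient_id=pid, birth_date=birth, notes=notes, observations=observations)
        )
        truths.append(GroundTruth(pid, granular, index_out, tuple(criteria)))

    return SyntheticCorpus(config=config, records=records, truths=truths)


def perturb_negate_all(corpus: SyntheticCorpus) -> SyntheticCorpus:
    """Rewrite every canonical affirmed evidence sentence with a negation.

    The physician-diagnosis line is rewritten too, so no classification route
    survives; ground truth is relabelled ``none``.  Idempotent: negated forms
    contain no affirmed template.
    """
    new_records = []
    for rec in corpus.records:
        new_notes = []
        for note in rec.notes:
            text = note.text
            for affirmed, negated in AFFIRM_TO_NEGATED.items():
                text = text.replace(affirmed, negated)
            new_notes.append(replace(note, text=text, sections=[]))
        new_records.append(
            PatientRecord(
                patient_id=rec.patient_id,
                birth_date=rec.birth_date,
                notes=new_notes,
                observations=list(rec.observations),
            )
        )
    new_truths = [
        GroundTruth(t.patient_id, "none", None, t.criteria) for t in corpus.truths
    ]
    return SyntheticCorpus(config=corpus.config, records=new_records, truths=new_truths)


def write_corpus_files(corpus: SyntheticCorpus, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write notes.jsonl, observations.csv, ground_truth.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notes_path = outdir / "notes.jsonl"
    with notes_path.open("w", encoding="utf-8") as fh:
        for rec in corpus.records:
            for note in rec.notes:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": note.patient_id,
                            "note_id": note.note_id,
                            "note_date": note.note_date.isoformat(),
                            "birth_date": rec.birth_date.isoformat() if rec.birth_date else None,
                            "provider_type": note.provider_type,
                            "text": note.text,
                        }
                    )
                    + "\n"
                )
    obs_rows = [
        {
            "patient_id": o.patient_id,
            "obs_date": o.obs_date.isoformat(),
            "kind": o.kind,
            "value": o.value,
        }
        for rec in corpus.records
        for o in rec.observations
    ]
    obs_path = outdir / "observations.csv"
    pd.DataFrame(obs_rows, columns=["patient_id", "obs_date", "kind", "value"]).to_csv(
        obs_path, index=False
    )
    truth_rows = [
        {
            "patient_id": t.patient_id,
            "granular": t.granular,
            "index_date": t.index_date.isoformat() if t.index_date else "",
            "criteria": ";".join(t.criteria),
        }
        for t in corpus.truths
    ]
    truth_path = outdir / "ground_truth.csv"
    pd.DataFrame(
        truth_rows, columns=["patient_id", "granular", "index_date", "criteria"]
    ).to_csv(truth_path, index=False)
    return {"notes": notes_path, "observations": obs_path, "ground_truth": truth_path}
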