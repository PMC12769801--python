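"""Patient-level asthma classification against the predetermined asthma criteria.

The criteria classify a patient as *definite* asthma when a physician has made
an asthma diagnosis, or when all three of the following hold; *probable*
asthma when only the first two hold:

1. history of cough with wheezing and/or dyspnea, or history of cough and/or
   dyspnea plus wheezing at examination;
2. substantial variability in symptoms, or symptom-free periods of weeks;
3. two or more minor criteria: nocturnal cough-and-wheeze sleep disturbance;
   nonsmoker aged >=14; nasal polyps; blood eosinophilia >300 cells/uL;
   positive skin tests or elevated serum IgE; history of hay fever, infantile
   eczema, or antigen-triggered symptoms; a qualifying pulmonary-function
   pattern; or a favorable bronchodilator response.

Eight exclusion conditions (cystic fibrosis, bullous emphysema or pulmonary
fibrosis, etc.) veto the classification.  Evidence is cumulative across a
patient's dated notes and observations, and the index date is the first
calendar date on which the criteria are met.

Only affirmed, patient-experienced mentions count as evidence; a physician
diagnosis is credited only from diagnosis/impression/plan sections.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus_io import PatientRecord, StructuredObservation
from .text_processing import AFFIRMED, PATIENT, ConceptMention, Lexicon, segment_sections, extract_mentions

__all__ = [
    "EngineConfig",
    "PatientEvidence",
    "AsthmaStatus",
    "EvidenceItem",
    "build_evidence",
    "eval_pft_criterion",
    "classify",
    "determine_index_date",
    "classify_record",
    "classify_cohort",
]

MINOR_CRITERIA = (
    "nocturnal_symptoms",
    "nonsmoker_14plus",
    "nasal_polyps",
    "eosinophilia_gt300",
    "atopy_test_positive",
    "atopy_history",
    "pft_criterion",
    "bronchodilator_response",
)

EXCLUSION_IDS = (
    "fev1_lt50_consistent_or_low_dlco",
    "foreign_body_near_index",
    "hypogammaglobulinemia_or_immunodeficiency",
    "wheeze_only_anesthesia_meds",
    "bullous_emphysema_or_fibrosis",
    "pizz_a1at",
    "cystic_fibrosis",
    "other_major_chest_disease",
)

_COND1_CONCEPTS = ("cough", "wheezing", "dyspnea", "wheeze_on_exam")
_COND2_CONCEPTS = ("symptom_variability", "symptom_free_weeks")
_ATOPY_HISTORY_CONCEPTS = ("hay_fever", "infantile_eczema", "antigen_triggered_symptoms")


@dataclass(frozen=True)
class EngineConfig:
    """Tunable thresholds and policy knobs for the criteria engine.

    min_episodes: distinct symptom-evidence dates condition 1 must span.
    bd_response_threshold: numeric post-bronchodilator FEV1 improvement (%)
        accepted as a favorable response when only numbers are available.
    eosinophil_threshold: cells/uL; the criterion requires a strictly greater
        count.
    ige_threshold: numeric serum IgE (kU/L) treated as elevated; None means
        only the elevated/normal flag counts.
    admit_former_smoker: whether "former" also satisfies the nonsmoker
        criterion (default: only "never").
    foreign_body_window_days: half-width of the "at or about the index date"
        window for the tracheobronchial foreign-body exclusion.
    assume_age_ok_without_birth_date: with no recorded birth date the age>=14
        gate of the nonsmoker criterion is taken as met (adult corpora).
    """

    min_episodes: int = 1
    bd_response_threshold: float = 12.0
    eosinophil_threshold: float = 300.0
    pft_low_threshold: float = 70.0
    pft_improvement_threshold: float = 20.0
    methacholine_decline_threshold: float = 20.0
    fev1_exclusion_threshold: float = 50.0
    igg_exclusion_threshold: float = 2.0
    ige_threshold: Optional[float] = None
    admit_former_smoker: bool = False
    foreign_body_window_days: int = 365
    assume_age_ok_without_birth_date: bool = True


DEFAULT_CONFIG = EngineConfig()


@dataclass(frozen=True)
class EvidenceItem:
    """One audit-trail line: which criterion was credited, when, from what."""

    patient_id: str
    item: str
    date: dt.date
    source: str


@dataclass
class PatientEvidence:
    """Per-patient dated satisfaction record for every criterion and exclusion.

    ``cond1_dates``/``cond2_dates`` hold every timeline date on which the
    condition is satisfied by the cumulative evidence up to that date (so the
    sets are upward-closed within the patient's date range); each minor
    criterion maps to its earliest satisfaction date, each exclusion to its
    earliest evidence date.
    """

    patient_id: str
    physician_dx_dates: set[dt.date] = field(default_factory=set)
    cond1_dates: set[dt.date] = field(default_factory=set)
    cond2_dates: set[dt.date] = field(default_factory=set)
    minor_criteria: dict[str, dt.date] = field(default_factory=dict)
    exclusions: dict[str, dt.date] = field(default_factory=dict)
    trail: list[EvidenceItem] = field(default_factory=list)

    def first(self, which: str) -> Optional[dt.date]:
        dates = {"dx": self.physician_dx_dates, "cond1": self.cond1_dates, "cond2": self.cond2_dates}[which]
        return min(dates) if dates else None


@dataclass(frozen=True)
class AsthmaStatus:
    """Granular class, binary asthma flag, and index date for one patient."""

    patient_id: str
    granular: str  # definite | probable | none | excluded
    asthma: bool
    index_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.granular not in ("definite", "probable", "none", "excluded"):
            raise ValueError(f"invalid granular status {self.granular!r}")
        if self.asthma != (self.granular in ("definite", "probable")):
            raise ValueError("asthma flag inconsistent with granular status")
        if (self.index_date is not None) != self.asthma:
            raise ValueError("index_date must be present iff asthma is true")


# ---------------------------------------------------------------------------
# evidence construction


def eval_pft_criterion(
    observations: Iterable[StructuredObservation], config: EngineConfig = DEFAULT_CONFIG
) -> Optional[dt.date]:
    """Earliest date at which the pulmonary-function minor criterion is met.

    Route (a): some FEV1 or FVC below 70% predicted, plus another test showing
    at least 20% improvement reaching FEV1 above 70% predicted (an improvement
    reading and a same-day post-bronchodilator FEV1).  Route (b): methacholine
    challenge with a decline of at least 20%.  Both 20% boundaries are
    inclusive; the 70% boundaries are strict.
    """
    obs = list(observations)
    low_dates = sorted(
        o.obs_date
        for o in obs
        if o.kind in ("fev1_pct_pred", "fvc_pct_pred") and float(o.value) < config.pft_low_threshold
    )
    post_by_date: dict[dt.date, float] = {}
    for o in obs:
        if o.kind == "fev1_post_bd_pct_pred":
            post_by_date[o.obs_date] = max(post_by_date.get(o.obs_date, 0.0), float(o.value))
    improvement_dates = sorted(
        o.obs_date
        for o in obs
        if o.kind == "fev1_bd_improvement"
        and float(o.value) >= config.pft_improvement_threshold
        and post_by_date.get(o.obs_date, 0.0) > config.pft_low_threshold
    )
    candidates: list[dt.date] = []
    if low_dates and improvement_dates:
        candidates.append(max(low_dates[0], improvement_dates[0]))
    meth = sorted(
        o.obs_date
        for o in obs
        if o.kind == "methacholine_fev1_decline"
        and float(o.value) >= config.methacholine_decline_threshold
    )
    if meth:
        candidates.append(meth[0])
    return min(candidates) if candidates else None


def _nonsmoker_first_date(
    record: PatientRecord, config: EngineConfig
) -> Optional[dt.date]:
    """Earliest date at which the nonsmoker (>=14 years) criterion holds."""
    smoking = sorted(
        (o for o in record.observations if o.kind == "smoking_status"),
        key=lambda o: o.obs_date,
    )
    if not smoking:
        return None
    ok_levels = {"never", "former"} if config.admit_former_smoker else {"never"}
    if record.birth_date is not None:
        try:
            fourteenth = record.birth_date.replace(year=record.birth_date.year + 14)
        except ValueError:  # Feb 29
            fourteenth = record.birth_date.replace(year=record.birth_date.year + 14, day=28)
    elif config.assume_age_ok_without_birth_date:
        fourteenth = dt.date.min
    else:
        return None
    candidates = sorted({o.obs_date for o in smoking} | {fourteenth})
    for d in candidates:
        if d < fourteenth:
            continue
        latest = None
        for o in smoking:
            if o.obs_date <= d:
                latest = o.value
        if latest in ok_levels:
            return d
    return None


def _first_concept_date(by_concept: dict[str, list[ConceptMention]], *concepts: str) -> Optional[dt.date]:
    dates = [m.note_date for c in concepts for m in by_concept.get(c, [])]
    return min(dates) if dates else None


def build_evidence(
    record: PatientRecord,
    mentions: Sequence[ConceptMention],
    config: EngineConfig = DEFAULT_CONFIG,
    dx_sections: frozenset = frozenset({"diagnosis", "impression_assessment", "plan"}),
) -> PatientEvidence:
    """Combine asserted mentions and observations into dated criterion evidence.

    Only affirmed, patient-experienced mentions are credited; the physician
    asthma diagnosis concept is additionally restricted to ``dx_sections``,
    and no symptom concept is credited from a family-history section.
    Condition 1 combines primary concepts across notes: cough with (wheezing
    or dyspnea), or (cough or dyspnea) with wheezing at examination.
    """
    for m in mentions:
        if m.patient_id != record.patient_id:
            raise ValueError(
                f"mention for patient {m.patient_id!r} passed to record {record.patient_id!r}"
            )
    ev = PatientEvidence(patient_id=record.patient_id)
    usable = [
        m
        for m in mentions
        if m.assertion == AFFIRMED
        and m.experiencer == PATIENT
        and m.section_label != "family_history"
    ]
    by_concept: dict[str, list[ConceptMention]] = {}
    for m in usable:
        if m.concept_id == "physician_asthma_dx" and m.section_label not in dx_sections:
            continue
        by_concept.setdefault(m.concept_id, []).append(m)

    def log_concept(item: str, concepts: Sequence[str], date: dt.date) -> None:
        for c in concepts:
            for m in by_concept.get(c, []):
                if m.note_date == date:
                    ev.trail.append(
                        EvidenceItem(
                            record.patient_id, item, date,
                            f"note:{m.note_id} span {m.span[0]}-{m.span[1]} ({c})",
                        )
                    )
                    return

    all_dates = sorted(
        {m.note_date for m in usable}
        | {o.obs_date for o in record.observations}
        | {n.note_date for n in record.notes}
    )

    # physician diagnosis
    for m in by_concept.get("physician_asthma_dx", []):
        ev.physician_dx_dates.add(m.note_date)
    if ev.physician_dx_dates:
        log_concept("physician_dx", ["physician_asthma_dx"], min(ev.physician_dx_dates))

    # condition 1: secondary-concept combination, cumulative across notes
    firsts = {c: _first_concept_date(by_concept, c) for c in _COND1_CONCEPTS}
    combos = [
        ("cough", "wheezing"),
        ("cough", "dyspnea"),
        ("cough", "wheeze_on_exam"),
        ("dyspnea", "wheeze_on_exam"),
    ]
    combo_first: Optional[dt.date] = None
    for a, b in combos:
        if firsts[a] and firsts[b]:
            d = max(firsts[a], firsts[b])
            combo_first = d if combo_first is None else min(combo_first, d)
    episode_dates = sorted({m.note_date for c in _COND1_CONCEPTS for m in by_concept.get(c, [])})
    cond1_first: Optional[dt.date] = None
    if combo_first is not None and len(episode_dates) >= config.min_episodes:
        cond1_first = max(combo_first, episode_dates[config.min_episodes - 1])
        ev.cond1_dates = {d for d in all_dates if d >= cond1_first} | {cond1_first}
        log_concept("cond1", list(_COND1_CONCEPTS), cond1_first)

    # condition 2: symptom variability / symptom-free weeks
    cond2_first = _first_concept_date(by_concept, *_COND2_CONCEPTS)
    if cond2_first is not None:
        ev.cond2_dates = {d for d in all_dates if d >= cond2_first} | {cond2_first}
        log_concept("cond2", list(_COND2_CONCEPTS), cond2_first)

    # minor criteria -----------------------------------------------------
    def credit(criterion: str, date: Optional[dt.date], source: str) -> None:
        if date is None:
            return
        if criterion not in ev.minor_criteria or date < ev.minor_criteria[criterion]:
            ev.minor_criteria[criterion] = date
            ev.trail.append(EvidenceItem(record.patient_id, criterion, date, source))

    d = _first_concept_date(by_concept, "nocturnal_cough_wheeze")
    credit("nocturnal_symptoms", d, "note concept nocturnal_cough_wheeze")

    credit("nonsmoker_14plus", _nonsmoker_first_date(record, config), "obs:smoking_status")

    credit("nasal_polyps", _first_concept_date(by_concept, "nasal_polyps"), "note concept nasal_polyps")

    eos = sorted(
        o.obs_date
        for o in record.observations
        if o.kind == "eosinophil_count" and float(o.value) > config.eosinophil_threshold
    )
    credit("eosinophilia_gt300", eos[0] if eos else None, "obs:eosinophil_count")

    atopy_dates = []
    d = _first_concept_date(by_concept, "atopy_test_positive")
    if d:
        atopy_dates.append((d, "note concept atopy_test_positive"))
    for o in record.observations:
        if o.kind == "serum_ige":
            elevated = (o.value == "elevated") or (
                config.ige_threshold is not None
                and not isinstance(o.value, str)
                and float(o.value) >= config.ige_threshold
            )
            if elevated:
                atopy_dates.append((o.obs_date, "obs:serum_ige"))
    if atopy_dates:
        d, src = min(atopy_dates)
        credit("atopy_test_positive", d, src)

    credit(
        "atopy_history",
        _first_concept_date(by_concept, *_ATOPY_HISTORY_CONCEPTS),
        "note concept atopy history",
    )

    credit("pft_criterion", eval_pft_criterion(record.observations, config), "obs:pft")

    bd_dates = []
    d = _first_concept_date(by_concept, "bronchodilator_response")
    if d:
        bd_dates.append(d)
    bd_dates += [
        o.obs_date
        for o in record.observations
        if o.kind == "fev1_bd_improvement" and float(o.value) >= config.bd_response_threshold
    ]
    credit("bronchodilator_response", min(bd_dates) if bd_dates else None, "bronchodilator evidence")

    # exclusions ---------------------------------------------------------
    def exclude(excl: str, date: Optional[dt.date], source: str) -> None:
        if date is None:
            return
        if excl not in ev.exclusions or date < ev.exclusions[excl]:
            ev.exclusions[excl] = date
            ev.trail.append(EvidenceItem(record.patient_id, f"exclusion:{excl}", date, source))

    for excl in EXCLUSION_IDS:
        exclude(excl, _first_concept_date(by_concept, excl), f"note concept {excl}")

    fev1 = sorted(
        (o.obs_date, float(o.value))
        for o in record.observations
        if o.kind == "fev1_pct_pred"
    )
    if len(fev1) >= 2 and all(v < config.fev1_exclusion_threshold for _, v in fev1):
        exclude("fev1_lt50_consistent_or_low_dlco", fev1[1][0], "obs:fev1_pct_pred")
    dlco = sorted(
        o.obs_date
        for o in record.observations
        if o.kind == "diffusion_capacity" and o.value == "diminished"
    )
    if dlco:
        exclude("fev1_lt50_consistent_or_low_dlco", dlco[0], "obs:diffusion_capacity")
    igg = sorted(
        o.obs_date
        for o in record.observations
        if o.kind == "igg" and float(o.value) < config.igg_exclusion_threshold
    )
    if igg:
        exclude("hypogammaglobulinemia_or_immunodeficiency", igg[0], "obs:igg")

    ev.trail.sort(key=lambda t: (t.date, t.item))
    return ev


# ---------------------------------------------------------------------------
# classification


def determine_index_date(
    evidence: PatientEvidence, as_of: Optional[dt.date] = None
) -> Optional[dt.date]:
    """First date on which the criteria are met, minimised over routes.

    Routes: physician diagnosis (its first date); probable (conditions 1 and 2,
    at the max of their first dates); definite-by-criteria (conditions 1 and 2
    plus the second-earliest minor criterion).  The probable route is a subset
    of the definite-by-criteria route, so the latter can never precede it.
    """
    cutoff = as_of or dt.date.max

    def upto(d: Optional[dt.date]) -> Optional[dt.date]:
        return d if d is not None and d <= cutoff else None

    dx = upto(evidence.first("dx"))
    c1 = upto(evidence.first("cond1"))
    c2 = upto(evidence.first("cond2"))
    minors = sorted(d for d in evidence.minor_criteria.values() if d <= cutoff)

    routes: list[dt.date] = []
    if dx is not None:
        routes.append(dx)
    if c1 is not None and c2 is not None:
        routes.append(max(c1, c2))
        if len(minors) >= 2:
            routes.append(max(c1, c2, minors[1]))
    return min(routes) if routes else None


def classify(
    evidence: PatientEvidence,
    as_of: Optional[dt.date] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> AsthmaStatus:
    """Apply the criteria to cumulative evidence on or before ``as_of``.

    Any exclusion condition vetoes the classification; the foreign-body
    exclusion applies only when its date falls within the configured window
    around the candidate index date.
    """
    cutoff = as_of or dt.date.max
    candidate = determine_index_date(evidence, as_of)

    active_exclusions = {e: d for e, d in evidence.exclusions.items() if d <= cutoff}
    fb = active_exclusions.pop("foreign_body_near_index", None)
    if fb is not None and candidate is not None:
        window = dt.timedelta(days=config.foreign_body_window_days)
        if abs(fb - candidate) <= window:
            active_exclusions["foreign_body_near_index"] = fb
    if active_exclusions:
        return AsthmaStatus(evidence.patient_id, "excluded", False, None)

    dx = evidence.first("dx")
    c1 = evidence.first("cond1")
    c2 = evidence.first("cond2")
    has_dx = dx is not None and dx <= cutoff
    has_c1 = c1 is not None and c1 <= cutoff
    has_c2 = c2 is not None and c2 <= cutoff
    n_minors = sum(1 for d in evidence.minor_criteria.values() if d <= cutoff)

    if has_dx or (has_c1 and has_c2 and n_minors >= 2):
        return AsthmaStatus(evidence.patient_id, "definite", True, candidate)
    if has_c1 and has_c2:
        return AsthmaStatus(evidence.patient_id, "probable", True, candidate)
    return AsthmaStatus(evidence.patient_id, "none", False, None)


# ---------------------------------------------------------------------------
# orchestration helpers


def classify_record(
    record: PatientRecord,
    lexicon: Optional[Lexicon] = None,
    config: EngineConfig = DEFAULT_CONFIG,
    as_of: Optional[dt.date] = None,
) -> tuple[AsthmaStatus, PatientEvidence]:
    """Segment, extract, build evidence, and classify one patient record."""
    lexicon = lexicon or Lexicon.default()
    mentions: list[ConceptMention] = []
    for note in record.notes:
        sectioned = note if note.sections else segment_sections(note, lexicon)
        mentions.extend(extract_mentions(sectioned, lexicon))
    evidence = build_evidence(record, mentions, config, dx_sections=lexicon.dx_sections)
    return classify(evidence, as_of, config), evidence


def classify_cohort(
    records: Sequence[PatientRecord],
    lexicon: Optional[Lexicon] = None,
    config: EngineConfig = DEFAULT_CONFIG,
    as_of: Optional[dt.date] = None,
) -> tuple[list[AsthmaStatus], list[PatientEvidence]]:
    """Classify every record; ``as_of`` defaults to the corpus end date."""
    lexicon = lexicon or Lexicon.default()
    if as_of is None:
        dates = [n.note_date for r in records for n in r.notes] + [
            o.obs_date for r in records for o in r.observations
        ]
        as_of = max(dates) if dates else None
    statuses, evidences = [], []
    for rec in records:
        st, ev = classify_record(rec, lexicon, config, as_of)
        statuses.append(st)
        evidences.append(ev)
    return statuses, evidences
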