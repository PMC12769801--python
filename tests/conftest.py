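import dataclasses
import datetime as dt

import pytest

from pacpheno.synthetic_corpus import canonical_config, generate
from pacpheno.text_processing import Lexicon, ConceptMention


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def canonical_corpus():
    """The versioned fixture corpus: n=500 with distractor rates 0.3."""
    return generate(canonical_config())


@pytest.fixture(scope="session")
def noise_free_corpus():
    """Same cohort conditions with all distractors and filler noise disabled."""
    cfg = dataclasses.replace(
        canonical_config(),
        template_noise=0.0,
        p_negation_distractor=0.0,
        p_family_distractor=0.0,
    )
    return generate(cfg)


def make_mention(
    concept_id,
    note_date,
    patient_id="P1",
    assertion="affirmed",
    experiencer="patient",
    section_label="unknown",
    note_id="N1",
):
    """Concise ConceptMention factory for engine-level tests."""
    if isinstance(note_date, str):
        note_date = dt.date.fromisoformat(note_date)
    return ConceptMention(
        concept_id=concept_id,
        patient_id=patient_id,
        note_id=note_id,
        note_date=note_date,
        span=(0, 1),
        section_label=section_label,
        assertion=assertion,
        experiencer=experiencer,
    )
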