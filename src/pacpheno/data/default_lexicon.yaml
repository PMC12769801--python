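# Default evidence lexicon and context-rule configuration.
#
# Patterns are case-insensitive literal phrases (internal whitespace matches any
# run of whitespace).  The concept ids are consumed by the PAC engine; patterns
# are fully user-replaceable.  Every concept needs at least one pattern.
concepts:
  wheezing:
    - wheezing
    - wheeze
    - wheezes
    - wheezy
    - audible wheezing
  cough:
    - cough
    - coughing
    - coughs
    - persistent cough
    - chronic cough
  dyspnea:
    - dyspnea
    - dyspnoea
    - shortness of breath
    - short of breath
    - breathlessness
  wheeze_on_exam:
    - wheezing on exam
    - wheezing on examination
    - wheezing at examination
    - wheezes on auscultation
    - expiratory wheezes on auscultation
    - wheezing heard on lung exam
  symptom_variability:
    - substantial variability in symptoms
    - symptoms vary from time to time
    - symptoms wax and wane
    - variable symptoms from time to time
  symptom_free_weeks:
    - symptom free for weeks
    - symptom-free periods of weeks
    - periods of weeks without symptoms
    - asymptomatic for several weeks
  nocturnal_cough_wheeze:
    - sleep disturbance by nocturnal cough and wheeze
    - nocturnal cough and wheeze
    - awakened at night by cough and wheeze
    - nighttime cough and wheezing
  nasal_polyps:
    - nasal polyps
    - nasal polyposis
    - polyps in the nose
  hay_fever:
    - hay fever
    - allergic rhinitis
    - seasonal allergic rhinitis
  infantile_eczema:
    - infantile eczema
    - atopic dermatitis in infancy
    - eczema as an infant
    - childhood eczema
  antigen_triggered_symptoms:
    - cough, dyspnea, and wheezing regularly on exposure to an antigen
    - cough and wheezing on exposure to an antigen
    - symptoms on antigen exposure
  atopy_test_positive:
    - positive wheal and flare skin tests
    - positive skin test
    - positive skin tests
    - elevated serum ige
    - elevated ige
  bronchodilator_response:
    - favorable clinical response to bronchodilator
    - favorable response to bronchodilator therapy
    - good response to bronchodilator
    - symptoms improved with albuterol
  physician_asthma_dx:
    - asthma
    - bronchial asthma
    - asthma exacerbation
  # one concept per exclusion condition
  fev1_lt50_consistent_or_low_dlco:
    - fev1 consistently below 50
    - fev1 consistently less than 50% predicted
    - diminished diffusion capacity
    - reduced diffusion capacity
  foreign_body_near_index:
    - tracheobronchial foreign body
    - foreign body aspiration
    - airway foreign body
  hypogammaglobulinemia_or_immunodeficiency:
    - hypogammaglobulinemia
    - immunodeficiency disorder
    - common variable immunodeficiency
  wheeze_only_anesthesia_meds:
    - wheezing only in response to anesthesia
    - wheezing only with anesthesia
    - wheezing only after medications
    - wheezing occurring only in response to anesthesia or medications
  bullous_emphysema_or_fibrosis:
    - bullous emphysema
    - pulmonary fibrosis on chest radiograph
    - pulmonary fibrosis
  pizz_a1at:
    - pizz alpha-1 antitrypsin
    - pizz alpha 1 antitrypsin deficiency
    - pizz phenotype
  cystic_fibrosis:
    - cystic fibrosis
  other_major_chest_disease:
    - bronchiectasis
    - juvenile kyphoscoliosis
    - major chest disease

triggers:
  negation:
    - denies
    - denied
    - denying
    - "no"
    - "not"
    - without
    - negative for
    - no evidence of
    - never
  negation_window: 5
  scope_terminators:
    - but
    - however
    - except
    - although
  hypothetical:
    - "if"
    - should
    - return if
  family:
    - mother
    - father
    - family history
    - sibling
    - brother
    - sister
    - grandmother
    - grandfather
    - aunt
    - uncle

sections:
  headers:
    history of present illness: history_of_present_illness
    hpi: history_of_present_illness
    past medical history: past_medical_history
    pmh: past_medical_history
    family history: family_history
    fh: family_history
    social history: social_history
    medications: medications
    allergies: allergies
    review of systems: review_of_systems
    ros: review_of_systems
    physical exam: physical_exam
    physical examination: physical_exam
    impression: impression_assessment
    assessment: impression_assessment
    impression/assessment: impression_assessment
    diagnosis: diagnosis
    diagnoses: diagnosis
    plan: plan
  # sections from which a physician asthma diagnosis may be credited
  dx_sections:
    - diagnosis
    - impression_assessment
    - plan

abbreviations:
  - dr.
  - vs.
  - mr.
  - mrs.
  - ms.
  - pt.
  - approx.
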