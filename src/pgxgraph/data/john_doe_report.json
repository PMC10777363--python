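{
  "name": "John Doe",
  "age": 54,
  "sex": "male",
  "bmi": 26.3,
  "diagnoses": ["ADHD", "depression"],
  "prescriptions": [
    {"drug_name": "clomipramine", "drug_cas": "303-49-1", "brand_name": "Anafranil"},
    {"drug_name": "atomoxetine", "drug_cas": "83015-26-3", "brand_name": null}
  ],
  "variants": [
    {"gene": "CYP2D6", "diplotype": "*4/*6", "activity_score": 0.0},
    {"gene": "CYP2C19", "diplotype": "*17/*17", "activity_score": 3.0},
    {"gene": "CYP3A4", "diplotype": "*1A/*1B", "activity_score": null}
  ],
  "guidelines": [
    {
      "guideline_id": "gl-cyp2d6-clomipramine",
      "gene": "CYP2D6",
      "diplotype": "*4/*6",
      "metabolizer_status": "poor metabolizer",
      "drug_name": "clomipramine",
      "drug_cas": "303-49-1",
      "recommendation_text": "The risk of side effects is increased. Lower the dose to 70 percent of the standard dose and monitor the plasma concentrations of clomipramine and desmethylclomipramine.",
      "recommendation_category": "decrease dose",
      "severity": 3,
      "evidence_level": "1A",
      "source_url": "https://www.pharmgkb.org/chemical/PA449048/guidelineAnnotation",
      "effect_text": "Increased metabolism of TCAs to less active compounds compared to NMs; Lower plasma concentrations of active drug will increase probability of pharmacotherapy failure"
    },
    {
      "guideline_id": "gl-cyp2c19-clomipramine",
      "gene": "CYP2C19",
      "diplotype": "*17/*17",
      "metabolizer_status": "Ultrarapid Metabolizer",
      "drug_name": "clomipramine",
      "drug_cas": "303-49-1",
      "recommendation_text": "Avoid tertiary amine use. Consider an alternative drug not metabolized by CYP2C19.",
      "recommendation_category": "avoid",
      "severity": 2,
      "evidence_level": "1A",
      "source_url": "https://www.pharmgkb.org/chemical/PA449048/guidelineAnnotation",
      "effect_text": "Increased metabolism of tertiary amines compared to NMs; greater conversion to the secondary amine."
    },
    {
      "guideline_id": "gl-cyp2d6-atomoxetine",
      "gene": "CYP2D6",
      "diplotype": "*4/*6",
      "metabolizer_status": "PM",
      "drug_name": "atomoxetine",
      "drug_cas": "83015-26-3",
      "recommendation_text": "Start with the standard dose and be alert to side effects; plasma concentrations of atomoxetine are increased.",
      "recommendation_category": "standard",
      "severity": 1,
      "evidence_level": "1A",
      "source_url": "https://www.pharmgkb.org/chemical/PA134688071/guidelineAnnotation",
      "effect_text": "Reduced metabolism of atomoxetine leading to higher plasma concentrations."
    }
  ]
}
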