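{
  "_comment": "Original synthetic few-shot example banks (no real clinical text). 'easy': unambiguous cases; 'hard': cases needing adjudication (questionnaires, context flags); 'synthetic': machine-style paraphrases.",
  "easy": [
    {
      "segment_text": "Patient reports being homeless and sleeping in a shelter for the past month.",
      "domains": ["housing status"],
      "subcategories": ["homelessness"],
      "explanation": "An explicit, current, patient-specific statement of homelessness."
    },
    {
      "segment_text": "She is unemployed and actively looking for work.",
      "domains": ["employment status"],
      "subcategories": ["unemployment"],
      "explanation": "Unemployment is stated directly about the patient in the present."
    },
    {
      "segment_text": "Pt lives alone in an apartment downtown.",
      "domains": ["social resources"],
      "subcategories": ["living alone"],
      "explanation": "Living alone is stated as the patient's current living situation."
    },
    {
      "segment_text": "Patient is on Medicaid.",
      "domains": ["health insurance status"],
      "subcategories": ["government-assisted insurance"],
      "explanation": "Medicaid enrollment is a current, confirmed government-assisted insurance status."
    },
    {
      "segment_text": "Reports significant financial hardship and is unable to pay utility bills.",
      "domains": ["general financial status"],
      "subcategories": ["financial hardship"],
      "explanation": "Financial hardship is explicit and current."
    }
  ],
  "hard": [
    {
      "segment_text": "Do you worry about food running out before you can buy more? Answer: yes.",
      "domains": ["food security status"],
      "subcategories": ["food insecurity"],
      "explanation": "A questionnaire pair: the affirmative answer to the food-worry question establishes current food insecurity."
    },
    {
      "segment_text": "Do you worry about food running out before you can buy more? Answer: ___",
      "domains": ["none of the above"],
      "subcategories": ["N/A"],
      "explanation": "The questionnaire answer is missing, so no finding can be assigned despite the question text."
    },
    {
      "segment_text": "Social worker discussed applying for public housing with the patient.",
      "domains": ["none of the above"],
      "subcategories": ["N/A"],
      "explanation": "A housing application under discussion is hypothetical, not a current housing status."
    },
    {
      "segment_text": "Her mother is unemployed and recently moved in with the patient.",
      "domains": ["social resources"],
      "subcategories": ["living with or accompanied by someone"],
      "explanation": "The unemployment belongs to the mother (experiencer: other), but the move establishes that the patient lives with someone."
    },
    {
      "segment_text": "Patient denies being homeless but is behind on rent.",
      "domains": ["housing status"],
      "subcategories": ["housing instability"],
      "explanation": "Homelessness is negated; being behind on rent is a current, affirmed housing-instability finding."
    }
  ],
  "synthetic": [
    {
      "segment_text": "Subject indicates absence of stable employment at present time.",
      "domains": ["employment status"],
      "subcategories": ["unemployment"],
      "explanation": "A paraphrase of current unemployment."
    },
    {
      "segment_text": "Individual currently without health coverage of any kind.",
      "domains": ["health insurance status"],
      "subcategories": ["lack of insurance"],
      "explanation": "Uninsured status stated in paraphrased form."
    },
    {
      "segment_text": "Resides by self; no cohabitants reported.",
      "domains": ["social resources"],
      "subcategories": ["living alone"],
      "explanation": "Living alone expressed telegraphically."
    },
    {
      "segment_text": "Engages in structured exercise on a regular weekly schedule.",
      "domains": ["physical activity"],
      "subcategories": ["physically active"],
      "explanation": "Regular exercise indicates a physically active status."
    },
    {
      "segment_text": "No social or financial stressors identified at this visit.",
      "domains": ["none of the above"],
      "subcategories": ["N/A"],
      "explanation": "An explicit negative screen yields no positive finding."
    }
  ]
}
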