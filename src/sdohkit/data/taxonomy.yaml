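# Default two-level SDoH taxonomy: 7 domains, 23 subcategories.
# Eleven subcategory names are attested in the clinical SDoH literature this
# schema follows; the rest are marked `placeholder: true` and may be renamed
# freely by editing this file — all code is name-agnostic.
sentinels:
  domain: "none of the above"
  subcategory: "N/A"
domains:
  general financial status:
    - name: financial hardship
    - name: financial stability
      placeholder: true
    - name: financial strain from medical costs
      placeholder: true
  employment status:
    - name: employed
      placeholder: true
    - name: unemployment
    - name: job loss
    - name: retirement
      placeholder: true
    - name: other job insecurity and employment issues
  housing status:
    - name: stable housing
      placeholder: true
    - name: housing instability
      placeholder: true
    - name: homelessness
    - name: subsidized/public housing
  health insurance status:
    - name: adequate insurance coverage
    - name: lack of insurance
    - name: government-assisted insurance
  food security status:
    - name: food security
      placeholder: true
    - name: food insecurity
  social resources:
    - name: living with or accompanied by someone
    - name: living alone
    - name: good social resources
    - name: poor social resources
  physical activity:
    - name: physically active
      placeholder: true
    - name: physically inactive
      placeholder: true
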