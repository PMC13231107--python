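# Demonstration SDoH lexicon (original, illustrative — not a curated clinical vocabulary).
# pattern	match_kind	case_sensitive	target_subcategory	provenance
financial hardship	literal	false	financial hardship	seed
financial difficulties	literal	false	financial hardship	expanded
cannot afford	literal	false	financial hardship	expanded
financially stable	literal	false	financial stability	seed
medical bills	literal	false	financial strain from medical costs	seed
currently employed	literal	false	employed	seed
works full-time	literal	false	employed	expanded
unemployed	literal	false	unemployment	seed
laid off	literal	false	job loss	seed
job loss	literal	false	job loss	expanded
retired	literal	false	retirement	seed
job insecurity	literal	false	other job insecurity and employment issues	seed
hours were cut	literal	false	other job insecurity and employment issues	manual
stable housing	literal	false	stable housing	seed
owns her home	literal	false	stable housing	manual
housing instability	literal	false	housing instability	seed
behind on rent	literal	false	housing instability	expanded
homeless	literal	false	homelessness	seed
homelessness	literal	false	homelessness	seed
public housing	literal	false	subsidized/public housing	seed
section[ -]?8	regex	false	subsidized/public housing	expanded
adequate insurance	literal	false	adequate insurance coverage	seed
well insured	literal	false	adequate insurance coverage	manual
uninsured	literal	false	lack of insurance	seed
no health insurance	literal	false	lack of insurance	expanded
medicaid	literal	false	government-assisted insurance	seed
masshealth	literal	false	government-assisted insurance	expanded
food secure	literal	false	food security	seed
enough food	literal	false	food security	expanded
food insecurity	literal	false	food insecurity	seed
food running out	literal	false	food insecurity	expanded
WIC	literal	true	food insecurity	manual
lives with	literal	false	living with or accompanied by someone	seed
lives alone	literal	false	living alone	seed
living alone	literal	false	living alone	seed
strong support system	literal	false	good social resources	seed
church community	literal	false	good social resources	manual
socially isolated	literal	false	poor social resources	seed
no close friends	literal	false	poor social resources	expanded
exercises regularly	literal	false	physically active	seed
walks daily	literal	false	physically active	expanded
sedentary	literal	false	physically inactive	seed
no regular exercise	literal	false	physically inactive	expanded
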