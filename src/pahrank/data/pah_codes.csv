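condition_label,code_prefix
# Default PAH condition list: each condition commonly treated as potentially
# avoidable in residential aged care is mapped to ICD-10 code prefixes chosen
# by the package authors. Matching is by prefix after stripping dots, so J18
# covers J18.0-J18.9. This bundled list is a documented stand-in; supply your
# own CSV (condition_label,code_prefix) to use a study-specific definition.
chronic_obstructive_pulmonary_disease,J44
bronchitis,J40
bronchitis,J41
bronchitis,J42
pneumonia,J12
pneumonia,J13
pneumonia,J14
pneumonia,J15
pneumonia,J16
pneumonia,J18
congestive_heart_failure,I50
dehydration,E86
urinary_tract_infection,N39.0
urinary_tract_infection,N30
anaemia,D50
anaemia,D51
anaemia,D52
anaemia,D53
anaemia,D62
anaemia,D64
cellulitis,L03
leg_ulcers,L97
collapse_or_syncope,R55
constipation,K59.0
influenza,J09
influenza,J10
influenza,J11
fall_related_fracture_or_injury,S02
fall_related_fracture_or_injury,S12
fall_related_fracture_or_injury,S22
fall_related_fracture_or_injury,S32
fall_related_fracture_or_injury,S42
fall_related_fracture_or_injury,S52
fall_related_fracture_or_injury,S62
fall_related_fracture_or_injury,S72
fall_related_fracture_or_injury,S82
fall_related_fracture_or_injury,S92
gastroenteritis,A09
pressure_ulcer,L89
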