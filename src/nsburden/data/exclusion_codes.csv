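condition,icd_version,code_prefix
dementia,10,F01
dementia,10,F02
dementia,10,F03
dementia,10,G30
dementia,9,290
frontotemporal_lobe_disease,10,G310
frontotemporal_lobe_disease,9,3311
prion_disease,10,A81
prion_disease,9,046
autism_spectrum_disorder,10,F84
autism_spectrum_disorder,9,299
epilepsy,10,G40
epilepsy,9,345
intellectual_disability,10,F70
intellectual_disability,10,F71
intellectual_disability,10,F72
intellectual_disability,10,F73
intellectual_disability,10,F78
intellectual_disability,10,F79
intellectual_disability,9,317
intellectual_disability,9,318
intellectual_disability,9,319
multiple_sclerosis,10,G35
multiple_sclerosis,9,340
parkinsons_disease,10,G20
parkinsons_disease,9,332
stroke,10,I60
stroke,10,I61
stroke,10,I62
stroke,10,I63
stroke,9,430
stroke,9,431
stroke,9,432
stroke,9,433
stroke,9,434
traumatic_brain_injury,10,S06
traumatic_brain_injury,9,850
traumatic_brain_injury,9,851
traumatic_brain_injury,9,852
traumatic_brain_injury,9,853
traumatic_brain_injury,9,854
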