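component,weight,code_prefix
myocardial_infarction,1,I21
myocardial_infarction,1,I22
myocardial_infarction,1,I252
congestive_heart_failure,1,I099
congestive_heart_failure,1,I110
congestive_heart_failure,1,I130
congestive_heart_failure,1,I132
congestive_heart_failure,1,I255
congestive_heart_failure,1,I420
congestive_heart_failure,1,I425
congestive_heart_failure,1,I426
congestive_heart_failure,1,I427
congestive_heart_failure,1,I428
congestive_heart_failure,1,I429
congestive_heart_failure,1,I43
congestive_heart_failure,1,I50
congestive_heart_failure,1,P290
peripheral_vascular_disease,1,I70
peripheral_vascular_disease,1,I71
peripheral_vascular_disease,1,I731
peripheral_vascular_disease,1,I738
peripheral_vascular_disease,1,I739
peripheral_vascular_disease,1,I771
peripheral_vascular_disease,1,I790
peripheral_vascular_disease,1,I792
peripheral_vascular_disease,1,K551
peripheral_vascular_disease,1,K558
peripheral_vascular_disease,1,K559
peripheral_vascular_disease,1,Z958
peripheral_vascular_disease,1,Z959
cerebrovascular_disease,1,G45
cerebrovascular_disease,1,G46
cerebrovascular_disease,1,H340
cerebrovascular_disease,1,I60
cerebrovascular_disease,1,I61
cerebrovascular_disease,1,I62
cerebrovascular_disease,1,I63
cerebrovascular_disease,1,I64
cerebrovascular_disease,1,I65
cerebrovascular_disease,1,I66
cerebrovascular_disease,1,I67
cerebrovascular_disease,1,I68
cerebrovascular_disease,1,I69
dementia,1,F00
dementia,1,F01
dementia,1,F02
dementia,1,F03
dementia,1,F051
dementia,1,G30
dementia,1,G311
chronic_pulmonary_disease,1,I278
chronic_pulmonary_disease,1,I279
chronic_pulmonary_disease,1,J40
chronic_pulmonary_disease,1,J41
chronic_pulmonary_disease,1,J42
chronic_pulmonary_disease,1,J43
chronic_pulmonary_disease,1,J44
chronic_pulmonary_disease,1,J45
chronic_pulmonary_disease,1,J46
chronic_pulmonary_disease,1,J47
chronic_pulmonary_disease,1,J60
chronic_pulmonary_disease,1,J61
chronic_pulmonary_disease,1,J62
chronic_pulmonary_disease,1,J63
chronic_pulmonary_disease,1,J64
chronic_pulmonary_disease,1,J65
chronic_pulmonary_disease,1,J66
chronic_pulmonary_disease,1,J67
chronic_pulmonary_disease,1,J684
chronic_pulmonary_disease,1,J701
chronic_pulmonary_disease,1,J703
rheumatic_disease,1,M05
rheumatic_disease,1,M06
rheumatic_disease,1,M315
rheumatic_disease,1,M32
rheumatic_disease,1,M33
rheumatic_disease,1,M34
rheumatic_disease,1,M351
rheumatic_disease,1,M353
rheumatic_disease,1,M360
peptic_ulcer_disease,1,K25
peptic_ulcer_disease,1,K26
peptic_ulcer_disease,1,K27
peptic_ulcer_disease,1,K28
mild_liver_disease,1,B18
mild_liver_disease,1,K700
mild_liver_disease,1,K701
mild_liver_disease,1,K702
mild_liver_disease,1,K703
mild_liver_disease,1,K709
mild_liver_disease,1,K713
mild_liver_disease,1,K714
mild_liver_disease,1,K715
mild_liver_disease,1,K717
mild_liver_disease,1,K73
mild_liver_disease,1,K74
mild_liver_disease,1,K760
mild_liver_disease,1,K762
mild_liver_disease,1,K763
mild_liver_disease,1,K764
mild_liver_disease,1,K768
mild_liver_disease,1,K769
mild_liver_disease,1,Z944
diabetes_uncomplicated,1,E100
diabetes_uncomplicated,1,E101
diabetes_uncomplicated,1,E106
diabetes_uncomplicated,1,E108
diabetes_uncomplicated,1,E109
diabetes_uncomplicated,1,E110
diabetes_uncomplicated,1,E111
diabetes_uncomplicated,1,E116
diabetes_uncomplicated,1,E118
diabetes_uncomplicated,1,E119
diabetes_uncomplicated,1,E120
diabetes_uncomplicated,1,E121
diabetes_uncomplicated,1,E126
diabetes_uncomplicated,1,E128
diabetes_uncomplicated,1,E129
diabetes_uncomplicated,1,E130
diabetes_uncomplicated,1,E131
diabetes_uncomplicated,1,E136
diabetes_uncomplicated,1,E138
diabetes_uncomplicated,1,E139
diabetes_uncomplicated,1,E140
diabetes_uncomplicated,1,E141
diabetes_uncomplicated,1,E146
diabetes_uncomplicated,1,E148
diabetes_uncomplicated,1,E149
diabetes_complicated,2,E102
diabetes_complicated,2,E103
diabetes_complicated,2,E104
diabetes_complicated,2,E105
diabetes_complicated,2,E107
diabetes_complicated,2,E112
diabetes_complicated,2,E113
diabetes_complicated,2,E114
diabetes_complicated,2,E115
diabetes_complicated,2,E117
diabetes_complicated,2,E122
diabetes_complicated,2,E123
diabetes_complicated,2,E124
diabetes_complicated,2,E125
diabetes_complicated,2,E127
diabetes_complicated,2,E132
diabetes_complicated,2,E133
diabetes_complicated,2,E134
diabetes_complicated,2,E135
diabetes_complicated,2,E137
diabetes_complicated,2,E142
diabetes_complicated,2,E143
diabetes_complicated,2,E144
diabetes_complicated,2,E145
diabetes_complicated,2,E147
hemiplegia_paraplegia,2,G041
hemiplegia_paraplegia,2,G114
hemiplegia_paraplegia,2,G801
hemiplegia_paraplegia,2,G802
hemiplegia_paraplegia,2,G81
hemiplegia_paraplegia,2,G82
hemiplegia_paraplegia,2,G830
hemiplegia_paraplegia,2,G831
hemiplegia_paraplegia,2,G832
hemiplegia_paraplegia,2,G833
hemiplegia_paraplegia,2,G834
hemiplegia_paraplegia,2,G839
renal_disease,2,I120
renal_disease,2,I131
renal_disease,2,N032
renal_disease,2,N033
renal_disease,2,N034
renal_disease,2,N035
renal_disease,2,N036
renal_disease,2,N037
renal_disease,2,N052
renal_disease,2,N053
renal_disease,2,N054
renal_disease,2,N055
renal_disease,2,N056
renal_disease,2,N057
renal_disease,2,N18
renal_disease,2,N19
renal_disease,2,N250
renal_disease,2,Z490
renal_disease,2,Z491
renal_disease,2,Z492
renal_disease,2,Z940
renal_disease,2,Z992
malignancy,2,C00
malignancy,2,C01
malignancy,2,C02
malignancy,2,C03
malignancy,2,C04
malignancy,2,C05
malignancy,2,C06
malignancy,2,C07
malignancy,2,C08
malignancy,2,C09
malignancy,2,C10
malignancy,2,C11
malignancy,2,C12
malignancy,2,C13
malignancy,2,C14
malignancy,2,C15
malignancy,2,C16
malignancy,2,C17
malignancy,2,C18
malignancy,2,C19
malignancy,2,C20
malignancy,2,C21
malignancy,2,C22
malignancy,2,C23
malignancy,2,C24
malignancy,2,C25
malignancy,2,C26
malignancy,2,C30
malignancy,2,C31
malignancy,2,C32
malignancy,2,C33
malignancy,2,C34
malignancy,2,C37
malignancy,2,C38
malignancy,2,C39
malignancy,2,C40
malignancy,2,C41
malignancy,2,C43
malignancy,2,C45
malignancy,2,C46
malignancy,2,C47
malignancy,2,C48
malignancy,2,C49
malignancy,2,C50
malignancy,2,C51
malignancy,2,C52
malignancy,2,C53
malignancy,2,C54
malignancy,2,C55
malignancy,2,C56
malignancy,2,C57
malignancy,2,C58
malignancy,2,C60
malignancy,2,C61
malignancy,2,C62
malignancy,2,C63
malignancy,2,C64
malignancy,2,C65
malignancy,2,C66
malignancy,2,C67
malignancy,2,C68
malignancy,2,C69
malignancy,2,C70
malignancy,2,C71
malignancy,2,C72
malignancy,2,C73
malignancy,2,C74
malignancy,2,C75
malignancy,2,C76
malignancy,2,C81
malignancy,2,C82
malignancy,2,C83
malignancy,2,C84
malignancy,2,C85
malignancy,2,C88
malignancy,2,C90
malignancy,2,C91
malignancy,2,C92
malignancy,2,C93
malignancy,2,C94
malignancy,2,C95
malignancy,2,C96
malignancy,2,C97
moderate_severe_liver_disease,3,I850
moderate_severe_liver_disease,3,I859
moderate_severe_liver_disease,3,I864
moderate_severe_liver_disease,3,I982
moderate_severe_liver_disease,3,K704
moderate_severe_liver_disease,3,K711
moderate_severe_liver_disease,3,K721
moderate_severe_liver_disease,3,K729
moderate_severe_liver_disease,3,K765
moderate_severe_liver_disease,3,K766
moderate_severe_liver_disease,3,K767
metastatic_solid_tumor,6,C77
metastatic_solid_tumor,6,C78
metastatic_solid_tumor,6,C79
metastatic_solid_tumor,6,C80
aids_hiv,6,B20
aids_hiv,6,B21
aids_hiv,6,B22
aids_hiv,6,B24
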