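drug
vancomycin
piperacillin-tazobactam
cefepime
ceftriaxone
cefazolin
ceftazidime
meropenem
imipenem-cilastatin
ertapenem
levofloxacin
ciprofloxacin
moxifloxacin
azithromycin
ampicillin-sulbactam
ampicillin
amoxicillin-clavulanate
nafcillin
oxacillin
linezolid
daptomycin
metronidazole
clindamycin
gentamicin
tobramycin
amikacin
aztreonam
doxycycline
trimethoprim-sulfamethoxazole
fluconazole
micafungin
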