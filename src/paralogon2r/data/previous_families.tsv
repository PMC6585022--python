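family	chromosomes	note
MATN	1,2,8,20	matrilin family; member table in the earlier companion study
EYA	1,6,8,20	eyes-absent family; member table in the earlier companion study
HCK	1,2,8,20	Src-related tyrosine kinase family; member table in the earlier companion study
KCNS	2,8,20	delayed-rectifier potassium channel family; member table in the earlier companion study
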