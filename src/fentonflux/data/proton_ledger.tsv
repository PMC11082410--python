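rm	h_plus	h_plus_alt	co2	per_unit	conditional
Purine dRN salvage synthesis	1		0	purine	no
Proline synthesis	0		1	proline	no
Tryptophan degradation	1		0	tryptophan	no
Pyrimidine RN salvage synthesis	1		0	pyrimidine	no
Pyrimidine dRN salvage synthesis	0	1	0	pyrimidine	yes
Phospholipid synthesis-PE	0		1	PE	no
Phospholipid synthesis-PA	1		0	PA	no
Phospholipid synthesis-PI	1		0	PI	no
Phospholipid synthesis-PS	4		0	PS	no
Phospholipid degradation	0	1	0	phospholipid	yes
Mevalonate pathway	0		1	farnesyl diphosphate	no
Gluconeogenesis-specific	1		0	pyruvate	no
Sialic acid synthesis	2		0	sialic acid	no
Fatty acid transporter	1		0	fatty acid	no
Beta-oxidation	1		0	fatty acid	no
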