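type	doubling_days
BRCA_TNBC	103
BRCA_ER+	241
BRCA_HER2	162
COAD	10
HNSC	99
KIRC	667
KIRP	504
LUAD	214
PRAD	900
STAD	300
THCA	803
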