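name	n	mean	sd	min	max
onset_trio	44	46.1	9.1	26	63
onset_bank	828	61.9	11.5	26	99
father_age_trio	44	29.4	5.1	22	42
father_age_bank	689	31.4	6.9	15	67
mother_age_trio	44	26.3	4.0	20	38
mother_age_bank	689	28.2	6.1	13	50
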