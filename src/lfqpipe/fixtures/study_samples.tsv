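sample	age	gender	group	indication
Control 1	23	M	control	Pseudotumor cerebri
Control 2	28	M	control	Headaches
Control 3	32	F	control	Pseudotumor cerebri
Control 4	39	F	control	Pseudotumor cerebri
Control 5	44	F	control	Pseudotumor cerebri
A-T 1	21	F	AT	A-T patient
A-T 2	21	F	AT	A-T patient
A-T 3	26	F	AT	A-T patient
A-T 4	20	M	AT	A-T patient
A-T 5	22	M	AT	A-T patient
A-T 6	23	F	AT	A-T patient
A-T 7	20	F	AT	A-T patient
A-T 8	22	F	AT	A-T patient
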