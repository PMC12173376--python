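sample	condition
A_1	A
A_2	A
A_3	A
A_4	A
B_1	B
B_2	B
B_3	B
B_4	B
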