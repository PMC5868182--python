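900001	M:0000001	JOINTPAIN	1
900001	M:0000002	CHRONICJOINTPAIN	2
900001	M:0000003	NIGHTBLINDNESS	2
900001	M:0000004	MUSCLEWEAKNESS	3
900001	M:0000005	RHYTHMICSHAKING	4
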