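12
Properties=species:S:1:pos:R:3 energy=-227.8913603807 method=HF/sto-3g max_force_Ha_per_A=1.60e-05
C 1.3867895816 0.0000000000 -0.0000000000
C 0.6933947908 1.2009950074 0.0000000000
C -0.6933947908 1.2009950074 -0.0000000000
C -1.3867895816 -0.0000000000 -0.0000000000
C -0.6933947908 -1.2009950074 -0.0000000000
C 0.6933947908 -1.2009950074 0.0000000000
H 2.4693925621 -0.0000000000 0.0000000000
H 1.2346962811 2.1385566907 0.0000000000
H -1.2346962811 2.1385566907 -0.0000000000
H -2.4693925621 0.0000000000 0.0000000000
H -1.2346962811 -2.1385566907 0.0000000000
H 1.2346962811 -2.1385566907 -0.0000000000
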