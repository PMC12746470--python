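3
Properties=species:S:1:pos:R:3 energy=-185.0683905640 method=HF/sto-3g max_force_Ha_per_A=2.60e-07
C -0.0000000000 0.0000000000 -0.0000000000
O -0.0000000000 -0.0000000000 1.1879259048
O 0.0000000000 -0.0000000000 -1.1879259048
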