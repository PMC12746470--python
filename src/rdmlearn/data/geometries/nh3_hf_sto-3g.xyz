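4
Properties=species:S:1:pos:R:3 energy=-55.4554197786 method=HF/sto-3g max_force_Ha_per_A=1.82e-05
N 0.0000000000 -0.0000000339 0.1509651553
H -0.0000000000 0.9405642156 -0.2749853614
H 0.8145464981 -0.4702820909 -0.2749898970
H -0.8145464981 -0.4702820909 -0.2749898970
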