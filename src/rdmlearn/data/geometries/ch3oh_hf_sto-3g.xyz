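6
Properties=species:S:1:pos:R:3 energy=-113.5491932664 method=HF/sto-3g max_force_Ha_per_A=1.00e-05
C -0.0377562100 0.6563802029 -0.0000000000
O -0.0901418485 -0.7756622817 0.0000000000
H -1.0651611706 1.0248009087 0.0000000000
H 0.4666687676 1.0549446877 0.8864885283
H 0.4666687675 1.0549446877 -0.8864885283
H 0.8628216940 -1.0480082052 0.0000000000
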