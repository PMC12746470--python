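3
Properties=species:S:1:pos:R:3 energy=-74.9659011923 method=HF/sto-3g max_force_Ha_per_A=5.96e-08
O 0.0000000000 0.0000000000 0.1501682073
H -0.0000000000 0.7580806061 -0.4856341037
H 0.0000000000 -0.7580806061 -0.4856341037
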