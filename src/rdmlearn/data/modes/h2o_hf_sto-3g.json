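{"molecule": "h2o", "method": "HF/sto-3g", "n_vib": 3, "frequencies_au": [0.009886351152826135, 0.0188616288988617, 0.02000543000690851], "modes": [[-2.4127155800236807e-17, -3.113933986044952e-17, 3.628247245580661e-17], [1.1093384810968426e-08, -1.62160544078286e-07, 0.26244689845520597], [-0.2644372517583215, 0.20488944399888126, 1.3777449138634195e-07], [2.690988323592964e-16, -4.755371290309811e-17, -1.4734492141862858e-16], [0.43308828201867344, 0.5589587479846562, -0.5227900707461044], [0.5267551711221519, -0.4081370580757751, 0.43846410575543326], [4.8061207246151805e-17, 6.202732016165378e-17, -5.177753363047621e-17], [-0.4330883262143944, -0.558958101941773, -0.5227907248714757], [0.5267551340551947, -0.40813651623951813, -0.43846465464499185]], "masses_me": [29164.39289085779, 1837.4715940986719, 1837.4715940986719], "geometry_fingerprint": "3c38a3c26ffb1a62"}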