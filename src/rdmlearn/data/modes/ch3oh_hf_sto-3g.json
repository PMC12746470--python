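{"molecule": "ch3oh", "method": "HF/sto-3g", "n_vib": 12, "frequencies_au": [0.0018158488074811235, 0.005506204319821763, 0.005959346362855937, 0.005997852809439256, 0.007850094160498113, 0.008060139119466478, 0.00826693470552114, 0.008339798746397627, 0.01602077354180645, 0.016763761151657498, 0.01692569070584198, 0.019263308346050594], "modes": [[4.207679727321559e-08, -0.2850474583103343, -3.873931274449919e-07, -0.08736799047749283, 0.3134003936286637, -0.08618355467111206, 8.838869344140682e-07, 0.17622821704956784, 0.03128407983483339, -4.197901981309194e-09, 0.3140712301133108, -0.011091433644659211], [-5.138773988452062e-08, 0.1373375087397631, -1.1179665959388034e-06, -0.5989361351153535, 0.03354906054732527, 0.4557845562574623, -2.2853392303233033e-06, 0.08549451138797562, 0.17555507089418493, -2.033175209290111e-08, -0.018436595811847846, -0.015061161907439473], [0.015151355350364487, -2.5820388505277114e-07, 0.4099526059599422, -7.776166814116085e-07, 4.5772593138717e-08, 1.2279030635629782e-06, 0.21378256031723625, -4.6477745147775816e-07, 1.27655251401307e-08, 0.3141586134250396, 5.913184268494424e-09, -1.1442585207837024e-08], [-1.2078115648256497e-08, 0.07050976081144479, 1.326843139527176e-07, 0.037663783051545274, -0.2695597862627242, 0.03221200299688293, -5.032816069479422e-08, 0.05024323316286068, 0.0003225997793720887, -7.66421935930296e-09, -0.007842981343729806, -0.22963703487523274], [2.2198235893553982e-08, -0.2592792922508341, 9.965156005697524e-07, 0.6314633382425822, -0.15626547833603427, -0.030509666814147716, 3.059703143403071e-07, 0.014346761893786116, 0.0019102974969910807, 6.4467487713248145e-09, 0.0013688798352105935, 0.08356010586964426], [-0.24133720800193867, 1.4490985932167933e-07, -0.2129804457930691, 3.9650936511427186e-07, -4.8955658504758e-09, 5.492683462253764e-08, 0.02284062612778243, -5.8788408847386565e-08, -3.6785866872504415e-09, -5.794039240833237e-05, 2.8825615013182665e-10, -5.27596057576409e-09], [5.37550359054537e-10, 0.1330679307563208, 1.772351621445988e-07, 0.013978996433395424, -0.028209512567908327, -0.2455653919398741, 1.5509813843214751e-06, 0.12057430890141084, 0.4446828804744991, -3.209592076384942e-09, -0.7875295118767751, 0.013891198715980367], [-3.890086421464345e-08, 0.6340803265568765, 4.7597111474908874e-07, -0.07149574677046341, -0.36026826414997465, -0.4692001539987544, 2.887011206227488e-06, 0.2411963268517619, -0.16160211311079045, 4.766033273911288e-09, 0.2782118919794042, -0.003780915100725881], [0.287228138534546, -1.44178690275903e-10, -0.21631601449357268, 4.284127666002545e-07, -1.0856516353202934e-07, -3.85721696533663e-06, -0.7226558945587395, 1.5995090821923866e-06, 1.9610015530123888e-08, 0.00560828207729428, -1.1096905658622544e-09, 2.472493376846306e-08], [0.22920211611267974, 0.2032633792727413, 0.04672819115362545, 0.06661376378121968, -0.08171719446657846, 0.21931124017746823, 0.3865920399202232, -0.4580157427392786, -0.2787083818280373, -0.3141808302884411, -0.14320524306911112, 0.005290739927437528], [-0.034033654928926106, -0.24643722798285664, 0.5830507511672745, -0.29487515320819, 0.04336497567319075, -0.4262803154943645, -0.2515976054842209, -0.2526337873280813, -0.22133497815431893, -0.23899660611005288, -0.11215300387482934, 0.00029952072773118543], [-0.11483764220922194, -0.036455764987759584, -0.16612508034516976, 0.002558896444334786, 0.08143133985397123, 0.1125097161263231, -0.05485152986905937, 0.40683968507857016, -0.4954319848987587, -0.5429546676484379, -0.2614557931606291, 0.006667623462569034], [-0.229202188448672, 0.2032631792301524, -0.04672768414562967, 0.0666139460116325, -0.08171730438929665, 0.2193070819312617, -0.3865964997948779, -0.4580140434046092, -0.2787083346606405, 0.314180853647968, -0.1432052328432904, 0.005290744250689653], [0.03403382411793993, -0.2464361432362932, -0.5830520736016829, -0.29487296195581947, 0.043365002590522554, -0.42627786435407644, 0.2516011270030255, -0.2526349139628756, -0.22133497391000362, 0.23899665674673776, -0.11215299118510863, 0.0002994748560823966], [-0.11483762053702366, 0.03645595546690295, -0.16612497241647303, -0.0025582714816966058, -0.08143136972313342, -0.11251041108562204, -0.05485210681166571, -0.40683945610201777, 0.4954319299647521, -0.5429547208121415, 0.26145577221319477, -0.0066675937613017225], [-2.5327965634993862e-08, 0.1634545180102233, 1.243921612490039e-07, 0.00432821783746413, 0.18373275722402932, -0.023886837659042096, 5.830207784917402e-08, -0.013035838925800302, 0.0034588163261220608, 2.4874866683858445e-08, 0.021040942956832252, 0.9286811901035941], [-4.1339489556340985e-08, 0.4176776297108409, 7.354929477642197e-07, 0.21298525975325194, 0.7802870994266973, -0.13001877910270737, 2.612758526597449e-07, -0.08820396605383822, -0.009338604584346768, -1.0903022871736525e-08, 0.004281973671830395, -0.27772934943701544], [0.8516264308180939, 1.2364465048843114e-07, -0.018045065384139938, 5.120472910868819e-08, -6.470194324381908e-11, 9.473992201810446e-08, 0.0034052336663460293, 1.0095062692331669e-08, 5.9139446892401825e-09, -0.003914953965075759, 4.969477657654328e-10, 6.091833078285871e-09]], "masses_me": [21894.713607856298, 29164.39289085779, 1837.4715940986719, 1837.4715940986719, 1837.4715940986719, 1837.4715940986719], "geometry_fingerprint": "a0ce7f9edb1c398d"}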