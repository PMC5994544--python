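glycerophospholipid	Glycerophospholipid metabolism (synthetic toy graph)	C00157	C04230	C00350	C00588	C01233
linoleic_acid	Linoleic acid metabolism (synthetic toy graph)	C01595	C06426	C16342	C00219	C04056
arachidonic_acid	Arachidonic acid metabolism (synthetic toy graph)	C00219	C00909	C02165	C05956
tryptophan	Tryptophan / kynurenine metabolism (synthetic toy graph)	C00078	C00328	C01717	C00780	C05635
arginine_biosynthesis	Arginine / citrulline metabolism (synthetic toy graph)	C00327	C00062	C00077	C00169	C00049	C00122
creatine	Creatine / creatinine metabolism (synthetic toy graph)	C00791	C00300	C02305	C00062
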