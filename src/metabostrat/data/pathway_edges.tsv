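pathway_id	source	target
glycerophospholipid	C00588	C00157
glycerophospholipid	C00157	C04230
glycerophospholipid	C00157	C00350
glycerophospholipid	C00350	C01233
linoleic_acid	C01595	C06426
linoleic_acid	C06426	C00219
linoleic_acid	C01595	C16342
linoleic_acid	C01595	C04056
arachidonic_acid	C00219	C00909
arachidonic_acid	C00219	C02165
arachidonic_acid	C00219	C05956
tryptophan	C00078	C00328
tryptophan	C00328	C01717
tryptophan	C00078	C00780
tryptophan	C00780	C05635
arginine_biosynthesis	C00169	C00327
arginine_biosynthesis	C00077	C00327
arginine_biosynthesis	C00049	C00327
arginine_biosynthesis	C00327	C00062
arginine_biosynthesis	C00062	C00122
creatine	C00062	C00300
creatine	C00300	C02305
creatine	C00300	C00791
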