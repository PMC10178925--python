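variable	unit	weight
pH	-	1.028E-1
conductivity	uS/cm	6.769E-5
temperature	degC	-6.12E-2
DIC	mg C/L	2.037E-4
DOC	mg C/L	7.199E-3
DO	ppm	1.746E-1
Fe(II)	ppm	-2.610E-2
sulfide	ppb	-9.36E-5
phosphate	ppm	-2.242E-2
ammonia	ppm	-1.615E-3
Mg	ppb	-2.57E-5
Co	ppb	-2.01E-2
Ni	ppb	2.39E-2
Cu	ppb	2.89E-3
Zn	ppb	-2.77E-3
As	ppb	-2.35E-4
Mo	ppb	-6.35E-3
Cd	ppb	-7.15E-1
W	ppb	2.44E-3
Pb	ppb	-2.35E-2
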