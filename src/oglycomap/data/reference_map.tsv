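structure	gu_amide	gu_c30	mass_printed	source
GalNAc-PA	0.8	3.0	300	standard
Man-PA	0.8	0.8	259	standard
GlcNAc-PA	1.0	2.7	300	standard
Gal-PA	1.2	0.4	259	standard
Fuc-PA	0.7	1.5	243	standard
Galβ1-3GalNAc-PA	1.7	2.4	462	standard
GlcNAcβ1-6GalNAc-PA	2.4	6.3	503	standard
Galβ1-3(Fucα1-2)GalNAc-PA	2.4	8.5	608	standard
GlcNAcβ1-3Galβ1-3(GlcNAcβ1-6)GalNAc-PA	3.0	2.9	868	standard
Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-PA	3.4	4.0	827	standard
Neu5Acα2-3Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAc-PA	3.2	4.3	1118	standard
Galβ1-3(Neu5Acα2-6)GalNAc-PA	1.6	2.3	753	standard
Fucα1-2Galβ1-3GalNAc-PA	2.4	5.3	608	Porcine stomach mucin
Galβ1-4GlcNAcβ1-4Galβ1-3(GlcNAcβ1-4Galβ1-4GlcNAcβ1-6)GalNAc-PA	6.0	5.2	1395	Porcine stomach mucin
GalNAcα1-3(Fucα1-2)Galβ1-3GalNAc-PA	3.0	12.8	811	Porcine stomach mucin
Galβ1-3GlcNAcβ1-6GalNAc-PA	2.6	6.1	665	Porcine stomach mucin
GalNAcα1-3Galβ1-3GalNAc-PA	2.6	3.0	665	Porcine stomach mucin
Galβ1-3(GlcNAcβ1-6)GalNAc-PA	3.2	4.6	665	Porcine stomach mucin
Neu5Acα2-3Galβ1-3GalNAc-PA	2.1	2.6	753	Colostrum IgA
Neu5Acα2-3Galβ1-3(Neu5Acα2-6)GalNAc-PA	2.7	2.2	1044	Colostrum IgA
Neu5Acα2-3Galβ1-3(GlcNAcβ1-6)GalNAc-PA	2.2	4.1	956	in vitro derivatization
Galβ1-3(Neu5Acα2-3Galβ1-4GlcNAcβ1-6)GalNAc-PA	3.2	4.2	1118	in vitro derivatization
Neu5Acα2-6Galβ1-3(Neu5Acα2-6)GalNAc-PA	2.7	2.3	1044	in vitro derivatization
HSO3-6GlcNAcβ1-6GalNAc-PA	2.2	6.9	583	in vitro derivatization
Galβ1-4GlcNAcβ1-4Galβ1-3(HSO3-6GlcNAcβ1-4Galβ1-4GlcNAcβ1-6)GalNAc-PA	5.6	4.9	1475	in vitro derivatization
GlcNAcβ1-3Galβ1-3(HSO3-6GlcNAcβ1-6)GalNAc-PA	2.6	3.7	948	in vitro derivatization
Galβ1-3(HSO3-6GlcNAcβ1-6)GalNAc-PA	1.5	5.2	745	in vitro derivatization
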