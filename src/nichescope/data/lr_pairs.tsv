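ligand	receptor	source
Gas6	Axl	curated
Gas6	Mertk	curated
Pros1	Axl	curated
Pros1	Tyro3	curated
Tgfb1	Tgfbr1	curated
Tgfb1	Tgfbr2	curated
Tgfb2	Tgfbr1	curated
Il4	Il4ra	curated
Il1b	Il1r1	curated
Il6	Il6ra	curated
Bmp7	Bmpr1a	curated
Bmp7	Bmpr2	curated
Tnfsf12	Tnfrsf12a	curated
Sema3d	Nrp1	curated
Sema3d	Plxna4	curated
Dll4	Notch1	curated
Jag1	Notch1	curated
Vegfa	Kdr	curated
Vegfa	Flt1	curated
Pdgfb	Pdgfrb	curated
Pdgfa	Pdgfra	curated
Igf1	Igf1r	curated
Cxcl12	Cxcr4	curated
Ccl2	Ccr2	curated
Csf1	Csf1r	curated
Spp1	Cd44	curated
Fn1	Itgb1	curated
Hgf	Met	curated
Egf	Egfr	curated
Nrg1	Erbb4	curated
Angpt1	Tek	curated
Edn1	Ednra	curated
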