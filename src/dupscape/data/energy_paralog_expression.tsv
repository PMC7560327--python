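family	paralog	localization	testis_biased	ovary_biased	long_branch
Glutaredoxin	Grx1t	undefined	1		0
Glutaredoxin	Grx1		digestive system		0
Thioredoxin reductase	Trxr-1	cytosol/mitochondrial	digestive system/testis		0
Thioredoxin reductase	Trxr-2	mitochondrial	1		1
Thioredoxin	Trx-2	nuclear	0		0
Thioredoxin	Trx-1 (dhd)	nuclear	0	1	1
Thioredoxin	TrxT/1	chromosome	1		1
Thioredoxin	CG13473	-	1		1
Heat Shock Protein 60	Hsp60	cytosol/mitochondrial	0		0
Heat Shock Protein 60	Hsp60B		1		1
Heat Shock Protein 60	Hsp60C		1	0	1
Heat Shock Protein 60	Hsp60D		1		1
Mitochondrial inner membrane translocases (Tim13)	Tim13	mitochondrial	1		1
Mitochondrial inner membrane translocases (Tim13)	CG34132		0		0
Mitochondrial inner membrane translocases (Tim13)	CG42302		1		1
Mitochondrial inner membrane translocases (Tim17)	Tim17b1	mitochondrial	1		1
Mitochondrial inner membrane translocases (Tim17)	Tim17b2		1		1
Mitochondrial inner membrane translocases (Tim17)	CG1724		1		1
Mitochondrial inner membrane translocases (Tim17)	Tim17b		0		0
P-P-bond-hydrolysis-driven protein transmembrane transporter 20	Tom20	mitochondrial	1	1	0
P-P-bond-hydrolysis-driven protein transmembrane transporter 20	tomboy20		1	0	1
P-P-bond-hydrolysis-driven protein transmembrane transporter 40	Tom40	mitochondrial	0	1	1
P-P-bond-hydrolysis-driven protein transmembrane transporter 40	tomboy40		1	0	1
Glycerol 3 phosphate dehydrogenase	Gpdh1	cytosolic	muscle specific		0
Glycerol 3 phosphate dehydrogenase	Gpdh2		1		1
Glycerol 3 phosphate dehydrogenase	Gpdh3		1		1
Glycerophosphate oxidase-1	Gpo-1	mitochondrial	muscle specific		0
Glycerophosphate oxidase-1	Gpo-3		1		1
Glycerophosphate oxidase-1	Gpo-2		1		1
Mitochondrial anion carrier protein (MACP)	Ucp4A	mitochondrial	0		0
Mitochondrial anion carrier protein (MACP)	Ucp4B		1		1
Mitochondrial anion carrier protein (MACP)	Ucp4C		1		1
Mitochondrial carrier (TC 2.A.29)	MME1	mitochondrial	1		1
Mitochondrial carrier (TC 2.A.29)	colt		0		0
Eukaryotic mitochondrial porin	porin	mitochondrial	0		0
Eukaryotic mitochondrial porin	Porin2		1		1
Hexokinase	Hex-A	cytosolic	0		0
Hexokinase	Hex-C		0		1
Hexokinase	Hex-t1		1		1
Hexokinase	Hex-t2		1		1
Malate dehydrogenase 2	Mdh2	mitochondrial	0		0
Malate dehydrogenase 2	CG10748		1		1
Malate dehydrogenase 2	CG10749		1		1
Succinate dehydrogenase subunit C	SdhC	mitochondrial	0		0
Succinate dehydrogenase subunit C	CG6629		1		1
Malic enzyme like-1	Menl-1	mitochondrial	1		1
Malic enzyme like-1	Menl-2		1		1
Malic enzyme like-1	Men-b		0		0
Malic enzyme	CG7848	mitochondrial	1		1
Malic enzyme	Men	mitochondrial/cytosol	0		0
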