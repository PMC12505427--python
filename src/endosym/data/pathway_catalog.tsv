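pathway_id	display_name	class	step_index	alternatives	synonym	canonical
isoleucine	Isoleucine	EAA	0	ilvA
isoleucine	Isoleucine	EAA	1	ilvB,ilvG,ilvI
isoleucine	Isoleucine	EAA	2	ilvC
isoleucine	Isoleucine	EAA	3	ilvD
isoleucine	Isoleucine	EAA	4	ilvE
valine	Valine	EAA	0	ilvB,ilvG,ilvI
valine	Valine	EAA	1	ilvC
valine	Valine	EAA	2	ilvD
valine	Valine	EAA	3	ilvE
leucine	Leucine	EAA	0	leuA
leucine	Leucine	EAA	1	leuC
leucine	Leucine	EAA	2	leuD
leucine	Leucine	EAA	3	leuB
leucine	Leucine	EAA	4	ilvE,tyrB
lysine	Lysine	EAA	0	lysC
lysine	Lysine	EAA	1	asd
lysine	Lysine	EAA	2	dapA
lysine	Lysine	EAA	3	dapB
lysine	Lysine	EAA	4	dapD
lysine	Lysine	EAA	5	dapC,argD
lysine	Lysine	EAA	6	dapE
lysine	Lysine	EAA	7	dapF
lysine	Lysine	EAA	8	lysA
threonine	Threonine	EAA	0	thrA,metL
threonine	Threonine	EAA	1	asd
threonine	Threonine	EAA	2	thrB
threonine	Threonine	EAA	3	thrC
methionine	Methionine	EAA	0	metC
methionine	Methionine	EAA	1	metE,metH
arginine	Arginine	EAA	0	carA
arginine	Arginine	EAA	1	carB
arginine	Arginine	EAA	2	argF,argI
arginine	Arginine	EAA	3	argG
arginine	Arginine	EAA	4	argH
histidine	Histidine	EAA	0	hisG
histidine	Histidine	EAA	1	hisE
histidine	Histidine	EAA	2	hisI
histidine	Histidine	EAA	3	hisA
histidine	Histidine	EAA	4	hisH
histidine	Histidine	EAA	5	hisF
histidine	Histidine	EAA	6	hisB
histidine	Histidine	EAA	7	hisC
histidine	Histidine	EAA	8	hisN
histidine	Histidine	EAA	9	hisD
phenylalanine	Phenylalanine (shikimate)	EAA	0	aroF,aroG,aroH
phenylalanine	Phenylalanine (shikimate)	EAA	1	aroB
phenylalanine	Phenylalanine (shikimate)	EAA	2	aroD
phenylalanine	Phenylalanine (shikimate)	EAA	3	aroE
phenylalanine	Phenylalanine (shikimate)	EAA	4	aroK,aroL
phenylalanine	Phenylalanine (shikimate)	EAA	5	aroA
phenylalanine	Phenylalanine (shikimate)	EAA	6	aroC
phenylalanine	Phenylalanine (shikimate)	EAA	7	pheA
tryptophan	Tryptophan	EAA	0	trpE
tryptophan	Tryptophan	EAA	1	trpD
tryptophan	Tryptophan	EAA	2	trpC
tryptophan	Tryptophan	EAA	3	trpA
tryptophan	Tryptophan	EAA	4	trpB
cysteine	Cysteine	non-essential AA	0	cysE
cysteine	Cysteine	non-essential AA	1	cysK,cysM
riboflavin	Riboflavin	B-vitamin	0	ribA
riboflavin	Riboflavin	B-vitamin	1	ribD
riboflavin	Riboflavin	B-vitamin	2	ribB
riboflavin	Riboflavin	B-vitamin	3	ribH
riboflavin	Riboflavin	B-vitamin	4	ribE
riboflavin	Riboflavin	B-vitamin	5	yigB
biotin	Biotin	B-vitamin	0	bioC
biotin	Biotin	B-vitamin	1	bioH
biotin	Biotin	B-vitamin	2	bioW
biotin	Biotin	B-vitamin	3	bioF
biotin	Biotin	B-vitamin	4	bioA
biotin	Biotin	B-vitamin	5	bioD
biotin	Biotin	B-vitamin	6	bioB
					ribG	ribD
					ilvN	ilvB
					ilvH	ilvI
					ilvM	ilvG
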