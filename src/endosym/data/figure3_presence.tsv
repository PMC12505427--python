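genome	gene	status	source
Karelsulcia_CW	ilvI	present	figure
Karelsulcia_CW	ilvC	present	figure
Karelsulcia_CW	ilvD	present	figure
Karelsulcia_CW	ilvE	present	figure
Karelsulcia_CW	leuA	present	figure
Karelsulcia_CW	leuC	present	figure
Karelsulcia_CW	leuD	present	figure
Karelsulcia_CW	leuB	present	figure
Karelsulcia_PL	ilvI	present	figure
Karelsulcia_PL	ilvC	present	figure
Karelsulcia_PL	ilvD	present	figure
Karelsulcia_PL	ilvE	present	figure
Karelsulcia_PL	leuA	present	figure
Karelsulcia_PL	leuC	present	figure
Karelsulcia_PL	leuD	present	figure
Karelsulcia_PL	leuB	present	figure
Vidania_CW	lysC	present	figure
Vidania_CW	asd	present	figure
Vidania_CW	dapA	present	figure
Vidania_CW	dapB	present	figure
Vidania_CW	dapD	present	figure
Vidania_CW	argD	present	text
Vidania_CW	dapE	present	figure
Vidania_CW	dapF	present	figure
Vidania_CW	lysA	present	figure
Vidania_CW	thrA	present	figure
Vidania_CW	thrB	present	figure
Vidania_CW	thrC	present	figure
Vidania_CW	metC	present	text
Vidania_CW	metE	present	text
Vidania_CW	carA	present	text
Vidania_CW	carB	present	text
Vidania_CW	argF	present	text
Vidania_CW	argG	present	text
Vidania_CW	argH	present	text
Vidania_CW	hisG	present	figure
Vidania_CW	hisE	present	figure
Vidania_CW	hisI	present	figure
Vidania_CW	hisA	present	figure
Vidania_CW	hisH	present	figure
Vidania_CW	hisF	present	figure
Vidania_CW	hisB	present	figure
Vidania_CW	hisC	present	figure
Vidania_CW	hisD	present	figure
Vidania_CW	aroG	present	text
Vidania_CW	aroB	present	figure
Vidania_CW	aroD	present	figure
Vidania_CW	aroK	present	figure
Vidania_CW	aroA	present	figure
Vidania_CW	aroC	present	figure
Vidania_CW	pheA	present	figure
Vidania_CW	trpE	present	figure
Vidania_CW	trpD	present	figure
Vidania_CW	trpC	present	figure
Vidania_CW	trpA	present	figure
Vidania_CW	trpB	present	figure
Vidania_PL	lysC	present	figure
Vidania_PL	asd	present	figure
Vidania_PL	dapA	present	figure
Vidania_PL	dapB	present	figure
Vidania_PL	dapD	present	figure
Vidania_PL	argD	present	text
Vidania_PL	dapE	present	figure
Vidania_PL	dapF	present	figure
Vidania_PL	lysA	present	figure
Vidania_PL	thrA	present	figure
Vidania_PL	thrB	present	figure
Vidania_PL	thrC	present	figure
Vidania_PL	metC	present	text
Vidania_PL	metE	present	text
Vidania_PL	carA	present	text
Vidania_PL	carB	present	text
Vidania_PL	argF	present	text
Vidania_PL	argG	present	text
Vidania_PL	argH	present	text
Vidania_PL	hisG	present	figure
Vidania_PL	hisE	present	figure
Vidania_PL	hisI	present	figure
Vidania_PL	hisA	present	figure
Vidania_PL	hisH	present	figure
Vidania_PL	hisF	present	figure
Vidania_PL	hisB	present	figure
Vidania_PL	hisC	present	figure
Vidania_PL	hisD	present	figure
Vidania_PL	aroG	present	text
Vidania_PL	aroB	present	figure
Vidania_PL	aroD	present	figure
Vidania_PL	aroE	present	text
Vidania_PL	aroK	present	figure
Vidania_PL	aroA	present	figure
Vidania_PL	aroC	present	figure
Vidania_PL	pheA	present	figure
Vidania_PL	trpE	present	figure
Vidania_PL	trpD	present	figure
Vidania_PL	trpC	present	figure
Vidania_PL	trpA	present	figure
Vidania_PL	trpB	present	figure
Purcelliella_PL	cysE	present	figure
Purcelliella_PL	cysK	present	figure
Purcelliella_PL	ribA	present	figure
Purcelliella_PL	ribD	present	figure
Purcelliella_PL	ribB	present	figure
Purcelliella_PL	ribH	present	figure
Purcelliella_PL	ribE	present	figure
Purcelliella_PL	bioB	present	text
Mirabilia_CW	cysE	present	figure
Mirabilia_CW	cysK	present	figure
Mirabilia_CW	ribA	present	figure
Mirabilia_CW	ribD	present_split	text
Mirabilia_CW	ribB	present	figure
Mirabilia_CW	ribH	present	figure
Mirabilia_CW	ribE	present	figure
Mirabilia_CW	bioC	present	figure
Mirabilia_CW	bioF	present	figure
Mirabilia_CW	bioA	present_split	text
Mirabilia_CW	bioD	present	figure
Mirabilia_CW	bioB	present	figure
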