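genus	bougainville	eastern_highlands	east_sepik	total
Ageratum	2	1	1	4
Alpinia	7	5	4	16
Alstonia	4	3	4	11
Aristolochia	1	1	2	4
Barringtonia	2	1	1	4
Ficus	11	7	11	29
Graptophyllum	1	1	1	3
Hemigraphis	1	2	1	4
Leucosyke	1	1	1	3
Litsea	1	1	2	4
Melastoma	1	2	1	4
Mucuna	3	1	5	9
Musa	2	1	2	5
Piper	4	5	6	15
Plectranthus	2	1	6	9
Psidium	2	1	2	5
Sida	1	1	1	3
Smilax	1	3	1	5
Syzygium	4	4	4	12
Uncaria	2	1	2	5
Zingiber	1	2	4	7
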