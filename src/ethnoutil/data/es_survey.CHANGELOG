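Curation log for es_survey.tsv (one line per flagged cell)
BK 021/06	local-name/ailment boundary has no case transition in source; split as Kulukir | knee pain/...
DK 39/05	area curated DK->GW so that Zingiber officinale is present in all four study areas as the narrative states; the printed table has no GW record for it. See header comment in scratch parser / methods note for the reasoning.
MS 37/04-2	voucher MS 37/04 is printed twice; second occurrence suffixed '-2' to keep ids unique (true number unknown; MS 34/04 and MS 51/04 are absent from the printed table)
MS 09/04	code cell 'RT' is ambiguous (rhizome+topical vs raw+topical); read as prep=R raw, route=T, part absent
BK 020/06	irregular code token(s) kept verbatim: 'S?'
GW 23/04	irregular code token(s) kept verbatim: 'L or B'
BK 038/06	irregular code token(s) kept verbatim: 'R or H'
DK 57/05	irregular code token(s) kept verbatim: '-'
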