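# Species from the East Sepik survey reported as previously undescribed in
# the historical PNG medicinal-plant literature, spelled as in the survey
# table (Pongamia pinnata is the survey table's name for Millettia pinnata).
Averrhoa carambola
Campnosperma brevipetiolatum
Capsicum annuum
Caryota mitis
Cascabela thevetia
Chrysopogon aciculatus
Clitoria ternatea
Curcuma longa
Cycas rumphii
Endospermum formicarium
Endospermum labios
Endospermum medullosum
Erythrina merrilliana
Hydriastele costata
Intsia bijuga
Planchonia papuana
Pongamia pinnata
Riedelia corallina
Schismatoglottis calyptrata
Sterculia shillinglawii
Tinospora arfakiana
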