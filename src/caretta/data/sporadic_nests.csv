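# Sporadic loggerhead nesting events recorded in the western and central Mediterranean
# (1870, 1990, 2001-2015). One row per recorded nesting event.
# hatching_success: % of eggs hatching ("Predated" where the nest was predated before counting).
# eggs: clutch size as reported (">78" = incomplete count).
# temperature_c: mean incubation temperature where recorded ("22-28" = reported range only).
# incubation_days: incubation duration Id.
# percent_female_min/max: estimated % female offspring range from incubation duration.
# habitat: published habitat-suitability class for the beach.
code,site,description,date,hatching_success,eggs,temperature_c,incubation_days,percent_female_min,percent_female_max,habitat
N1,Mar Menor (Spain),Possible nest,1870,,,,,,,Good
N2,Ebro delta (Spain),Dead embryo,09/1990,,,,,,,Moderate
N3,Vera (Spain),Full nest,27/07/2001,43.3,97,,58,10,72,Good
N4,Baia Domizia (Italy),Full nest (relocated),11/07/2002,49.4,92,27.5,64,0,22,Good
N5,Palombaggia (France),4 shells and 2 eggs,20/11/2002,,,,,,,Marginal
N6,Conigli (Italy),Full nest (relocated),04/06/2002,69.5,128,,77,0,0,Good
N7,Conigli (Italy),Full nest (relocated),20/06/2002,71.3,94,,69,0,5,Good
N8,Conigli (Italy),Full nest,20/06/2002,90.8,130,,73,0,2,Good
N9,Conigli (Italy),Full nest (relocated),04/07/2002,64.5,138,,65,0,16,Good
N10,Conigli (Italy),Full nest (relocated),11/07/2002,99.1,106,,64,0,21,Good
N11,Marina di Camerota (Italy),Egg remains,17/10/2004,,,,,,,Good
N12,Saint Tropez (France),Full nest (all eggs died),18/07/2006,0,141,22-28,,0,0,Marginal
N13,Puzol (Spain),Full nest (relocated),11/08/2006,36.8,>78,,>50,,,Moderate
N14,Premia de Mar (Spain),Full nest,27/10/2006,68.3,82,,,,,Marginal
N15,Conigli (Italy),Full nest (relocated),19/07/2006,67.3,110,28.8,57,10,85,Good
N16,Conigli (Italy),Full nest (relocated),23/07/2006,85.1,94,28.8,56,10,93,Good
N17,Conigli (Italy),Full nest,07/08/2006,92.6,94,27.9,67,0,10,Good
N18,Conigli (Italy),Full nest (relocated; all eggs died),26/08/2006,0,85,26.7,,0,0,Good
N19,Ogliastro (Italy),Full nest (relocated),26/07/2006,33.3,93,27.1,73,0,16,Good
N20,Lucrino (Italy),Full nest (relocated),15/07/2008,92.2,115,34.5,46,100,100,Good
N21,Malgrat de Mar (Spain),Full nest,01/10/2011,70.8,120,,,,,Marginal
N22,Ogliastro (Italy),Full nest,28/08/2012,75.3,73,,,,,Good
N23,Palinuro (Italy),Full nest,18/08/2013,62.1,132,,,,,Good
N24,Palinuro (Italy),Full nest,15/07/2013,99.0,96,28.9,56,15,93,Good
N25,Battipaglia (Italy),Full nest,12/10/2013,,110,,,,,Good
N26,Palinuro (Italy),Full nest (predated),06/12/2013,Predated,48,,,,,Good
N27,Alicante (Spain),Full nest (relocated ~200 km north),30/06/2014,79,131,29.1,59,3,57,Moderate
N28,Tarragona (Spain),Full nest (relocated; all eggs died),31/10/2014,0.0,89,,,0,0,Marginal
N29,Tarragona (Spain),Full nest,30/10/2014,62.1,58,,,,,Marginal
N30,Acciaroli (Italy),Full nest,30/07/2014,95.8,118,28.4,60,7,50,Good
N31,Capaccio (Italy),Full nest,25/08/2014,91.5,117,,,,,Good
N32,Torrevieja (Spain),Full nest (relocated),31/07/2015,52.9,85,,69,0,5,Moderate
N33,Pulpi (Spain),Full nest (relocated),17/07/2015,32.5,80,,53.5,87,100,Good
N34,Marina di Camerota (Italy),Full nest,19/06/2015,83.0,99,31.1,50,90,100,Good
N35,Marina di Camerota (Italy),Full nest,07/07/2015,80.0,60,,58,22,72,Good
N36,Ascea Marina (Italy),Full nest (relocated),18/07/2015,80.5,87,29.0,56,20,93,Good
N37,Eboli (Italy),Full nest (predated),28/08/2015,Predated,,,,,,Good
N38,Marina di Camerota (Italy),Full nest,29/07/2015,89.3,56,29.9,58,10,95,Good
N39,Ascea Marina (Italy),Full nest,29/07/2015,78.2,55,29.1,57,30,85,Good
N40,Ascea Marina (Italy),Full nest (relocated),30/07/2015,25.9,58,29.2,62,0,59,Good
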