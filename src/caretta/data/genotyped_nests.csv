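# Genetic summary of the 18 sporadic western-Mediterranean clutches with samples assayed.
# n_samples: hatchlings assayed (N33 additionally includes the sampled nesting female).
# origin: nuclear-DNA origin call for the clutch (Atlantic / Mediterranean / Mixed / Unknown).
# p_atlantic: mean probability of Atlantic assignment where a single summary value was
#   reported (blank for clutches summarised per-individual in the source figure).
# min_fathers: minimum number of fathers from parental-genotype reconstruction
#   (na = not applicable, two or fewer hatchlings sampled).
code,site,n_samples,origin,p_atlantic,min_fathers,haplotype,haplotype_origin
N3,Vera,15,Atlantic,,2,CC-A3.1,Shared
N4,Baia Domizia,1,Mediterranean,0.009,na,CC-A10.4,Atlantic
N6,Conigli,1,Unknown,0.668,na,CC-A2.1,Shared
N8,Conigli,1,Unknown,0.686,na,CC-A2.1,Shared
N9,Conigli,1,Unknown,0.781,na,CC-A2.1,Shared
N10,Conigli,1,Unknown,0.720,na,CC-A2.1,Shared
N13,Puzol,6,Mixed,,2,CC-A2.1,Shared
N14,Premia de Mar,23,Atlantic,,2,CC-A1.1,Atlantic
N15,Conigli,1,Atlantic,0.926,na,CC-A9.1,Atlantic
N16,Conigli,2,Unknown,0.576,na,CC-A2.1,Shared
N17,Conigli,2,Atlantic,0.814,na,CC-A2.1,Shared
N18,Conigli,14,Mediterranean,,1,CC-A2.1,Shared
N21,Malgrat de Mar,2,Mediterranean,0.118,na,CC-A2.1,Shared
N27,Alicante,14,Mediterranean,,2,CC-A20.1,Shared
N28,Tarragona,1,Atlantic,0.888,na,CC-A3.1,Shared
N29,Tarragona,18,Atlantic,,2,CC-A2.1,Shared
N32,Torrevieja,10,Atlantic,,2,CC-A2.1,Shared
N33,Pulpi,8,Atlantic,,1,CC-A2.1,Shared
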