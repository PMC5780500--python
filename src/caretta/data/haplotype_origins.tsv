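# mtDNA control-region haplotypes observed in western-Mediterranean sporadic nests,
# with the nesting-area class where each has been reported and its public accession.
# CC-A10.4 has been reported from an Atlantic rookery (Melbourne Beach) and a
# Mediterranean forager; its short ~380 bp form (CC-A10) also occurs in a
# Mediterranean rookery (Zakynthos), hence the Mediterranean-reported class.
name	origin_class	accession
CC-A1.1	Atlantic-exclusive	EU179436
CC-A2.1	shared	EU179445
CC-A3.1	shared	EU179455
CC-A9.1	Atlantic-exclusive	EU179463
CC-A10.4	Mediterranean-reported	JQ340912
CC-A20.1	shared	EU179452
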