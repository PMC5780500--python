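# Demographic/TSD parameters by nest temperature during the middle third of incubation.
# Columns: temperature (degrees C), incubation duration Id (days),
# percent female offspring Of (%), emergence success Es (%).
temperature_c,incubation_days,percent_female,emergence_success
28.0,63,0,90
29.1,54,25,90
29.3,53,50,90
29.5,52,75,90
31.0,47,100,75
33.0,43,100,10
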