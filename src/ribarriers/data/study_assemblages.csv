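population,guild,species,count
CO,pollinator,Cynanthus sordidus,17
CO,pollinator,Amazilia beryllina,34
CO,pollinator,Amazilia violiceps,3
CO,pollinator,Calothorax pulcher,1
AO,pollinator,Cynanthus latirostris,3
AO,pollinator,Cynanthus sordidus,5
AO,pollinator,Amazilia beryllina,39
AO,pollinator,Amazilia violiceps,4
AO,pollinator,Calothorax pulcher,8
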