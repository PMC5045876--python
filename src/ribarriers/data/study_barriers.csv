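name,stage,guild,raw_a,raw_b
Host species isolation,pre,host,0.200,0.800
Seed dispersers isolation,pre,disperser,0.400,0.600
Pollinator isolation,pre,pollinator,0.800,0.200
CO Fruit set,post,,0.185,0.814
AO Fruit set,post,,0.400,0.600
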