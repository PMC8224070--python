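species,stage,t_low_c,dd_total
Eriosoma lanigerum,instar 1,5.2,125.6
Eriosoma lanigerum,instar 2,5.2,51.0
Eriosoma lanigerum,instar 3,5.2,47.7
Eriosoma lanigerum,instar 4,5.2,50.7
Eriosoma lanigerum,total,5.2,267.6
Aphelinus mali,total,8.3,254.8
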