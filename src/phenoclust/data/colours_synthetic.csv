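label,L,a,b
white,96,0,2
pale yellow,93,-8,40
yellow,90,-10,85
orange,72,30,75
salmon,74,35,24
pink,81,24,5
red,53,70,50
dark red,38,55,35
purple,45,55,-30
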