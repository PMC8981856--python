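id,prickles,petal_colour,origin,breeding_period,flowers_per_volume
R001,Low,pink,NW France,1840-1849,12
R002,Low,red,Provence,1850-1859,15
R003,Medium,dark red,Provence,1860-1869,
R004,Medium,pink,Brittany,1840-1849,14
R005,High,yellow,China,>1920,30
R006,Very high,pale yellow,China,1890-1899,28
R007,High,orange,Japan,NA,25
R008,,white,Central Europe,<1700,5
R009,Low,white,Alsace,<1700,NA
R010,Very high,salmon,Japan,1900-1909,26
R011,,purple,North America,1700-1749,
R012,Medium,red,Normandy,1830-1839,13
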