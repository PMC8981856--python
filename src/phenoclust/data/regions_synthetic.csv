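label,lat,lon,areas
Brittany,48.2,-2.9,
Normandy,49.1,0.1,
Provence,43.9,6.0,
Alsace,48.3,7.5,
NW France,,,Brittany;Normandy
Central Europe,50.1,14.4,
China,35.0,103.0,
Japan,36.2,138.3,
North America,39.8,-98.6,
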