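concept_a,concept_b,distance
Quantity of prickles,,
Few prickles,,
Many prickles,,
Low,,
Medium,,
High,,
Very high,,
Quantity of prickles,Few prickles,is_a
Quantity of prickles,Many prickles,is_a
Few prickles,Low,is_a
Few prickles,Medium,is_a
Many prickles,High,is_a
Many prickles,Very high,is_a
Low,Medium,1
Low,High,2
Low,Very high,3
Medium,High,1
Medium,Very high,2
High,Very high,1
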