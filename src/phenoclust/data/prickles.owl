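<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF
   xmlns="http://phenoclust.org/onto#"
   xmlns:owl="http://www.w3.org/2002/07/owl#"
   xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
   xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
>
  <rdf:Description rdf:about="http://phenoclust.org/onto#Low">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Low</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://phenoclust.org/onto#Few%20prickles"/>
    <has_distance rdf:resource="http://phenoclust.org/onto#Medium"/>
    <has_distance rdf:resource="http://phenoclust.org/onto#Very%20high"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#Medium">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Medium</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://phenoclust.org/onto#Few%20prickles"/>
    <has_distance rdf:resource="http://phenoclust.org/onto#Very%20high"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#axiom_4">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Axiom"/>
    <owl:annotatedSource rdf:resource="http://phenoclust.org/onto#Low"/>
    <owl:annotatedProperty rdf:resource="http://phenoclust.org/onto#has_distance"/>
    <owl:annotatedTarget rdf:resource="http://phenoclust.org/onto#Very%20high"/>
    <distance rdf:datatype="http://www.w3.org/2001/XMLSchema#double">6.0</distance>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#axiom_2">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Axiom"/>
    <owl:annotatedSource rdf:resource="http://phenoclust.org/onto#High"/>
    <owl:annotatedProperty rdf:resource="http://phenoclust.org/onto#has_distance"/>
    <owl:annotatedTarget rdf:resource="http://phenoclust.org/onto#Very%20high"/>
    <distance rdf:datatype="http://www.w3.org/2001/XMLSchema#double">1.0</distance>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#Quantity%20of%20prickles">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Quantity of prickles</rdfs:label>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#axiom_0">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Axiom"/>
    <owl:annotatedSource rdf:resource="http://phenoclust.org/onto#High"/>
    <owl:annotatedProperty rdf:resource="http://phenoclust.org/onto#has_distance"/>
    <owl:annotatedTarget rdf:resource="http://phenoclust.org/onto#Low"/>
    <distance rdf:datatype="http://www.w3.org/2001/XMLSchema#double">5.0</distance>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#axiom_5">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Axiom"/>
    <owl:annotatedSource rdf:resource="http://phenoclust.org/onto#Medium"/>
    <owl:annotatedProperty rdf:resource="http://phenoclust.org/onto#has_distance"/>
    <owl:annotatedTarget rdf:resource="http://phenoclust.org/onto#Very%20high"/>
    <distance rdf:datatype="http://www.w3.org/2001/XMLSchema#double">5.0</distance>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#Very%20high">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Very high</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://phenoclust.org/onto#Many%20prickles"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#High">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>High</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://phenoclust.org/onto#Many%20prickles"/>
    <has_distance rdf:resource="http://phenoclust.org/onto#Low"/>
    <has_distance rdf:resource="http://phenoclust.org/onto#Medium"/>
    <has_distance rdf:resource="http://phenoclust.org/onto#Very%20high"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#Few%20prickles">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Few prickles</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://phenoclust.org/onto#Quantity%20of%20prickles"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#axiom_3">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Axiom"/>
    <owl:annotatedSource rdf:resource="http://phenoclust.org/onto#Low"/>
    <owl:annotatedProperty rdf:resource="http://phenoclust.org/onto#has_distance"/>
    <owl:annotatedTarget rdf:resource="http://phenoclust.org/onto#Medium"/>
    <distance rdf:datatype="http://www.w3.org/2001/XMLSchema#double">1.0</distance>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#Many%20prickles">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Many prickles</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://phenoclust.org/onto#Quantity%20of%20prickles"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#distance">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#DatatypeProperty"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#axiom_1">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Axiom"/>
    <owl:annotatedSource rdf:resource="http://phenoclust.org/onto#High"/>
    <owl:annotatedProperty rdf:resource="http://phenoclust.org/onto#has_distance"/>
    <owl:annotatedTarget rdf:resource="http://phenoclust.org/onto#Medium"/>
    <distance rdf:datatype="http://www.w3.org/2001/XMLSchema#double">4.0</distance>
  </rdf:Description>
  <rdf:Description rdf:about="http://phenoclust.org/onto#has_distance">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#ObjectProperty"/>
  </rdf:Description>
</rdf:RDF>
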