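# Domain schema (TBox) for lignocellulose-enzyme literature mining.
# Instance data (ABox) is produced at run time by the ontology module.
@prefix ligno: <https://w3id.org/lignominer/onto#> .
@prefix owl:   <http://www.w3.org/2002/07/owl#> .
@prefix rdfs:  <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd:   <http://www.w3.org/2001/XMLSchema#> .

ligno:Document  a owl:Class .
ligno:Sentence  a owl:Class .
ligno:Entity    a owl:Class .
ligno:Enzyme    a owl:Class ; rdfs:subClassOf ligno:Entity .
ligno:Organism  a owl:Class ; rdfs:subClassOf ligno:Entity .
ligno:Host      a owl:Class ; rdfs:subClassOf ligno:Organism .
ligno:Gene      a owl:Class ; rdfs:subClassOf ligno:Entity .
ligno:Substrate a owl:Class ; rdfs:subClassOf ligno:Entity .
ligno:Assay     a owl:Class ; rdfs:subClassOf ligno:Entity .
ligno:Strain    a owl:Class ; rdfs:subClassOf ligno:Entity .

ligno:inDocument   a owl:ObjectProperty ; rdfs:range ligno:Document .
ligno:mentionedIn  a owl:ObjectProperty ; rdfs:domain ligno:Entity ; rdfs:range ligno:Sentence .
ligno:fromOrganism a owl:ObjectProperty ; rdfs:domain ligno:Enzyme ; rdfs:range ligno:Organism .
ligno:hasStrain    a owl:ObjectProperty ; rdfs:domain ligno:Organism ; rdfs:range ligno:Strain .
ligno:encodes      a owl:ObjectProperty ; rdfs:domain ligno:Gene ; rdfs:range ligno:Enzyme .

ligno:docId                 a owl:DatatypeProperty ; rdfs:range xsd:string .
ligno:ecNumber              a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:string .
ligno:recommendedName       a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:string .
ligno:systematicName        a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:string .
ligno:swissProtId           a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:string .
ligno:taxId                 a owl:DatatypeProperty ; rdfs:domain ligno:Organism ; rdfs:range xsd:string .
ligno:hasOptimalTemperature a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:double .
ligno:hasOptimalPH          a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:double .
ligno:hasSpecificActivity   a owl:DatatypeProperty ; rdfs:domain ligno:Enzyme ; rdfs:range xsd:double .
ligno:charStart             a owl:DatatypeProperty ; rdfs:domain ligno:Sentence ; rdfs:range xsd:integer .
ligno:charEnd               a owl:DatatypeProperty ; rdfs:domain ligno:Sentence ; rdfs:range xsd:integer .
ligno:hasMentionSpan        a owl:DatatypeProperty ; rdfs:range xsd:string .
ligno:externalLink          a owl:ObjectProperty .
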