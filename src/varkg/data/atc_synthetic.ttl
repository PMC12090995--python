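@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix uatc: <http://purl.bioontology.org/ontology/UATC/> .

<http://example.org/notatc/1> a owl:Class .

<http://example.org/notatc/2> a owl:Class .

<http://example.org/notatc/3> a owl:Class .

uatc:A05BB03 a owl:Class ;
    rdfs:label "Synthdrug 3" .

uatc:A05BD02 a owl:Class ;
    rdfs:label "Synthdrug 2" .

uatc:A05BE04 a owl:Class ;
    rdfs:label "Synthdrug 4" .

uatc:A07BD01 a owl:Class ;
    rdfs:label "Synthdrug 1" .

uatc:B01AC06 a owl:Class ;
    rdfs:label "Aspirin" .

uatc:Z99ZA01 a owl:Class ;
    rdfs:label "Unused ATC class 1" .

uatc:Z99ZB02 a owl:Class ;
    rdfs:label "Unused ATC class 2" .

uatc:Z99ZC03 a owl:Class ;
    rdfs:label "Unused ATC class 3" .

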