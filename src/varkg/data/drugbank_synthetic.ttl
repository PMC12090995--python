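@prefix atc: <http://bio2rdf.org/atc:> .
@prefix bio2rdf: <http://bio2rdf.org/bio2rdf_vocabulary:> .
@prefix drugbank: <http://bio2rdf.org/drugbank:> .
@prefix drugbank_vocabulary: <http://bio2rdf.org/drugbank_vocabulary:> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

drugbank:DB00945 rdfs:label "Aspirin" ;
    bio2rdf:identifier "DB00945" ;
    drugbank_vocabulary:x-atc atc:B01AC06 .

drugbank:DB10001 rdfs:label "Synthdrug 1" ;
    bio2rdf:identifier "DB10001" ;
    drugbank_vocabulary:x-atc atc:A07BD01 .

drugbank:DB10002 rdfs:label "Synthdrug 2" ;
    bio2rdf:identifier "DB10002" ;
    drugbank_vocabulary:x-atc atc:A05BD02 .

drugbank:DB10003 rdfs:label "Synthdrug 3" ;
    bio2rdf:identifier "DB10003" ;
    drugbank_vocabulary:x-atc atc:A05BB03 .

drugbank:DB10004 rdfs:label "Synthdrug 4" ;
    bio2rdf:identifier "DB10004" ;
    drugbank_vocabulary:x-atc atc:A05BE04 .

drugbank:DB20001 rdfs:label "Orphan drug 1" ;
    bio2rdf:identifier "DB20001" ;
    drugbank_vocabulary:x-atc atc:X00XX01 .

drugbank:DB20002 rdfs:label "Orphan drug 2" ;
    bio2rdf:identifier "DB20002" ;
    drugbank_vocabulary:x-atc atc:X00XX02 .

drugbank:DB20003 rdfs:label "Orphan drug 3" ;
    bio2rdf:identifier "DB20003" ;
    drugbank_vocabulary:x-atc atc:X00XX03 .

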