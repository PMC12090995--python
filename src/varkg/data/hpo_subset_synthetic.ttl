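@prefix HP: <http://purl.obolibrary.org/obo/HP_> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

HP:0000252 rdfs:label "Microcephaly" ;
    rdfs:subClassOf HP:0000118 .

HP:0000256 rdfs:label "Macrocephaly" ;
    rdfs:subClassOf HP:0000118 .

HP:0000365 rdfs:label "Hearing impairment" ;
    rdfs:subClassOf HP:0000118 .

HP:0000486 rdfs:label "Strabismus" ;
    rdfs:subClassOf HP:0000118 .

HP:0000505 rdfs:label "Visual impairment" ;
    rdfs:subClassOf HP:0000118 .

HP:0000618 rdfs:label "Blindness" ;
    rdfs:subClassOf HP:0000118 .

HP:0000750 rdfs:label "Delayed speech and language development" ;
    rdfs:subClassOf HP:0000118 .

HP:0001249 rdfs:label "Intellectual disability" ;
    rdfs:subClassOf HP:0000118 .

HP:0001250 rdfs:label "Seizure" ;
    rdfs:subClassOf HP:0000118 .

HP:0001252 rdfs:label "Hypotonia" ;
    rdfs:subClassOf HP:0000118 .

HP:0001263 rdfs:label "Global developmental delay" ;
    rdfs:subClassOf HP:0000118 .

HP:0001344 rdfs:label "Absent speech" ;
    rdfs:subClassOf HP:0000118 .

HP:0001382 rdfs:label "Joint hypermobility" ;
    rdfs:subClassOf HP:0000118 .

HP:0001508 rdfs:label "Failure to thrive" ;
    rdfs:subClassOf HP:0000118 .

HP:0001631 rdfs:label "Atrial septal defect" ;
    rdfs:subClassOf HP:0000118 .

HP:0002119 rdfs:label "Ventriculomegaly" ;
    rdfs:subClassOf HP:0000118 .

HP:0002360 rdfs:label "Sleep abnormality" ;
    rdfs:subClassOf HP:0000118 .

HP:0002650 rdfs:label "Scoliosis" ;
    rdfs:subClassOf HP:0000118 .

HP:0004322 rdfs:label "Short stature" ;
    rdfs:subClassOf HP:0000118 .

HP:0100704 rdfs:label "Cerebral visual impairment" ;
    rdfs:subClassOf HP:0000118 .

HP:0900001 rdfs:label "Synthetic phenotype 1" ;
    rdfs:subClassOf HP:0000118 .

HP:0900002 rdfs:label "Synthetic phenotype 2" ;
    rdfs:subClassOf HP:0000118 .

HP:0900003 rdfs:label "Synthetic phenotype 3" ;
    rdfs:subClassOf HP:0000118 .

HP:0900004 rdfs:label "Synthetic phenotype 4" ;
    rdfs:subClassOf HP:0000118 .

HP:0900005 rdfs:label "Synthetic phenotype 5" ;
    rdfs:subClassOf HP:0000118 .

HP:0900006 rdfs:label "Synthetic phenotype 6" ;
    rdfs:subClassOf HP:0000118 .

HP:0900007 rdfs:label "Synthetic phenotype 7" ;
    rdfs:subClassOf HP:0000118 .

HP:0900008 rdfs:label "Synthetic phenotype 8" ;
    rdfs:subClassOf HP:0000118 .

HP:0900009 rdfs:label "Synthetic phenotype 9" ;
    rdfs:subClassOf HP:0000118 .

HP:0900010 rdfs:label "Synthetic phenotype 10" ;
    rdfs:subClassOf HP:0000118 .

HP:0000001 rdfs:label "All" .

HP:0000118 rdfs:label "Phenotypic abnormality" ;
    rdfs:subClassOf HP:0000001 .

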