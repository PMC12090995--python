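@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

<https://w3id.org/varkg/vocab/consequence/frameshift_variant> rdfs:label "frameshift variant" .

<https://w3id.org/varkg/vocab/consequence/intron_variant> rdfs:label "intron variant" .

<https://w3id.org/varkg/vocab/consequence/missense_variant> rdfs:label "missense variant" .

<https://w3id.org/varkg/vocab/consequence/splice_donor_variant> rdfs:label "splice donor variant" .

<https://w3id.org/varkg/vocab/consequence/stop_gained> rdfs:label "stop gained" .

<https://w3id.org/varkg/vocab/consequence/synonymous_variant> rdfs:label "synonymous variant" .

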