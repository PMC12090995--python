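@prefix compound: <http://rdf.ncbi.nlm.nih.gov/pubchem/compound/> .
@prefix sio: <http://semanticscience.org/resource/> .

compound:CID10001_cas_attr a sio:CHEMINF_000446 ;
    sio:SIO_000011 compound:CID10001 ;
    sio:SIO_000300 "67113-72-6" .

compound:CID10001_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID10001 ;
    sio:SIO_000300 "DB10001" .

compound:CID10002_cas_attr a sio:CHEMINF_000446 ;
    sio:SIO_000011 compound:CID10002 ;
    sio:SIO_000300 "28731-74-2" .

compound:CID10002_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID10002 ;
    sio:SIO_000300 "DB10002" .

compound:CID10003_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID10003 ;
    sio:SIO_000300 "DB10003" .

compound:CID10004_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID10004 ;
    sio:SIO_000300 "DB10004" .

compound:CID20001_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID20001 ;
    sio:SIO_000300 "DB20001" .

compound:CID20002_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID20002 ;
    sio:SIO_000300 "DB20002" .

compound:CID20003_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID20003 ;
    sio:SIO_000300 "DB20003" .

compound:CID2244_cas_attr a sio:CHEMINF_000446 ;
    sio:SIO_000011 compound:CID2244 ;
    sio:SIO_000300 "50-78-2" .

compound:CID2244_drugbank_attr a sio:CHEMINF_000406 ;
    sio:SIO_000011 compound:CID2244 ;
    sio:SIO_000300 "DB00945" .

compound:CID30001_cas_attr a sio:CHEMINF_000446 ;
    sio:SIO_000011 compound:CID30001 ;
    sio:SIO_000300 "111-21-3" .

compound:CID30002_cas_attr a sio:CHEMINF_000446 ;
    sio:SIO_000011 compound:CID30002 ;
    sio:SIO_000300 "111-22-3" .

compound:CID30003_cas_attr a sio:CHEMINF_000446 ;
    sio:SIO_000011 compound:CID30003 ;
    sio:SIO_000300 "111-23-3" .

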