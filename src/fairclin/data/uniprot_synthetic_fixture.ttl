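# Synthetic protein-annotation fixture graph shaped like UniProt RDF.
# A desk-scale stand-in for the live UniProt knowledgebase, NOT a mirror:
# ten human cytokine proteins with preferred name and organism, each
# linked (rdfs:seeAlso) from the measurement-datum term of the analyte it
# annotates in the shipped default analyte->ontology mapping.
@prefix efo: <http://www.ebi.ac.uk/efo/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .
@prefix uniprot: <http://purl.uniprot.org/uniprot/> .
@prefix up: <http://purl.uniprot.org/core/> .
@prefix uptaxon: <http://purl.uniprot.org/taxonomy/> .

uptaxon:9606 up:scientificName "Homo sapiens" .

# analyte IL-6
efo:EFO_090008 rdfs:seeAlso uniprot:P05231 .
uniprot:P05231 a up:Protein ;
    skos:prefLabel "Interleukin-6" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P05231> .

# analyte IL-8
efo:EFO_090010 rdfs:seeAlso uniprot:P10145 .
uniprot:P10145 a up:Protein ;
    skos:prefLabel "Interleukin-8" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P10145> .

# analyte IL-10
efo:EFO_090012 rdfs:seeAlso uniprot:P22301 .
uniprot:P22301 a up:Protein ;
    skos:prefLabel "Interleukin-10" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P22301> .

# analyte IL-2
efo:EFO_090004 rdfs:seeAlso uniprot:P60568 .
uniprot:P60568 a up:Protein ;
    skos:prefLabel "Interleukin-2" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P60568> .

# analyte IL-4
efo:EFO_090006 rdfs:seeAlso uniprot:P05112 .
uniprot:P05112 a up:Protein ;
    skos:prefLabel "Interleukin-4" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P05112> .

# analyte TNF-alpha
efo:EFO_090036 rdfs:seeAlso uniprot:P01375 .
uniprot:P01375 a up:Protein ;
    skos:prefLabel "Tumor necrosis factor" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P01375> .

# analyte IFN-gamma
efo:EFO_090053 rdfs:seeAlso uniprot:P01579 .
uniprot:P01579 a up:Protein ;
    skos:prefLabel "Interferon gamma" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P01579> .

# analyte CXCL10
efo:EFO_090077 rdfs:seeAlso uniprot:P02778 .
uniprot:P02778 a up:Protein ;
    skos:prefLabel "C-X-C motif chemokine 10" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P02778> .

# analyte CCL2
efo:EFO_090058 rdfs:seeAlso uniprot:P13500 .
uniprot:P13500 a up:Protein ;
    skos:prefLabel "C-C motif chemokine 2" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P13500> .

# analyte GM-CSF
efo:EFO_090085 rdfs:seeAlso uniprot:P04141 .
uniprot:P04141 a up:Protein ;
    skos:prefLabel "Granulocyte-macrophage colony-stimulating factor" ;
    up:organism uptaxon:9606 ;
    rdfs:seeAlso <https://www.uniprot.org/uniprotkb/P04141> .
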