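#+ name: cytokine_protein_profile_left
#+ description: >
#+   Patient cytokine profiles with protein annotation where available
#+   (left join: unannotated cytokines are kept with empty protein columns).
#+ params: []
#+ schema:
#+   - {name: patient, type: string}
#+   - {name: date, type: date}
#+   - {name: analyte, type: iri}
#+   - {name: value, type: decimal}
#+   - {name: protein, type: iri}
#+   - {name: protein_name, type: string}
PREFIX dct: <http://purl.org/dc/terms/>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX sio: <http://semanticscience.org/resource/>
PREFIX skos: <http://www.w3.org/2004/02/skos/core#>
PREFIX up: <http://purl.uniprot.org/core/>

SELECT ?patient ?date ?analyte ?value ?protein ?protein_name
WHERE {
  ?process obo:OBI_0000299 ?datum ;
           obo:OBI_0000293 ?sample ;
           dct:date ?date .
  ?sample prov:wasDerivedFrom ?patientNode .
  ?patientNode dct:identifier ?patient .
  ?datum a ?analyte ;
         sio:SIO_000300 ?value ;
         sio:SIO_000221 ?unit .
  OPTIONAL {
    ?analyte rdfs:seeAlso ?protein .
    ?protein a up:Protein ;
             skos:prefLabel ?protein_name .
  }
}
ORDER BY ?patient ?date ?analyte ?protein
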