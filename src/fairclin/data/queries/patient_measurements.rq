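#+ name: patient_measurements
#+ description: >
#+   All measured values for one patient (by clinical identifier), with the
#+   analyte term and sampling date.
#+ params:
#+   - {name: patient_id, required: true}
#+ schema:
#+   - {name: sampling_date, type: date}
#+   - {name: analyte, type: iri}
#+   - {name: value, type: decimal}
PREFIX dct: <http://purl.org/dc/terms/>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX sio: <http://semanticscience.org/resource/>

SELECT ?sampling_date ?analyte ?value
WHERE {
  ?patientNode dct:identifier ?patient_id .
  ?sample prov:wasDerivedFrom ?patientNode ;
          dct:date ?sampling_date .
  ?process obo:OBI_0000293 ?sample ;
           obo:OBI_0000299 ?datum .
  ?datum a ?analyte ;
         sio:SIO_000300 ?value ;
         sio:SIO_000221 ?unit .
}
ORDER BY ?sampling_date ?analyte
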