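#+ name: datum_count_per_analyte
#+ description: >
#+   Number of measurement datum nodes per analyte term (measurement datums
#+   are the datum nodes carrying a unit).
#+ params: []
#+ schema:
#+   - {name: analyte, type: iri}
#+   - {name: n, type: integer}
PREFIX sio: <http://semanticscience.org/resource/>

SELECT ?analyte (COUNT(?datum) AS ?n)
WHERE {
  ?datum a ?analyte ;
         sio:SIO_000300 ?value ;
         sio:SIO_000221 ?unit .
}
GROUP BY ?analyte
ORDER BY ?analyte
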