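#+ name: count_biosamples
#+ description: Count the number of distinct biosamples (specimens) in the store.
#+ params: []
#+ schema:
#+   - {name: n, type: integer}
PREFIX obo: <http://purl.obolibrary.org/obo/>

SELECT (COUNT(DISTINCT ?sample) AS ?n)
WHERE {
  ?sample a obo:OBI_0100051 .
}
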