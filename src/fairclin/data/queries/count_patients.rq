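#+ name: count_patients
#+ description: Count the number of distinct patients with data in the store.
#+ params: []
#+ schema:
#+   - {name: n, type: integer}
PREFIX obo: <http://purl.obolibrary.org/obo/>

SELECT (COUNT(DISTINCT ?patient) AS ?n)
WHERE {
  ?patient a obo:NCIT_C16960 .
}
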