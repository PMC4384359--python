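Prefix(owl:=<http://www.w3.org/2002/07/owl#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Ontology(<http://example.org/ontologies/go-fragment.owl>
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0006915>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0006919>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0008150>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0016049>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0040008>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0042981>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0043066>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0065007>))
Declaration(Class(<http://purl.obolibrary.org/obo/GO_0097194>))
Declaration(ObjectProperty(<http://purl.obolibrary.org/obo/BFO_0000050>))
SubClassOf(<http://purl.obolibrary.org/obo/GO_0006915> <http://purl.obolibrary.org/obo/GO_0008150>)
SubClassOf(<http://purl.obolibrary.org/obo/GO_0065007> <http://purl.obolibrary.org/obo/GO_0008150>)
SubClassOf(<http://purl.obolibrary.org/obo/GO_0016049> <http://purl.obolibrary.org/obo/GO_0008150>)
SubClassOf(<http://purl.obolibrary.org/obo/GO_0097194> ObjectIntersectionOf(<http://purl.obolibrary.org/obo/GO_0008150> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/GO_0006915>)))
SubClassOf(<http://purl.obolibrary.org/obo/GO_0006919> ObjectIntersectionOf(<http://purl.obolibrary.org/obo/GO_0008150> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/GO_0097194>)))
SubClassOf(<http://purl.obolibrary.org/obo/GO_0042981> ObjectIntersectionOf(<http://purl.obolibrary.org/obo/GO_0065007> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/GO_0006915>)))
SubClassOf(<http://purl.obolibrary.org/obo/GO_0043066> ObjectIntersectionOf(<http://purl.obolibrary.org/obo/GO_0008150> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/GO_0042981>)))
SubClassOf(<http://purl.obolibrary.org/obo/GO_0040008> ObjectIntersectionOf(<http://purl.obolibrary.org/obo/GO_0065007> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/GO_0016049>)))
TransitiveObjectProperty(<http://purl.obolibrary.org/obo/BFO_0000050>)
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/BFO_0000050> "part_of")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0006915> "apoptotic process")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0006919> "caspase activation")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0008150> "biological_process")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0016049> "cell growth")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0040008> "regulation of growth")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0042981> "regulation of apoptotic process")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0043066> "apoptotic regulation checkpoint")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0065007> "regulation")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/GO_0097194> "execution phase of apoptosis")
AnnotationAssertion(<http://purl.obolibrary.org/obo/IAO_0000115> <http://purl.obolibrary.org/obo/GO_0006915> "A programmed cell death process which begins when a cell receives an internal or external signal.")
)
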