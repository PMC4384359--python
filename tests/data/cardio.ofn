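Prefix(owl:=<http://www.w3.org/2002/07/owl#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Ontology(<http://example.org/ontologies/cardio.owl>
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0001627>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0001629>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0001636>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0001642>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0001667>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0002623>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0009999>))
Declaration(Class(<http://purl.obolibrary.org/obo/HP_0011623>))
Declaration(Class(<http://purl.obolibrary.org/obo/UBERON_0000947>))
Declaration(Class(<http://purl.obolibrary.org/obo/UBERON_0000948>))
Declaration(Class(<http://purl.obolibrary.org/obo/UBERON_0002082>))
Declaration(Class(<http://purl.obolibrary.org/obo/UBERON_0002094>))
Declaration(ObjectProperty(<http://purl.obolibrary.org/obo/BFO_0000050>))
SubClassOf(<http://purl.obolibrary.org/obo/HP_0001629> <http://purl.obolibrary.org/obo/HP_0001627>)
SubClassOf(<http://purl.obolibrary.org/obo/HP_0002623> <http://purl.obolibrary.org/obo/HP_0001627>)
SubClassOf(<http://purl.obolibrary.org/obo/HP_0001642> <http://purl.obolibrary.org/obo/HP_0001627>)
SubClassOf(<http://purl.obolibrary.org/obo/HP_0001667> <http://purl.obolibrary.org/obo/HP_0001627>)
EquivalentClasses(<http://purl.obolibrary.org/obo/HP_0001636> ObjectIntersectionOf(<http://purl.obolibrary.org/obo/HP_0001629> <http://purl.obolibrary.org/obo/HP_0001642> <http://purl.obolibrary.org/obo/HP_0001667> <http://purl.obolibrary.org/obo/HP_0002623>))
SubClassOf(<http://purl.obolibrary.org/obo/HP_0009999> <http://purl.obolibrary.org/obo/HP_0001636>)
SubClassOf(<http://purl.obolibrary.org/obo/HP_0011623> <http://purl.obolibrary.org/obo/HP_0001629>)
SubClassOf(<http://purl.obolibrary.org/obo/UBERON_0000947> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/UBERON_0000948>))
SubClassOf(<http://purl.obolibrary.org/obo/UBERON_0002082> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/UBERON_0000948>))
SubClassOf(<http://purl.obolibrary.org/obo/UBERON_0002094> ObjectSomeValuesFrom(<http://purl.obolibrary.org/obo/BFO_0000050> <http://purl.obolibrary.org/obo/UBERON_0002082>))
TransitiveObjectProperty(<http://purl.obolibrary.org/obo/BFO_0000050>)
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/BFO_0000050> "part_of")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0001627> "abnormal heart morphology")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0001629> "ventricular septal defect")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0001636> "tetralogy of Fallot")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0001642> "pulmonic stenosis")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0001667> "right ventricular hypertrophy")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0002623> "overriding aorta")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0009999> "tetralogy of Fallot with pulmonary atresia")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/HP_0011623> "muscular ventricular septal defect")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/UBERON_0000947> "aorta")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/UBERON_0000948> "heart")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/UBERON_0002082> "cardiac ventricle")
AnnotationAssertion(<http://www.w3.org/2000/01/rdf-schema#label> <http://purl.obolibrary.org/obo/UBERON_0002094> "interventricular septum")
AnnotationAssertion(<http://purl.obolibrary.org/obo/IAO_0000115> <http://purl.obolibrary.org/obo/HP_0001629> "An abnormality in which the ventricular septum has a hole.")
AnnotationAssertion(<http://purl.obolibrary.org/obo/IAO_0000115> <http://purl.obolibrary.org/obo/HP_0001636> "A cardiac malformation defined by four co-occurring heart phenotypes.")
)
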