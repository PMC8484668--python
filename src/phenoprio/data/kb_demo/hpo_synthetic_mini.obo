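format-version: 1.2
ontology: phenoprio/hpo-synthetic-mini
data-version: phenoprio/synthetic-mini-2024
remark: Synthetic miniature phenotype ontology for testing and demonstration.
remark: Term IDs and names follow HPO conventions but this is a hand-built
remark: stand-in covering hearing-loss phenotypes, not an HPO release.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0000598
name: Abnormality of the ear
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000364
name: Hearing abnormality
is_a: HP:0000598 ! Abnormality of the ear

[Term]
id: HP:0000365
name: Hearing impairment
is_a: HP:0000364 ! Hearing abnormality

[Term]
id: HP:0000405
name: Conductive hearing impairment
is_a: HP:0000365 ! Hearing impairment

[Term]
id: HP:0000407
name: Sensorineural hearing impairment
is_a: HP:0000365 ! Hearing impairment

[Term]
id: HP:0000410
name: Mixed hearing impairment
is_a: HP:0000365 ! Hearing impairment

[Term]
id: HP:0008527
name: Congenital sensorineural hearing impairment
is_a: HP:0000407 ! Sensorineural hearing impairment

[Term]
id: HP:0008625
name: Severe sensorineural hearing impairment
is_a: HP:0000407 ! Sensorineural hearing impairment

[Term]
id: HP:0008619
name: Bilateral sensorineural hearing impairment
is_a: HP:0000407 ! Sensorineural hearing impairment

[Term]
id: HP:0001730
name: Progressive hearing impairment
is_a: HP:0000365 ! Hearing impairment

[Term]
id: HP:0005101
name: High-frequency sensorineural hearing impairment
is_a: HP:0000407 ! Sensorineural hearing impairment
is_a: HP:0001730 ! Progressive hearing impairment

[Term]
id: HP:0000404
name: Auditory neuropathy
is_a: HP:0000407 ! Sensorineural hearing impairment

[Term]
id: HP:0000359
name: Abnormality of the inner ear
is_a: HP:0000598 ! Abnormality of the ear

[Term]
id: HP:0011389
name: Enlarged vestibular aqueduct
is_a: HP:0000359 ! Abnormality of the inner ear

[Term]
id: HP:0008560
name: Cochlear malformation
is_a: HP:0000359 ! Abnormality of the inner ear

[Term]
id: HP:0001751
name: Vestibular dysfunction
is_a: HP:0000359 ! Abnormality of the inner ear

[Term]
id: HP:0000152
name: Abnormality of head or neck
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001999
name: Abnormal facial shape
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0005321
name: Mandibulofacial dysostosis
is_a: HP:0001999 ! Abnormal facial shape

[Term]
id: HP:0000465
name: Webbed neck
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0001626
name: Abnormality of the cardiovascular system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0030148
name: Heart murmur
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0001642
name: Pulmonary valve stenosis
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0001629
name: Ventricular septal defect
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0000951
name: Abnormality of the skin
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001003
name: Multiple lentigines
is_a: HP:0000951 ! Abnormality of the skin

[Term]
id: HP:0000953
name: Hyperpigmentation of the skin
is_a: HP:0000951 ! Abnormality of the skin

[Term]
id: HP:0001507
name: Growth abnormality
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0004322
name: Short stature
is_a: HP:0001507 ! Growth abnormality

[Term]
id: HP:0000818
name: Abnormality of the endocrine system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000853
name: Goiter
is_a: HP:0000818 ! Abnormality of the endocrine system

[Term]
id: HP:0000819
name: Diabetes mellitus
is_a: HP:0000818 ! Abnormality of the endocrine system

[Term]
id: HP:0000478
name: Abnormality of the eye
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000510
name: Retinitis pigmentosa
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000648
name: Optic atrophy
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001251
name: Ataxia
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001263
name: Global developmental delay
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0099999
name: Retired hearing descriptor
is_obsolete: true
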