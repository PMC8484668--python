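# Synthetic demonstration knowledge base for the hearing-loss prioritizer.
# A hand-built stand-in for OMIM/ClinVar/HPO releases: gene symbols and HGVS
# strings are real published deafness variants, coordinates are plausible
# GRCh37-like integers used only as identifiers.
build: GRCh37
ontology: hpo_synthetic_mini.obo
disease_map: disease_map.tsv
known_variants: known_variants.tsv
constrained_genes: missense_constrained.txt
causal_annotations: causal_annotations.tsv
founder_subpopulations:
  - Finnish
  - Jewish
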