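# class <TAB> descriptor phrase
# Starter qualifier inventory for the 11 UniProt annotation categories plus
# the Clinical trial class. Descriptors are normalized (stemmed) at load time;
# the file is editable and extendable by the user.
Expression	expression
Expression	gene expression
Expression	microarray
Expression	rna seq
Expression	transcriptome
Expression	induction
Expression	tissue specificity
Family & Domains	domain
Family & Domains	protein family
Family & Domains	motif
Family & Domains	repeat
Family & Domains	similarity
Function	function
Function	activity regulation
Function	catalytic activity
Function	cofactor
Function	pathway
Function	enzyme regulation
Interaction	interaction
Interaction	binding
Interaction	subunit
Interaction	protein protein interaction
Names	nomenclature
Names	gene name
Names	synonym
Pathology & Biotech	disease
Pathology & Biotech	mutagenesis
Pathology & Biotech	biotechnology
Pathology & Biotech	pharmaceutical
Pathology & Biotech	allergen
Pathology & Biotech	toxic dose
PTM/processing	post translational modification
PTM/processing	phosphorylation
PTM/processing	glycosylation
PTM/processing	ubiquitination
PTM/processing	signal peptide
PTM/processing	ptm
Sequences	protein sequence
Sequences	nucleotide sequence
Sequences	sequencing
Sequences	genome sequence
Sequences	sequence variant
Sequences	mrna
Sequences	alternative splicing
Structure	structure
Structure	crystal structure
Structure	x ray crystallography
Structure	nmr spectroscopy
Structure	3d structure
Subcellular location	subcellular location
Subcellular location	membrane
Subcellular location	localization
Subcellular location	secreted
Unclassified	miscellaneous
Clinical trial	clinical trial
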