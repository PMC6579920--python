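# Coarse functional categories for gene product strings.
# Format: category<TAB>pattern (case-insensitive substring; first match wins).
# Edit or extend freely; order encodes priority.
phage & mobile elements	transposase
phage & mobile elements	insertion sequence
phage & mobile elements	insertion element
phage & mobile elements	integrase
phage & mobile elements	excisionase
phage & mobile elements	mobile element
phage & mobile elements	recombinase
phage & mobile elements	resolvase
phage & mobile elements	conjugal transfer
phage & mobile elements	relaxase
phage & mobile elements	phage
phage & mobile elements	capsid
phage & mobile elements	terminase
phage & mobile elements	portal protein
phage & mobile elements	tail protein
phage & mobile elements	tape measure
phage & mobile elements	holin
phage & mobile elements	plasmid partitioning
phage & mobile elements	plasmid replication
iron acquisition & metabolism	iron
iron acquisition & metabolism	siderophore
iron acquisition & metabolism	ferric
iron acquisition & metabolism	ferrous
iron acquisition & metabolism	ferrichrome
iron acquisition & metabolism	heme
iron acquisition & metabolism	hemin
membrane transport	ABC transporter
membrane transport	permease
membrane transport	transporter
membrane transport	efflux
membrane transport	porin
membrane transport	symporter
membrane transport	antiporter
membrane transport	secretion protein
membrane transport	channel protein
DNA/RNA metabolism	DNA polymerase
DNA/RNA metabolism	RNA polymerase
DNA/RNA metabolism	helicase
DNA/RNA metabolism	primase
DNA/RNA metabolism	topoisomerase
DNA/RNA metabolism	gyrase
DNA/RNA metabolism	ribonucleotide reductase
DNA/RNA metabolism	restriction
DNA/RNA metabolism	methyltransferase
DNA/RNA metabolism	endonuclease
DNA/RNA metabolism	exonuclease
DNA/RNA metabolism	DNA ligase
DNA/RNA metabolism	single-stranded DNA-binding
DNA/RNA metabolism	partitioning protein
DNA/RNA metabolism	replication initiator
DNA/RNA metabolism	replication protein
DNA/RNA metabolism	ribonuclease
transcriptional regulation	transcriptional regulator
transcriptional regulation	transcriptional activator
transcriptional regulation	transcriptional repressor
transcriptional regulation	sigma factor
transcriptional regulation	two-component system
transcriptional regulation	response regulator
stress response	heat shock
stress response	cold shock
stress response	chaperone
stress response	catalase
stress response	superoxide dismutase
stress response	osmotic
stress response	universal stress
stress response	peroxidase
carbohydrate/amino-acid/protein metabolism	dehydrogenase
carbohydrate/amino-acid/protein metabolism	synthetase
carbohydrate/amino-acid/protein metabolism	synthase
carbohydrate/amino-acid/protein metabolism	protease
carbohydrate/amino-acid/protein metabolism	peptidase
carbohydrate/amino-acid/protein metabolism	aminotransferase
carbohydrate/amino-acid/protein metabolism	decarboxylase
carbohydrate/amino-acid/protein metabolism	hydrolase
carbohydrate/amino-acid/protein metabolism	isomerase
carbohydrate/amino-acid/protein metabolism	kinase
carbohydrate/amino-acid/protein metabolism	mutase
carbohydrate/amino-acid/protein metabolism	aldolase
carbohydrate/amino-acid/protein metabolism	epimerase
carbohydrate/amino-acid/protein metabolism	ribosomal protein
carbohydrate/amino-acid/protein metabolism	hydroxylase
carbohydrate/amino-acid/protein metabolism	reductase
hypothetical	hypothetical
hypothetical	uncharacterized
hypothetical	unknown function
hypothetical	DUF
putative	putative
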