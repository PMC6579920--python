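# Signature-gene keyword screen for integrative and conjugative elements.
# Three core ICE function classes; case-insensitive substring match.
# Format: class<TAB>pattern
integration_excision	integrase
integration_excision	excisionase
integration_excision	recombinase
integration_excision	resolvase
replication	helicase
replication	primase
replication	DNA polymerase
replication	replication protein
replication	replicative DNA
conjugation	conjugal transfer
conjugation	conjugation
conjugation	ParB
conjugation	partitioning protein
conjugation	TrbL
conjugation	secretion
conjugation	single-stranded DNA-binding
conjugation	mobilization
conjugation	relaxase
conjugation	type IV
conjugation	FtsK
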