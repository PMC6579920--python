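"""Generate a synthetic genome suite and inspect its planted-truth ledger.

The generator builds a set of related genomes (shared core gene pool, shell
genes, strain-private ORFans) and plants the mobile-element structures the
pipeline detects: multi-copy IS elements, a composite transposon, HGT blocks,
an ICE-like island with att repeats, and dispersed plasmid fragments. The
ledger records where everything is, so downstream stages can be scored.
"""

from mobilomics import default_suite, simulate_genome_set

genomes, ledger = simulate_genome_set(default_suite(seed=1))

print(f"{len(genomes)} genomes:")
for g in genomes:
    chrom = g.chromosome
    print(
        f"  {g.strain:7s} {g.species_label:9s} {len(chrom.sequence):>7,} bp "
        f"{len(chrom.features):>4} features  plasmids: {len(g.plasmids)}"
    )

print("\nplanted structures:")
print(f"  IS elements: {list(ledger.is_elements)} with {len(ledger.is_copies)} copies")
print(f"  composite transposons: {len(ledger.composites)}")
print(f"  HGT blocks: {[(h['recipient'], h['r_end'] - h['r_start']) for h in ledger.hgt_blocks]}")
ice = ledger.ices[0]
print(f"  ICE island: {ice['genome']} [{ice['start']:,}, {ice['end']:,}) att={ice['att']}")
pl = ledger.plasmid_integrations[0]
print(
    f"  plasmid integration: {pl['coverage_fraction']:.0%} of {pl['plasmid']} "
    f"in {len(pl['fragments'])} fragments of {pl['recipient']}"
)
print("\nexpected k-spectrum over the 5 recipients "
      "(clusters present in exactly k genomes):")
print(" ", ledger.expected_spectrum([g.strain for g in genomes if g.species_label == "SpeciesA"]))
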