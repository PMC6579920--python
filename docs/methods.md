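# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic data generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model and genome IO

All coordinates are 0-based, half-open, forward-strand; GenBank's 1-based
inclusive convention is converted at the file boundary. Features of circular
replicons that span the origin are kept as a single interval with
`end > replicon length` and a `wraps` flag, so interval arithmetic reduces
modulo the length instead of special-casing split features.

*ori* normalization rotates the chromosome so that position 0 is the first
base of the intergenic region immediately upstream of *dnaA*, identified by
its product annotation (case-insensitive match on "chromosomal replication
initiator" / "dnaA"), never by sequence homology — the pipeline consumes
existing annotations. If *dnaA* lies on the reverse strand the chromosome is
reverse-complemented first so *dnaA* reads forward. Zero or multiple
candidates raise an error listing them; no silent choice is made. The
rotation is an isometry on circular coordinates (tested property).

Functional categorization of product strings is a first-match lookup in an
ordered keyword table shipped as editable TSV
(`mobilomics/data/functional_categories.tsv`). The categories approximate
coarse subsystem groupings; determinism was chosen over fidelity to any
specific annotation server, whose manual curation is not reproducible.
Unmatched products fall back to "hypothetical" when they contain a
hypothetical/uncharacterized marker, else "miscellaneous".

## Alignment primitives

**Protein identity/coverage.** Global alignment with affine gaps (BLOSUM62,
open −11, extend −1) and free terminal gaps. Identity is matches over
alignment columns excluding terminal gaps; coverage is the aligned span of
the *longer* sequence divided by its length. Measuring coverage on the
longer sequence is the stricter, symmetric reading of "alignment over more
than 75 % of the protein sequence".

**Nucleotide local search.** Seed-and-extend: exact k-mer seeds (default
k = 13) against a forward-strand index (minus-strand queries search the
reverse complement), seeds clustered by diagonal (band 48, join gap 400 bp),
each cluster aligned with a banded bit-vector edit alignment (edlib) over
padded windows, and the column path trimmed to its maximal-scoring
contiguous subpath under megablast-like column scores (match +1, mismatch
−2, gap extend −2 with −5 at gap opening). Because a cost-equal edit path
may park gaps against random flanking sequence, block ends are then
re-pinned by an exact ungapped sweep with an x-drop of 12; on
substitution-dominated data this recovers planted boundaries exactly. The
search is verified against a full dynamic-programming local aligner on
subjects ≤ 5 kb in the test suite. Sensitivity is not tuned for homologs
below ~80 % identity; that regime is out of scope.

**Repeat scans.** Terminal inverted repeats: exhaustive arm-pair scan
(defaults: arm 10–50 bp, ≤ 3 mismatches, terminal windows 150 bp),
vectorized over sliding windows; pairs ranked by arm length, then
mismatches, then terminal proximity, with nested arms suppressed. An IR is
only *accepted* during element delimitation if its length justifies its
mismatches (length ≥ 10 + 2·mismatches), which keeps chance pairs in
~1 kb elements below the noise floor. Flanking direct repeats: matching
cores of the requested length are found around both island edges and
extended maximally under exact matching, so the reported pair is the
maximal repeat — the generator in turn pins the bases adjacent to planted
att sites so the maximal pair is exactly the planted one.

**In-silico PCR.** Annealing sites allow up to 2 mismatches but require an
exact 3′-terminal base; annealing thermodynamics (Tm, secondary structure)
is deliberately not modelled. Any two sites on opposite strands pointing
toward each other within the product cap yield a product; circular
templates also yield origin-spanning products and the product set is
rotation-invariant (tested property).

## Pan-genome

Greedy centroid clustering with a fixed visiting order (length descending,
ties by locus tag then genome) makes the partition deterministic and
independent of input file order; order sensitivity is inherent to greedy
clustering and the published tooling does not document its order. Two exact
pruning bounds skip hopeless centroid comparisons without changing the
result: a length-ratio bound (`min/max ≥ min_identity × min_coverage`) and
an edit-distance bound (in any alignment, matches ≤ (|a|+|b|−d)/2 with d
the minimum edit distance, while a passing pair needs matches ≥
min_identity × min_coverage × |longer|). CDS without a translation
(e.g. pseudogene fragments) are skipped with a warning count.

Accumulation curves enumerate all n! genome orderings when n! ≤ 5,000, else
100 seeded random orderings; pan curves are non-decreasing and core curves
non-increasing in every ordering (tested). ORFan positional density counts
ORFan gene midpoints in windows tiling the ori-normalized chromosome
(default window 50 kb at the synthetic scale).

## IS discovery

The discovery heuristic mirrors manual curation on annotated genomes:
transposase/mobile-element CDS (integrases are tallied separately, not used
as anchors) grouped by identical translation length; one candidate per
group extracted with 1 kb flanks; confirmation requires ≥ 2 loci at ≥ 90 %
identity spanning ≥ 80 % of the consensus interval — the interval covered
by at least two loci, which separates the element from its flanks since
only the source locus matches the flanking sequence. Copies disagreeing
with the typical span by more than 50 % raise an ambiguity error; shorter
matches are flagged partial and censused separately, never as full copies.
Near-identical elements (either orientation) are collapsed at 95 %
identity; the threshold is configurable because the published analog
("not discriminating enough") has no stated numeric criterion.

Gene disruption is called from two signals: a copy contained within one
intact CDS annotation (≥ 90 % of the copy), or a CDS split into two
fragments with the same product abutting the copy boundaries (±25 bp).
Composite transposons: every ordered pair of full copies on one replicon
with cargo gap ≤ 20 kb, transposase amino-acid identity ≥ 0.60 and IR
cross-identity ≥ 0.60. These floors generalize the single well-described
field example (65 % transposase identity, 73.2 % right-IR identity) instead
of hard-coding it.

## HGT and plasmid integration

Raw alignment blocks are filtered strictly (> 2,000 bp and > 90 %
identity — a 2,000 bp or exactly-90 % block does not qualify), then merged
per partner replicon and strand within 1 kb on the recipient; both raw
blocks and merged regions are retained in the output, since the published
rule does not state whether it applied before or after merging. "Other
species" is operationalized by the `species_label` field; taxonomy lookup
is out of scope. Plasmid mapping uses stricter defaults (≥ 95 % identity,
blocks ≥ 500 bp), merges projected intervals on plasmid coordinates, and
lists plasmid features with < 50 % covered overlap as absent from the
integrated fragments.

## ICE model

Island coordinates follow the convention
`[left-repeat start, right-repeat start)`: the interval carries exactly one
att copy. Excision keeps one att copy on each recombination product — the
excised circle is the island plus one att (so its linearization shows the
attL/attR pair around the junction) and the re-sealed chromosome keeps the
remaining copy — hence `circle + re-sealed = chromosome + att`, the
bookkeeping asserted by tests. The signature screen is a case-insensitive
substring match against an editable keyword resource
(`data/ice_signature_keywords.tsv`) with the three core ICE function
classes. Expected amplicon sizes on real gels are not predicted beyond
product length; only the product/no-product logic per template form is
modelled.

## Synthetic data generator

The generator emulates, at reduced scale, the statistical structure that
identity-based mobilome analysis sees in a clonal species complex:

* **Gene pool.** Each species pool has ancestral core genes (dnaA included),
  shell genes present in random subsets, and per-genome ORFans; shared genes
  are independently mutated per genome at a within-cluster nucleotide rate
  (default 0.01, amino-acid identity ≈ 97–98 %, far above the 60 %
  clustering floor). Sixty percent of each genome's ORFans are packed at a
  fixed chromosome fraction (default 0.6) to create the positional
  enrichment signal.
* **Background.** Intergenic sequence is i.i.d. with 62.7 % G+C, the
  species range of the motivating system; ORFs are random codons, so coding
  G+C is ≈ 50 % and overall G+C lands near 60 %. There is no codon-usage or
  phylogenetic model: the detection methods exercised here are
  identity-based, not composition-based.
* **Scale.** Recipient chromosomes are ≈ 0.46 Mb with ≈ 135 genes (real
  chromosomes of the motivating genus are ≈ 4.2 Mb with ≈ 3,800 genes).
  All thresholds operate on absolute lengths and identities, so scaling
  down the chromosome preserves the decision problems while keeping the
  full pipeline runs to tens of seconds.
* **IS copies.** Default suite: one family at 5–13 copies per recipient
  genome with a single copy in one outgroup genome (the published abundance
  dichotomy), one family at 2–4 copies; 20 % of copies of the first family
  insert inside genes, splitting the host CDS into two translation-less
  fragments (as annotation pipelines mark pseudogenes). Same-family copies
  are placed left-to-right with a minimum spacing of 26 kb — larger than
  the 20 kb composite-cargo window. This mirrors the sparsity of real IS
  copies relative to that window (1 copy per ≈ 0.4 Mb in the motivating
  genomes); without it nearly every copy pair on a short synthetic
  chromosome would qualify as a composite candidate and composite calling
  would be vacuous.
* **HGT blocks** are copied from donor-species genomes with an *exact*
  substitution count, so realized identity equals the target to within
  0.5 %; carried genes keep their products and join the donor's truth
  clusters. The default suite plants blocks at 97 %, 95 % and 93 % plus a
  1,500 bp block at 99 % that must *not* be reported under the 2 kb rule.
* **ICE** is inserted at the 3′ end of a host gene with the att repeat
  (default `AGAAGTCCCAGT`) duplicated on both flanks and a roster of
  signature genes (3 integration/excision, 3 replication, 5 conjugation)
  among hypothetical filler genes.
* **Plasmid.** The outgroup donor carries a 6 kb plasmid; 80 % of it is
  integrated into one recipient as three dispersed fragments, each kept
  below 2 kb so the fragments are visible to plasmid mapping but correctly
  below the HGT length rule.
* **Determinism and bookkeeping.** All randomness flows from per-subsystem
  children of one seed (byte-identical outputs per seed). Every planted
  interval lives in a truth ledger whose coordinates are updated through
  every subsequent insertion and through the final ori rotation, and every
  CDS is tagged with its truth cluster, so the expected k-spectrum —
  including the effect of disruptions removing members — is computed
  exactly from the ledger rather than assumed.

What passing the synthetic tests does **not** show: robustness to
assembly/annotation errors, indel-rich divergence, compositional signals,
repeat families with internal rearrangements, or genomes at full scale.
The 5 %-noise tier measures the copy detector against the element
*consensus* (the ledger sequence): two independently 5 %-mutated copies are
≈ 90 % identical to *each other* — exactly at the confirmation floor — so
end-to-end library building from a noisy copy is only exercised at zero
noise, and detector recall under noise is measured where the quantity is
well-defined.

## Pipeline and CLI

`run_pipeline` sequences the stages over loaded (and by default
ori-normalized) genomes, writing TSV/GFF3/FASTA artifacts and a
machine-readable `summary.json`; every threshold is a named configuration
key with its documented default (cluster_identity 0.60, cluster_coverage
0.75, hgt_min_length 2000, hgt_min_identity 0.90, is_flank 1000,
att_repeat_length 12, ...). Island seeds come from the configuration or,
absent that, from detected HGT regions ≥ 20 kb. Re-running with identical
configuration reproduces identical summaries (tested). The `mobilomics`
CLI is a thin wrapper: `simulate`, `pangenome`, `is-scan`, `hgt-scan`,
`ice-scan`, `all`.

## Known limitations

* Greedy clustering is order-dependent by construction; the fixed order is
  an explicit convention, not a reconstruction of any published tool's
  internal order, so exact cluster counts on real data may differ slightly
  from published figures even at identical thresholds.
* The local search assumes high-identity (> ~85 %) homology and
  substitution-dominated divergence; it is not a general-purpose sensitive
  aligner.
* Target-site duplication inference, IS family taxonomy, HGT directionality
  and conjugation modelling are out of scope.
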