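# Methods

## Panortholog identification

Two genes in different genomes are reciprocal best hits (RBH) when each is
the other's unique top-scoring similarity hit. The default scorer is a
deterministic global protein alignment (BLOSUM62, gap open −11 / extend
−1); identity is matching columns over alignment columns, coverage is
aligned query residues over query length, and the default acceptance
thresholds are identity ≥ 0.5 and coverage ≥ 0.5. The scorer sits behind a
small config so an external search program's hits can be substituted.

Panortholog groups are connected components of the pairwise RBH graph
that (i) contain exactly one gene from every genome and (ii) form a
clique — every genome pair in the group must itself be an RBH pair. The
clique requirement is an assumption: plain connected components would
admit chains linked through a single intermediate genome, which is a
weaker orthology signal. Two further guards against recent duplication:

* a tie for a query's top score disqualifies it from RBH entirely;
* the best-local-hit guard discards a group when any member has a hit —
  in another genome or within its own genome — that outscores its hit to
  the group partner.

The reference genome's genes inside panortholog groups form the core
compartment; all its other protein-coding genes are flexible. L_core and
L_flex are the summed CDS lengths of the two compartments and always add
up to the total coding length.

Coordinates are 1-based inclusive; minus-strand genes store the
coding-strand (reverse-complemented) sequence. Translation uses the
bacterial code (table 11) with GTG/TTG starts rendered as Met.

## Diversity and divergence

Protein families are aligned with a deterministic center-star progressive
aligner: the center is the sequence with the highest summed pairwise
score against the rest (for ≤ 12 sequences; the longest sequence beyond
that, since the all-pairs scan grows quadratically), every other sequence
is aligned to it globally, and gap patterns merge under "once a gap,
always a gap". Pre-aligned FASTA input always takes precedence over the
built-in aligner, for reproducibility against external tools.

π_aa is the mean over all unordered pairs of (differing columns /
compared columns). Conventions:

* a residue aligned against a gap is a difference, so an indel spanning
  k residues contributes k differences — deliberately event-unaware;
* columns where both members of a pair are gapped are skipped for that
  pair (assumed; gap-gap columns say nothing about the pair);
* each pair is normalised by its own compared-column count before
  averaging (per-pair mean rather than pooled counts; the pooled
  alternative is a one-line change in `_restricted_pi` but the per-pair
  mean is the implemented and tested convention).

A pair sharing zero compared columns is an error naming the pair.
Site-partitioned diversity applies the same rule restricted to a target
column set (1-based alignment columns) and its complement; a pair with no
compared columns inside a restriction simply drops out of that mean.
Two-sequence divergence d uses the identical conventions, so d for a
gap-free pair is the mismatch fraction over the alignment length.

## Mutation classification and site counting

SNPs classify by translating both codons: same amino acid → synonymous;
new stop → nonsense, which is reported distinctly but counts as
nonsynonymous in every tally; otherwise nonsynonymous.

Site counting follows the Nei–Gojobori equal-weight convention: each of a
codon's 9 single-nucleotide neighbours contributes 1/3 site, classified
by the same rule (stop-creating changes are nonsynonymous sites), so
nonsyn_sites + syn_sites = 3 per codon exactly. The genome-wide site
ratio ρ is Σnonsyn / Σsyn over a gene set. Published results for the
ancestral genome use ρ ≈ 3.22; that value is also the accepted default
config constant so printed dN/dS ratios reproduce exactly without the
60-genome input.

Potential knockouts: small indels whose length is not a multiple of 3,
any IS-element insertion, and any large deletion overlapping the gene.
The small-indel / large-deletion boundary is set at 50 bp (configurable);
no published cutoff exists. A deletion spanning several genes flags every
overlapped gene. Events within 5 codons of the stop set a `near_terminal`
flag, since a frameshift in the final codons may leave the protein
functional. Mutator context is an input column, not inferred — deriving
it requires lineage reconstructions that are out of scope.

## Selection statistics

The printed enrichment statistic is the raw count ratio core_n/flex_n
(this reproduces all four published rows exactly); the length-normalised
rate ratio (core_n/L_core)/(flex_n/L_flex) is computed alongside because
the null expectation is length-based. The binomial test is exact and
two-tailed under the minimum-likelihood rule, with p0 =
L_core/(L_core+L_flex).

G = 2·O·ln(O/E) with E = T·L/ΣL; G is defined as 0 at O = 0 (the x·ln x
limit) and vanishes at O = E. ΣE = T holds to 1e−9.

Standard tests delegate to scipy behind a uniform result type, with exact
small-sample p-values by complete enumeration: Spearman uses all n!
pairings for n ≤ 8, Mann–Whitney all pooled relabellings for
n_a·n_b ≤ 400, Wilcoxon signed-rank all 2^n sign assignments for n ≤ 15
(zeros dropped, average ranks on ties, W = smaller rank sum). The
thresholds are fixed so the enumeration oracles in the test suite stay
desk-scale. Welch's t reports the Welch–Satterthwaite d.f.; Fisher's
exact test returns p = 1 (flagged degenerate) on a zero margin. The
bootstrap median CI is the percentile method, default 10,000 resamples,
seed mandatory.

## Structure contacts

PDB input is pre-validated line-by-line (coordinate fields must parse;
errors carry line numbers) and then parsed with gemmi. Waters are
dropped, the first alternate conformation is kept, ions count as ligands,
and chains are typed protein/nucleic/ligand from residue content. The
contact criterion takes all atoms of the target residue against all atoms
outside its chain plus ligand atoms, with an inclusive 8.0 Å threshold.
All-atom rather than side-chain-only distances are used (the filter is
unstated in the source analyses; X-ray files rarely carry hydrogens, so
the choice is close to heavy-atom). mmCIF is out of scope.

## Synthetic data

The generator emulates the study's input shapes at desk scale, with truth
tables for every entity:

* **Pangenome** — default 5 genomes, 20 core + 10 flexible families,
  gene lengths 60–120 codons, per-codon substitution probability 0.02
  (within-family identity ≳ 0.95, far above the 0.5 calling threshold;
  unrelated random families sit near 5% identity), indel probability 0.1
  per gene copy. Each family diverges star-wise from one random ancestor:
  independent branches, no coalescent tree, because none of the analyses
  uses tree shape. Flexible families are guaranteed absent from at least
  one genome so truth labels match the panortholog definition.
* **Mutations** — event totals default to the published 50,000-generation
  structure (194 nonmutator events, ~0.897 nonsynonymous; 6,473 mutator
  events, ~0.738 nonsynonymous). Nonmutator nonsynonymous events hit core
  genes at `core_enrichment_factor` (default 2) times the flexible per-bp
  rate — the planted selection signal; synonymous events and
  hitchhiker-dominated mutator events are length-proportional. Codon
  changes are rejection-sampled against the classifier so every generated
  SNP reclassifies to its intended label. A small fraction of nonmutator
  nonsynonymous events become knockout-category events instead of SNPs.
* **Essentiality** — integer scores on the +3 (essential) … −4
  (dispensable) scale from discretised normals, default means −0.5 (core)
  vs −1.5 (flexible), σ = 1.5: a planted one-point shift towards
  essentiality for core genes.
* **Structures** — partner chains placed on orthogonal coordinate axes
  with their closest atom at exactly the planted distance from a chain-A
  atom at the origin; orthogonality makes every cross-chain distance
  strictly larger, so the measured minimum equals the planted value to
  well under 1e−3 Å. At most 6 partner chains fit this scheme; larger
  requests raise.

All randomness flows from one seed through labelled substreams
(`numpy` SeedSequence spawn keys), so outputs are byte-identical per seed
and individual artifacts regenerate stably.

What passing tests on synthetic data do **not** show: the generator makes
no attempt at real codon usage, GC content, genome synteny, population
dynamics, or realistic family-size distributions, so recovery results
demonstrate correctness of the algorithms, not performance on real
genome collections.

## Problem sizes and test design

The test suite runs everything at desk scale: 5-genome pangenomes,
174-event mutation tables, 200-replicate calibration loops (enrichment
recovery at planted factors 1/2/4; Welch type-I and power on 500-gene
compartments), and enumeration oracles capped at the exact-method
thresholds above. The published genome-scale quantities that require the
real 60-genome collection (e.g. the 1,968-panortholog count or specific
rank-test statistics) are covered by these property-based checks instead
of value reproduction; the desk-scale worked examples (enrichment ratios,
dN/dS, core fraction, pair counts) reproduce the printed values exactly.

## Known limitations

* The all-vs-all pairwise scorer is quadratic in genes × genomes; for
  real genome collections an external search tool should be plugged in
  via the hit interface.
* The center-star aligner is adequate for closely related families but
  is not a substitute for a profile-based MSA at deep divergence;
  pre-aligned input is first-class for that reason.
* dN/dS here is count-based with a single genome-wide ρ, not a
  codon-model estimate.
* Deletions are attributed to every overlapped gene; no weighting by
  overlap fraction.
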