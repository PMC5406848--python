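# coreflex

Core vs. flexible genome analysis of experimental-evolution mutations.

Bacteria in a long-term evolution experiment accumulate mutations whose
genomic distribution carries a signature of selection. `coreflex` asks
whether the genes that evolve fastest in the laboratory are the same genes
that diversify in nature, by combining four analyses over a genome
collection and a table of sequenced-clone mutations:

1. **Pangenome partitioning** — reciprocal-best-hit orthology calls
   identify *panorthologs* (single-copy genes present in every genome of
   the collection); the reference genome's coding sequence splits into a
   *core* compartment (panorthologous genes) and a *flexible* compartment
   (everything else).
2. **Amino-acid diversity and divergence** — an amino-acid analogue of
   Nei's nucleotide diversity, π_aa = mean pairwise differences per site
   over all n(n−1)/2 sequence pairs of a family alignment, with each
   residue of an indel counted as a difference; interspecies divergence
   *d* = proportion of differing residues between two aligned orthologs.
3. **Mutation classification and selection statistics** — synonymous /
   nonsynonymous / nonsense SNP classes (nonsense tallied as
   nonsynonymous), potential-knockout flags, compartment enrichment with
   exact binomial tests, dN/dS = (N/S)/ρ with ρ the genome-wide
   nonsynonymous-to-synonymous site ratio (≈ 3.22 for the ancestral
   genome, by Nei–Gojobori equal-weight counting), and per-gene
   parallelism scores G = 2·O·ln(O/E) against a length-proportional
   expectation E.
4. **Structure contacts** — mutated residues mapped onto protein
   structures are called interface-proximal when any atom lies within
   8 Å of another chain, a nucleic acid, or a bound ligand.

A synthetic-data generator produces every input with known ground truth
(labelled core/flexible families, a planted core-enrichment factor,
essentiality scores, toy structures with planted distances), so the whole
pipeline is testable offline.

The package is aimed at microbial evolutionary genomicists who want these
analyses as reusable, tested building blocks rather than one-off scripts.

## Worked example

The four published mutation tallies from 50,000-generation clones
(core/flexible × nonmutator/mutator), with compartment coding lengths
L_core = 1,944,921 bp and L_flex = 2,066,263 bp:

```python
from coreflex.stats import CompartmentCounts, dnds_ratio, enrichment_test

for label, (core, flex) in {
    "nonsyn/nonmutator": (123, 51),
    "syn/nonmutator": (10, 10),
    "nonsyn/mutator": (2265, 2510),
    "syn/mutator": (838, 860),
}.items():
    r = enrichment_test(CompartmentCounts(core, flex, 1_944_921, 2_066_263))
    print(f"{label:18s} odds={r.odds_ratio:.2f}  p={r.p_value:.3g}")

print("dN/dS core nonmutator:", round(dnds_ratio(123, 10, 3.22).dnds, 2))
print("dN/dS flex nonmutator:", round(dnds_ratio(51, 10, 3.22).dnds, 2))
```

prints

```
nonsyn/nonmutator  odds=2.41  p=4.63e-09
syn/nonmutator     odds=1.00  p=1
nonsyn/mutator     odds=0.90  p=0.148
syn/mutator        odds=0.97  p=0.481
dN/dS core nonmutator: 3.82
dN/dS flex nonmutator: 1.58
```

Nonsynonymous mutations in non-hypermutator populations are strongly
over-represented in the core genome (odds 2.41, binomial p < 10⁻⁸),
while synonymous mutations and hypermutator populations sit at the null —
the excess is driven by selection, not mutation rate.

The full pipeline runs from one config:

```sh
printf 'seed: 11\n' > config.yaml
coreflex run-all --config config.yaml --outdir out/
```

which simulates a labelled pangenome, partitions it, aligns every
panortholog family, plants and classifies mutations, and writes
`enrichment_table.tsv`, `gscores.tsv`, `gscore_vs_diversity.tsv`,
`gscore_vs_divergence.tsv`, `site_partition.tsv`,
`knockout_essentiality.tsv`, `contacts.tsv`, and a `run_report.json`
with parameters and file checksums. Repeated runs with the same config
are byte-identical.

## Library layout

| module | contents |
| --- | --- |
| `coreflex.pangenome` | gene/genome models, similarity scoring, RBH, panortholog groups, core/flexible partition |
| `coreflex.alignment` | center-star family alignment, π_aa, site-partition diversity, divergence |
| `coreflex.mutations` | SNP classes, site counting, knockout flags, event collapse, compartment tallies |
| `coreflex.stats` | enrichment, dN/dS, G scores, rank/parametric tests, bootstrap median CIs |
| `coreflex.structures` | PDB parsing, residue mapping, interface distances |
| `coreflex.simulate` | synthetic pangenome / mutation / essentiality / structure generators |
| `coreflex.pipeline`, `coreflex.cli` | orchestration and the `coreflex` command |

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical conventions.
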