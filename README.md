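# polyshare

Allele-sharing, SNP filtering and clonality inference for establishing the
parentage and reproductive mode of allopolyploid plant lineages from
genotyping-by-sequencing (GBS) SNP data.

## The problem

When a polyploid taxon is suspected to be an allopolyploid — a hybrid
carrying two divergent parental subgenomes — its parents can be inferred
from genome-wide SNPs without assembled genomes: the allopolyploid's
alleles should be *shared* predominantly with its two parental species (or
their clades, if a parent is extinct), and alleles found in the focal taxon
and exactly one other species (*exclusively shared* alleles) point at
parents even more directly. Independently, whether the taxon reproduces
sexually or clonally is visible in pairwise *shared heterozygosity* (SH):
ramets of one genet carry identical heterozygous genotypes, so SH above
0.9 flags clonemate pairs, while sexually produced individuals segregate
and fall well below.

`polyshare` packages this reasoning as a tested pipeline for VCF input:

1. **Filter cascade** — remove indels; minor allele frequency ≥ 0.02
   (over known allele copies); mean site depth within [10, 300]; site
   genotyped in ≥ 40 samples; focal-informativeness rules (non-reference
   allele carried by ≥ 3 focal individuals, not carried in every species,
   focal lineage genotyped).
2. **Allele accounting** — a genpop-style per-(site, allele) copy-count
   table per lineage; private, shared and exclusively shared allele counts
   per species and per clade, with percentages of the focal taxon's
   non-private alleles: pct(L) = 100 · shared(L) / (total − private).
3. **Clonality** — for each intra-lineage sample pair, SH = |M| / |H|
   where H are sites with both calls known and ≥ 1 heterozygous and M ⊆ H
   those identically heterozygous; pairs with SH > 0.9 are clonemates.
4. **Synthetic data** — a hierarchical Balding–Nichols generator
   (clades → lineages → genotypes) with a disomically inheriting
   allotetraploid focal lineage, clonal ramets, missingness and depth
   noise, plus ground truth, so every stage is testable end to end.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a 2,000-locus dataset (nine diploid species in three clades, an
allotetraploid *bachofenii* formed from *vernus* × *heuffelianus*, one
clonal ramet pair), then run the full workflow:

```sh
printf 'n_loci: 2000\nseed: 42\n' > sim.yaml
polyshare simulate --config sim.yaml --out-dir sim
polyshare filter --vcf sim/simulated.vcf --popmap sim/popmap.tsv --out-dir filt
polyshare share  --vcf filt/filtered.vcf --popmap sim/popmap.tsv --out-dir share
polyshare clones --vcf sim/simulated.vcf --popmap sim/popmap.tsv --out-dir clones
```

prints

```
simulated 2000 loci x 82 samples (10 lineages; focal=bachofenii)
remove_indels: 2000 -> 2000 (-0)
maf: 2000 -> 1820 (-180)
depth: 1820 -> 1820 (-0)
site_presence: 1820 -> 1820 (-0)
focal_informative: 1820 -> 868 (-952)
0 private of 1726 focal alleles
top shared-allele candidates: heuffelianus (1410), vernus (1383), bertiscensis (1366)
1 clone pair
  bachofenii: 1
```

The two true parents lead the shared-allele ranking (1,410 and 1,383 of
the focal taxon's 1,726 non-private alleles, i.e. 81.69% and 80.13% in
`share/sharing.tsv`), and the one injected ramet pair is the one clone
pair found. `clones/sh_plot.png` is the per-pair SH point plot with the
0.9 threshold line; `filt/filter_log.tsv` records per-stage variant
counts.

The same operations are available as a library
(`polyshare.simulate_dataset`, `apply_filter_cascade`,
`build_allele_counts`, `sharing_report`, `rank_parent_candidates`,
`pairwise_sh`, `classify_clones`) on `GenotypeMatrix`/`PopulationMap`
objects read with `read_vcf` / `read_popmap`.

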