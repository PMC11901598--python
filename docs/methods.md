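# Methods

`polyshare` implements the SNP-based reasoning used to establish the origin
and reproductive mode of an allopolyploid taxon from a genotyping-by-
sequencing (GBS) SNP matrix: a variant filter cascade, per-lineage allele
accounting (private / shared / exclusively shared alleles, with clade
aggregation), a pairwise shared-heterozygosity (SH) clonality index, and a
synthetic-data generator with known ground truth for validating every stage.

## Data model

Genotypes are unordered diploid allele multisets: `0/1`, `1|0` and `1/0` are
the same call, because every statistic in the pipeline is phase-free.
Half-calls (`0/.`) and non-diploid calls are converted to missing on read
(with a warning); they are unusable by presence counting and by SH, both of
which need complete diploid calls. Multiallelic records are kept as single
variants, and an "allele" everywhere means a (site, allele-state) pair; the
reference allele is an allele like any other. Depth is tracked at two
levels: per-genotype `DP`, and the site-level `DP` INFO field; the working
site depth is the site `DP` when present, otherwise the mean of known
per-genotype depths, otherwise unknown.

## Filter cascade

Stages run in a fixed order — indels → minor-allele frequency → depth →
site presence → focal informativeness — matching the usual vcftools-style
cleanup of IPYRAD output:

* **MAF** (default ≥ 0.02) is computed over known allele copies only
  (missing calls leave the denominator); for a multiallelic site it is the
  frequency of the second most common allele. The bound is closed
  (0.02 is kept), matching vcftools semantics.
* **Depth** (default [10, 300], closed) has two modes because VCF tools
  support both: `site_mean` removes sites whose site depth falls outside
  the window (unknown-depth sites are kept, with a warning), while
  `genotype` masks individual out-of-window calls to missing and then drops
  emptied sites. `site_mean` is the default.
* **Site presence** (default ≥ 40 genotyped samples) emulates the
  "locus present in N of M samples" assembly threshold downstream of
  clustering.
* **Focal informativeness** keeps sites that can say something about the
  focal taxon: (a) at least `focal_min_carriers` (default 3) focal
  *individuals* carry a non-reference allele — "carriers" counts
  individuals, not allele copies, though a `focal_carrier_unit="copies"`
  switch provides the alternative reading; (b) the site's non-reference
  alleles are not carried in every lineage (such sites cannot discriminate
  parentage); (c) the focal lineage is genotyped at the site.

Each stage is idempotent and the cascade equals manual composition of the
stages; both properties are tested, the latter against an independent
composition oracle.

## Allele accounting

The genotype matrix plus a population map (sample → lineage, lineage →
clade, one focal lineage) becomes a genpop-style count table: copies of
each (site, allele) per lineage. Sharing is then defined on *presence*
(copy count > 0), not on copy counts, because "exclusively shared"
(present in exactly two lineages) is inherently a presence criterion:

* private(L): alleles present in exactly one lineage (L);
* shared(L): alleles present in both the focal lineage and L;
* exclusively shared(L): additionally absent from every other lineage;
* clade aggregation: shared = present in the focal lineage and in ≥ 1
  member; exclusive = additionally absent outside the clade (focal
  excepted). Unions of clades are merged clades.

Report percentages use the focal lineage's **non-private** allele count as
denominator (total − private) and are rounded half-up to 2 decimals; both
conventions are pinned down by reproducing every published percentage of
the study's sharing table exactly from its printed counts (the acceptance
suite does this). Parent candidates are ranked by shared count, ties broken
by exclusive count and then label. Known hybrid lineages other than the
focal can be excluded before the table is built.

One bookkeeping subtlety: the focal total always equals private plus
alleles shared with ≥ 1 other lineage (a tested invariant); a clade-union
row can be smaller than that shared-with-any count when some alleles are
shared only with lineages outside the union.

## Shared heterozygosity

For samples A and B, with H the sites where both calls are known and at
least one is heterozygous, and M ⊆ H the sites where both are heterozygous
and identical as multisets, SH = |M| / |H| (undefined when H is empty).
Heterozygote identity compares multisets, so `0/1` ≡ `1/0` but `0/1` ≠
`0/2`. The "at least one heterozygous" denominator makes SH insensitive to
shared homozygosity; because the index's source formulation is not
reprinted in full, the alternative denominator (heterozygous in *both*) is
available via `denominator="both"`. A pair is a clonemate when SH strictly
exceeds the threshold (default 0.9, "above 0.9"); undefined pairs are never
flagged. SH is symmetric and invariant to site order and to REF/ALT
relabelling — all tested, plus equivalence with a brute-force double loop.

## Synthetic data

Allele frequencies follow a two-level Balding–Nichols hierarchy: per locus
an ancestral frequency `p ~ Uniform(0.05, 0.95)`, a clade frequency
`~ Beta(p(1−Fc)/Fc, (1−p)(1−Fc)/Fc)`, and a lineage frequency drawn the
same way from the clade frequency with `Fl`. This was chosen over
coalescent simulation for speed and closed-form expectations; it is a
modelling stand-in, not a claim about the study system. Frequencies are
clipped to [1e−9, 1−1e−9] between levels so the beta parameters stay
positive.

Defaults: 5,000 unlinked biallelic loci; three clades of 3/4/2 diploid
lineages (named after the *Crocus* series *Verni* species whose structure
the generator emulates), 8 samples each; an allotetraploid focal lineage of
9 samples; 10% missing calls; negative-binomial per-call depths with mean
50 and dispersion 5; one clonal ramet pair in the focal lineage with 0.5%
per-site error.

The divergence defaults are `f_clade = 0.3` and `f_lineage = 0.3`, i.e.
pairwise differentiation ≈ 0.3 within a clade and ≈ 0.5 between clades.
These model distinct congeneric *species*: they reproduce the wide spread
of between-species sharing percentages seen in real interspecific data,
which is what lets a parent be distinguished from its clade relatives.
(Population-scale values such as `f_lineage = 0.05` make within-clade
lineages nearly exchangeable — presence over 16 allele copies saturates,
shared counts differ by ~1%, and parent identification degenerates to
chance within the clade.)

The allotetraploid inherits disomically: each sample draws two allele
copies from parent A's frequency and two from parent B's (no tetrasomic
mixing), and is exported as a pseudo-diploid presence call — heterozygous
iff both states occur among the four copies — mimicking diploid genotype
calling of GBS reads from a tetraploid. True dosage is kept in the truth
record. Clonal ramets copy a progenitor's genotype; with probability equal
to the error rate, a site's call is replaced by one of the other two
diploid genotypes. `inject_artifacts` adds filterable noise (indel records,
extra missingness, overwritten depths) with the injection truth returned
alongside. All randomness flows from a single seed through one generator;
replicate *k* of a study uses seed + *k*.

What the generator does **not** emulate: linkage and LD between loci,
selection, allele-frequency spectra shaped by mutation, unequal sample
sizes per species (real datasets range from 1 to dozens), post-origin
mutations in the allotetraploid (so simulated focal lineages have almost no
private alleles, unlike the ~5% observed in real data), and read-level
error processes. Passing recovery tests therefore show that the inference
is correct *given* hierarchical drift structure and disomic inheritance,
not that it is robust to every artefact of real GBS data.

## Validation study sizes

The recovery studies run 10 replicates of the default configuration
(5,000 loci, 82 samples): the two true parents must rank top two by shared
alleles (after the full filter cascade, as in the study's workflow) in at
least 9/10 replicates, their clades must take the two highest clade
percentages, injected ramets (error ≤ 1%) must all exceed SH 0.9, and
≥ 95% of non-clone intra-lineage pairs must fall below it. Observed
margins are comfortable: parent recovery 36–40/40 over larger sweeps,
clone SH ≈ 0.99 against a non-clone maximum ≈ 0.68.

## Numerical and edge-case choices

* Percentages: exact Decimal arithmetic with half-up rounding; a zero
  denominator yields undefined (`None`) percentages, not an exception.
* Depth unknowns use −1 sentinels; genotype missingness is the pair
  (−1, −1); pairs are canonicalised ascending on construction.
* Empty matrices, lineages with < 2 samples (no SH pairs), all-missing
  sites and monomorphic sites are all defined, tested cases rather than
  errors.
* Ranking ties break deterministically (exclusive count, then label) so
  reports are byte-reproducible.

## Limitations

Presence-based sharing is sensitive to sample size per lineage (an allele
is more likely "present" in a deeply sampled lineage); the real study's
unequal sampling is not modelled by the default generator. Maternal-parent
assignment is out of scope (it requires organellar data). The SH index
assumes comparable missingness between samples; heavily unbalanced
missingness shrinks the comparable-site count rather than biasing SH.
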