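# streakmap

Non-parametric identity-by-descent (IBD) mapping for disease pedigrees with
arbitrary inheritance mode and incomplete penetrance, built around the
**SNP-streak** rule, together with the companion analyses a rare-mutation
family study needs: unaffected-subject refinement of candidate regions,
subset-permutation significance, mid-P Fisher segregation testing, four-step
exome variant filtering with IBD intersection, peak-shift epigenomic
enrichment — and a gene-dropping simulator so the whole pipeline can be
exercised and validated without any external data.

## Who this is for

Statistical geneticists analysing a family — typically consanguineous, with
loops that defeat classical parametric linkage software — in which a rare,
possibly incompletely penetrant mutation appears to segregate with disease.
Classical homozygosity mapping assumes recessive inheritance; LOD-score
methods need an inheritance model and struggle with looped pedigrees. The
SNP-streak approach needs neither.

## The method

If the affected members share a risk mutation on a single ancestral
haplotype, each of them carries **at least one copy** of that haplotype.
At any SNP inside the shared segment the carrier set can therefore never
contain both homozygote classes — markers adjacent to the causal mutation
*lose homozygous genotypes for at least one allele*. The scan:

1. **Window rule.** Slide a 1-Mbp window across the (LD-pruned, r² ≥ 0.9)
   genome-wide SNP genotypes of the carrier set; call a window
   IBD-compatible when at most 1 SNP in it violates the rule (the exception
   absorbs genotyping error).
2. **Stretch calling.** Merge overlapping compatible windows; runs spanning
   ≥ 2 Mbp become IBD stretches.
3. **Refinement.** For each stretch, impute the ancestral haplotype's
   presence in every unaffected member (does the stretch survive that
   member's inclusion?), then consecutively restrict the number of
   unaffected members allowed to harbor a stretch until one region remains.
4. **Significance.** Re-run the whole pipeline over random "affected"
   subsets of the pedigree (10,000 permutations) to ask how often a stretch
   confined to ≤ k unaffected members arises by chance.

A recessive mode (all carriers homozygous for the same allele — classical
homozygosity mapping) shares the same window machinery.

Segregation of candidate variants is tested with the **two-sided mid-P
Fisher exact test**: enumerate all 2×2 tables with the observed margins
under the hypergeometric null and sum the probability of tables strictly
less probable than the observed one plus *half* the probability of equally
probable tables — less conservative than the standard exact test while
keeping type-I error near nominal. Naive penetrance is the fraction of all
mutation carriers who are affected.

## Worked example

```sh
python examples/segregation_midp.py
```

```
variant                                carriers    mid-P  Fisher P
chr2 missense (critical region)    6/6 vs 6/16     0.009     0.015
chrX missense                      6/6 vs 9/16     0.087      0.12
chrX in-frame indel                6/6 vs 14/16      0.74       1.0

penetrance estimate for the co-segregating variant: 0.50
```

Each row is a candidate variant from exome filtering: carried by all 6
members of the expected-carrier group, and by 6, 9 or 14 of 16 unaffected
relatives. Only the first co-segregates (mid-P = 0.0090); its 12 carriers
split 6 affected / 6 unaffected — a dominant model with penetrance 0.50.

```sh
python examples/ibd_mapping.py
```

```
expected-carrier group (8): II:12, II:6, III:1, III:11, III:2, III:3, IV:3, IV:4
unaffected pool: 16 members
true planted-haplotype carriers: 30

2 IBD stretch(es) spanning 21.0 Mbp:
  2:1,950,001-4,800,001 (2.9 Mbp, 58 markers)
  2:11,850,001-30,000,001 (18.2 Mbp, 364 markers)  <- contains planted locus

presence counts in the unaffected pool: [0, 5]
after restricting to <= 4 unaffected carriers: 1 stretch(es) survive
```

Here the pipeline runs on a simulated 49-member looped pedigree with a risk
haplotype planted on one founder chromosome: the scan recovers a stretch
containing the planted locus, and refinement counts how many unaffected
members share each region. The other examples cover variant filtering
(`variant_filtering.py`), peak-shift enrichment
(`peak_shift_enrichment.py`), and simulation plus permutation testing
(`simulate_and_permute.py`).

A thin CLI wraps the same functions: `streakmap load / scan / refine /
permute / midp / filter-variants / peakshift / simulate` (see
`streakmap --help`).

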