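# Methods

## The SNP-streak compatibility rule

Let the *carrier set* C be the members assumed to hold at least one copy of
a risk haplotype (the affected cases, optionally plus serology-positive
unaffected members). At a biallelic SNP with genotypes coded 0/1/2 against
a declared reference allele, the set is **compatible** with shared carriage
unless it contains *both* homozygote classes: some member 0 (hom-ref) and
some member 2 (hom-alt) cannot both carry one shared allele. The rule is
deliberately weak — it never uses phase, penetrance or allele frequencies —
which is what makes it valid under any inheritance mode and robust in
looped pedigrees where inheritance-vector methods fail.

A missing genotype imposes no constraint under the default
`missing_policy="compatible"` (a missing call cannot exhibit a homozygote
class); the `"incompatible"` policy is available for strictness. A
carrier set of size 1 is legal but warned about: everything is compatible.

The recessive mode replaces the rule with "all non-missing genotypes are
the same homozygote" — classical homozygosity mapping. Every
recessive-compatible marker is dominant-compatible, so recessive stretches
are always contained in dominant ones (property-tested).

## Windows, stretches, refinement

* **Window span** 1 Mbp, **exception budget** 1 marker per window, **stretch
  threshold** 2 Mbp. These are the method's canonical values; the budget
  absorbs isolated genotyping errors at array error rates (~0.5%), and the
  2-Mbp floor suppresses short chance runs.
* **Window placement**: a window starts at every marker (`per_marker`).
  The method's description says only "sliding window"; per-marker anchoring
  is the finest placement and subsumes any coarser step, which is offered
  as `fixed_bp`. The exception budget applies per window (bin level), not
  per merged stretch.
* **Stretch coordinates** are the marker-supported extent — first to last
  marker of the merged compatible windows — not window-boundary extent, so
  they are reproducible from the data alone. Internally coordinates are
  1-based inclusive; BED output converts to 0-based half-open.
* **LD pruning** (r² ≥ 0.9, greedy left-to-right against retained markers)
  precedes scanning so that a cluster of perfectly correlated markers
  cannot eat the exception budget as a block. r² can be supplied as pair
  lists or computed from a reference genotype panel.
* **Presence imputation**: the ancestral haplotype is imputed present in a
  non-carrier subject when re-running the window rule over the stretch's
  extent with the subject added leaves the *entire* extent compatible
  (strict default). A weaker reading — some ≥ 2 Mbp sub-stretch survives —
  is available via `strict=False`; it is markedly more sensitive to true
  unaffected carriers (the strict reading is specific instead: in
  simulations it calls essentially no false presences). The published
  description does not fix this detail; strict is the default because it
  matches "whether the IBD stretch remains".
* **Refinement schedule**: count presence per stretch, then walk the
  allowance k down from the pool size, keeping stretches with count ≤ k,
  stopping at the first k with ≤ 1 survivor or k = 0. Deterministic and
  fully reproducible; note that under incomplete penetrance the causal
  region's count need not be the smallest (unaffected carriers are real),
  so confinement is a localisation heuristic, not an inference.

## Permutation significance

Each of B iterations (default 10,000) draws `n_affected` members uniformly
without replacement from the supplied member pool (default: all genotyped
members — the published description is ambiguous about the pool, so it is a
parameter), re-runs scan → stretches → presence counts, and scores success
when any stretch is harbored by ≤ k of the non-drawn members. p is
reported as the plain fraction `n_success / B` (the alternative
(n+1)/(B+1) convention is not used; the convention is recorded in run
metadata). A single seeded NumPy generator drives all draws; identical
seeds give identical p. Distinct subsets are cached, which makes the
small-pedigree case (where C(n, k) is tiny) effectively exhaustive.

## Mid-P Fisher exact test

With margins fixed, the count a follows a hypergeometric distribution.
Two-sidedness is by the "tables no more probable than observed" criterion:

    p_mid = Σ P(tables strictly less probable) + ½ Σ P(tables equally probable)

with the observed table in the second sum. This is the only two-sided
convention that reproduces all three published validation values
(0.0090 / 0.087 / 0.74) — verified by enumeration. Masses are computed in
log space (`scipy.stats.hypergeom.logpmf`); probability ties use a 1e-12
relative tolerance. p_mid ≤ p_fisher holds for this construction and is
property-tested; the test oracle uses exact rational arithmetic
(`fractions` + `math.comb`), fully independent of scipy. Reported values
default to 2 significant figures, the precision of the published table.
Penetrance is estimated as affected-group carriers / all carriers.

## Variant filter

Criteria applied in order, each rejection labeled with its first failure:
(i) consequence ∈ {missense, nonsense, frameshift indel, splice
acceptor/donor}; (ii) not registered in any population database at
non-reference allele frequency ≥ 0.01 — the maximum across sources governs,
and a frequency-less known site rejects only on exact position match
(configurable); (iii) indels not within ±5 bp of a known variant, measured
between left-normalised coordinates; (iv) ≥ 1 non-reference allele in every
sequenced case. Consequence classes are consumed from annotation input,
never recomputed. Retention is monotone in the frequency threshold and
antitone in the required-carrier set (property-tested). Stretch
intersection keeps variants whose start position lies inside a stretch
(1-based inclusive; interval tree).

## Peak-shift enrichment

The null population is the finite set of joint displacements of all peaks
by multiples of 100 bp within ±2 Mbp (40,000 shifts; zero displacement
excluded by default — including it changes p by ≤ 1/n and is
flag-controlled). Peaks move, SNPs stay fixed, inter-peak spacing is
preserved. The statistic is binary any-SNP-in-any-peak; p is the exact
fraction of displacements that overlap, reported one-sided (no observed
overlap ⇒ p = 1). A nearest-summit-distance rank statistic is available
behind `summit_statistic=True` for analyses that emphasise proximity to
the peak summit. An alternative SNP-centric null (comparing against
neighbouring SNPs within ±2 Mbp rather than sliding peaks) appears in some
descriptions of this family of tests; this package implements the
peak-sliding null and documents the discrepancy here rather than resolving
it.

## Gene-dropping simulator

Founder haplotypes are drawn per-marker from given alt-allele frequencies
(linkage equilibrium; an intentional simplification — the scan exploits
family sharing, not background LD). Offspring haplotypes follow Mendelian
transmission with crossovers as a Poisson process at 1e-8 per bp (~1 cM/Mb,
no interference; genetic-map support is out of scope). Descent is tracked
by labeling each founder haplotype uniquely, so true carriers and the
unbroken shared segment are known exactly. The risk allele is planted on
one founder haplotype at the marker nearest the requested locus.
Phenotypes: carriers affected with probability `penetrance` (default
0.50), non-carriers with `phenocopy_rate` (default 0). Genotyping error
flips a call to a uniformly chosen different value; missingness is
independent per call. Everything is deterministic under one seed.

The packaged study pedigree has 49 members in 4 generations with five
first-cousin marriages (loops), 8 affected, and 24 genotyped members
splitting 6 expected carriers (5 affected + 1 antibody-positive unaffected,
reclassified) / 18 antibody-negative unaffected. The true family's mating
structure is known only from a drawing; this topology is an approximation
that reproduces all published counts and identifiers, and is versioned with
the package.

**What passing simulations do and do not show.** The generator emulates the
study conditions scaled to one 30-Mbp chromosome at 50-kbp marker spacing
(601 markers — the published array's density); recovery there transfers to
genome scale per-chromosome, but the simulator has no background LD, no
allele-frequency spectrum, no genotyping-batch structure and no phenotype
misclassification, so passing rates bound method behaviour under the
model's assumptions, not under all real-data pathologies. Recovery
replicates are conditioned on ≥ 2 genotyped carrier-set members — the
ascertainment under which a disease family is recruited at all.

## Numerical and degenerate-input choices

* Genotypes: int8, −1 missing; markers strictly increasing per chromosome;
  multi-allelic VCF records dropped with a logged count; half-calls read as
  missing (the streak rule needs full genotypes).
* Monomorphic markers are flagged allele-wise (at most one allele observed
  among non-missing calls) and can be dropped before scanning.
* PED alleles may be ACGT or 1/2; the internal dialect is always 0/1/2
  against a declared reference allele. The writer emits a 6-column
  BIM-style map so round-trips are bit-identical; 4-column maps infer the
  reference as the major allele (ties lexicographic).
* Empty r² source ⇒ identity keep-list (logged). Empty peak list ⇒ p = 1
  with a warning. Zero-margin tables are an error, as is an empty carrier
  set or penetrance estimation with zero carriers.
* Windows with no markers are non-calls, not incompatible calls.

## Problem sizes used in the shipped checks

Scan-vs-oracle uses 500 random instances of ≤ 50 markers × ≤ 6 carriers;
mid-P uses 1,000 random tables with N ≤ 40; recovery uses 200 replicates
per penetrance setting on the 601-marker map; permutation calibration uses
an 8-member pedigree where C(8,3) = 56 subsets are enumerable exactly and
B = 10,000 draws. These sizes were chosen so every check is exact or has
known Monte-Carlo error, with the full suite completing in well under a
minute of compute per check.

## Known limitations

* Genotype-only by design: no phasing, no phased-haplotype IBD, no cM maps.
* The permutation p measures confinement frequency under random labels in
  *this* pedigree; it is not a genome-wide linkage significance.
* The refinement schedule beyond the bin-level exception budget follows a
  faithful but unverifiable reading of the published description (the
  detailed supplementary schedule is not in the main text).
* Pedigree reconstruction, kinship checking, variant annotation, CNV
  calling and gene-based rare-variant tests are out of scope; annotations
  and known-site lists are inputs.
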