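# Methods

`cryptaxon` implements the population-genomic inference chain used to
delineate cryptic taxa within a species complex from whole-genome SNP data:
site filtering and LD pruning, structure analysis (PCA, ancestry-informative
markers), windowed diversity and divergence scans, formal admixture tests,
diagnostic-marker discovery with individual classification, haplotype-
homozygosity selection scans, and coverage-based copy-number calling. This
note records the models, the defaults that matter, the numerical choices,
and what the synthetic fixtures do and do not establish.

## Data model and conventions

Genotypes are a `(variants, samples, 2)` integer array with `-1` as the
missing sentinel; half-calls (one called allele) are normalised to fully
missing on construction, because a half call contributes an odd number of
alleles and would bias allele counts. Coordinates are 1-based inclusive
everywhere in the data model and in VCF I/O; BED input is 0-based half-open
and converted on read. External site-quality masks (e.g. consortium site
filters) are consumed as a boolean column, never recomputed.

Site filtering retains biallelic variants passing the site filter with
minor-allele frequency at or above the threshold (default 1%, inclusive, as
"≥1%" reads); MAF is computed globally over all analysed samples, the
natural choice when the cohort structure is itself under investigation.
Monomorphic sites are always removed. Down-sampling to a fixed SNP count
per arm uses an explicit seed; every stochastic operation in the package
takes one.

Windows for per-base statistics contain a fixed number of *accessible*
bases (default 100,000), so the denominator — and hence comparability
across windows — is unaffected by patchy callability. The terminal window
of a contig may be short.

## LD pruning

Pairwise r is the Pearson correlation of alt-allele dosage vectors over
pairwise-complete samples; pairs with fewer than two complete observations
or zero variance are treated as unlinked. Pruning is the greedy forward
scan familiar from the standard toolkits: in moving windows (default 500
SNPs, step 250), any pair with r² above the threshold (default 0.01) drops
the *later* variant; the result is deterministic for a fixed input order.
Each iteration re-windows over the currently retained variants, so once a
pass removes nothing the retained set is a fixed point (idempotence after
convergence). One pass is the default.

At small sample sizes this threshold is aggressive on *independent* sites:
with n samples the null r² is ≈1/n, so r² > 0.01 occurs frequently by
chance below a few hundred samples. That is a property of the method, not
of this implementation; the pipeline demonstration prunes hard for exactly
this reason.

## PCA and AIM fractions

PCA uses the Patterson normalisation: each variant row of the dosage matrix
is centred by twice its mean allele frequency and scaled by `sqrt(p(1-p))`
with `p` the mean-frequency estimate; missing dosages are mean-imputed and
zero-variance rows dropped; the decomposition is by SVD. Components are
sign-fixed so the largest-magnitude variant loading is positive, making
runs reproducible under sample reordering.

The AIM fraction of an individual is the number of taxon-A diagnostic
alleles it carries divided by twice its called panel sites (the per-allele
counting definition; the quantity is only ever defined over called sites).
Cohorts are assigned taxon A above a mean fraction of 0.95, taxon B below
0.05, and "intermediate" strictly between; the boundary values assign to
the nearest taxon.

## Diversity and divergence

Per-site π is the mean pairwise difference `2 c_ref c_alt / (n (n-1))`,
summed per window and divided by accessible bases. Watterson's θ is `S/a1`
per accessible base. Tajima's D uses the standard constants; because
missingness makes the per-site sample size vary, the constants use the
median called-allele count over segregating sites in the window (rounded).
D is undefined (NaN, never 0) when S = 0 or n < 4.

Hudson's FST follows the Bhatia formulation: per site,
`N = (p1-p2)² - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)` and
`D = p1(1-p2) + p2(1-p1)`, combined as a **ratio of sums** within windows
and genome-wide — never a mean of per-site ratios, which is biased.
Sites with fewer than two called alleles in either cohort are skipped.
Window values are reported unclipped; slightly negative values are
estimator noise and are informative as such. Dxy is the per-site
`p1(1-p2) + p2(1-p1)` per accessible base.

The folded SFS is the histogram of minor-allele counts 1..n/2; sites with
any missing call are dropped by default so n is constant. Top-window
ranking annotates the k highest windows with gene spans that intersect the
window, inclusive on both ends (a gene touching a boundary is listed).

## Admixture statistics

f3(X; A, B) uses per-site numerator `(x-a)(x-b) - x(1-x)/(n_x-1)` (the
subtraction removes the target's sampling-heterozygosity bias) and,
normalised, the target's unbiased heterozygosity `2x(1-x)n_x/(n_x-1)` as
denominator; the raw (unnormalised) value is also available since only the
sign and Z matter for the admixture test. A significantly negative f3 —
estimate < 0 with Z < −5 — is evidence of admixture. The outgroup form
applies the same estimator with the outgroup as target; larger values mean
more shared drift between test and reference.

Patterson's D uses `ABBA = (1-p1)p2p3(1-p4)`, `BABA = p1(1-p2)p3(1-p4)`
on alt-allele frequencies, `D = Σ(ABBA-BABA)/Σ(ABBA+BABA)`. Under this
convention gene flow between P3 and P2 drives D positive (between P3 and
P1, negative), and |Z| > 5 is reported as significant. A polymorphic
outgroup is retained — the frequency formulation does not require fixed
ancestral states.

Standard errors come from a delete-one block jackknife over contiguous SNP
blocks (default 100,000 SNPs; at desk scale the pipeline default is 1,000
so that tens of blocks exist). The point estimate is invariant to the
blocking; SE² = (m−1)/m · Σ(R₋ⱼ − mean)². Z is undefined when SE is zero.

## Diagnostic markers and classification

The DAF table compares alt-allele frequencies of a focal cohort A and a
reference cohort B at biallelic sites, after excluding sites whose overall
genotyping success (fraction of called genotypes over both cohorts jointly)
is below 10%. Tiers nest: `fixed` (|ΔAF| = 1) ⊂ `ge98` (> 0.98) ⊂ `ge85`
(> 0.85). Each selected marker is oriented toward A (the allele commoner in
A). An individual's allelic percentage is `100 × A-alleles / (2 × called
markers)`; missing genotypes shrink the denominator rather than counting
toward either taxon. Classification is strict: > 80% assigns to taxon A,
< 20% to taxon B, otherwise unassigned; accuracy against truth labels
counts unassigned as an error. Discovery-cohort and held-out accuracy are
reported separately to control leakage.

## Selection scans

H-statistics are computed from exact haplotype identity within SNP-count
windows: `H1 = Σfᵢ²`, `H12 = (f1+f2)² + Σᵢ≥₃fᵢ²`, `H123` analogously,
`H2/H1 = (H1−f1²)/H1`. Window size is calibrated per cohort: candidates
are scanned and the smallest whose genome-wide H12 distribution has its
95th percentile at or below 0.1 is chosen — a deterministic rule standing
in for choosing by eye from the plotted distributions. If no candidate
satisfies the rule the largest is returned with an explicit warning flag.
Step defaults to half the window. Peaks are maximal runs of contiguous
windows above the threshold (default 0.1, the calibration constant).

## Copy-number calling

Read counts in 300-bp windows are normalised per sample to a copy-number
scale: twice the count divided by the sample's mean count over unfiltered
autosomal windows in the same GC bin (1-percentage-point bins, bins under
100 windows merged with neighbours). Windows outside the GC band (default
0.15–0.85) or below the mappability threshold (default 0.9) are excluded,
as are samples whose normalised autosomal variance exceeds 0.2.

The HMM has states = copy numbers 0..12; state k emits
`Normal(k · baseline/ploidy, σ)` with baseline the sample's median
normalised value on the contig class and a shared σ estimated robustly
(1.4826 × MAD, floor 0.05). Transitions: stay probability 1−t, uniform
switching t/12 with t = 10⁻⁵ — CNVs are rare, so the prior against state
changes is strong. Decoding is by Viterbi; forward–backward posteriors
gate call quality (mean posterior ≥ 0.9 over a run, below which a call is
flagged and excluded from frequencies). Calls are maximal runs of at least
5 adjacent windows above ploidy (amplifications) or below it (deletions,
symmetric rule); on the X chromosome male samples use ploidy 1. Cohort
frequency is the fraction of QC-passing individuals with at least one
overlapping call per region — presence/absence, regardless of copy count.

## Amino-acid substitution reporting

SNPs inside a transcript's CDS are placed into codons via the ordered CDS
intervals, strand-aware (minus-strand coding coordinates run backwards with
complementation); the reference codon is read from the genome FASTA and a
mismatch with the variant table's reference allele is an error. Translation
uses the standard code. Only non-synonymous changes are reported; several
SNPs causing the same substitution are aggregated (frequencies summed, as
alternative routes to one change). A substitution is retained when its
frequency strictly exceeds 5% in at least one cohort. Frequencies are
computed over called alleles. Multi-nucleotide codon changes are out of
scope and flagged per variant.

## Synthetic data: what it emulates, what it does not

Allele-frequency divergence uses the Balding–Nichols model: a taxon's
frequency at a site is Beta-distributed around the ancestral frequency with
variance `F p(1-p)`; expected Hudson FST between two taxa is ≈ (F1+F2)/2.
Ancestral frequencies default to Uniform(0.05, 0.95), excluding the
extremes to avoid monomorphic inflation. Nested drift along a tree
(`simulate_tree_frequencies`) produces the shared-branch correlations that
topology-dependent statistics (outgroup-f3 ordering, Patterson's D) rely
on; a star phylogeny cannot.

The three-taxa study scenario (CO-like, GA-like, BIS-like at drift 0.03,
cohort size 60, 50,000 variants, plus an outgroup at drift 0.25 and an
optional 50/50 BIS×CO admixed cohort) makes divergence heterogeneous, as
real speciation landscapes are: a small set of "divergence island" loci
(default 300) holds ancestrally rare variants (frequency 0.02–0.10) driven
to near-fixation (0.90–1.0) in the focal taxon only, emulating completed
taxon-specific sweeps. Under uniform drift at the 0.03 scale essentially
no site reaches |ΔAF| > 0.85 at desk scale — Beta(≈16,16) has no mass near
the extremes — so without islands no diagnostic panel exists; with them
the marker-discovery chain has a ground truth to recover. The CO-like
taxon carries its own disjoint island set, which is what makes CO/GA
ancestry-informative markers discoverable and reproduces the qualitative
structure of interest: the focal taxon scores GA-like on CO/GA AIMs while
an admixed cohort scores intermediate. Island loci raise genome-wide FST
slightly above the drift parameter (≈0.04–0.05 at these defaults).

Haplotypes are independent sites at given frequencies — there is **no
background LD**; sweeps are implanted by copying founder sequences across a
flank into a fraction of haplotypes (split across founders for soft
sweeps). Passing H12 tests therefore shows correct statistic computation,
calibration behaviour and peak recovery, not performance under realistic
recombination-generated LD. Similarly, coverage is negative-binomial
(default mean 60 reads per 300-bp window ≈ 30× with 150-bp reads,
size 500) with a unimodal quadratic GC bias peaking at GC = 0.45; implanted
CNVs scale the mean by copy/2. Real coverage has longer-range waviness and
mapping artefacts the generator does not model.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the chain at desk scale:
50,000 sites and cohorts of 60–100 diploids for frequency statistics,
100,000 sites for the introgression D test, 200 replicates for
false-positive calibration, 50–100 sweep replicates at 2,500 SNPs × 200
haplotypes, and 8,000–10,000 coverage windows × 60–100 samples with 40–50
implanted duplications. These sizes give comfortable statistical resolution
for every property checked while keeping a full run to minutes.

## Known limitations

* No coalescent/recombination realism in the generator (by design; the
  frequency-based statistics do not need it, the haplotype module's tests
  are correspondingly limited in what they show about real data).
* Tajima's D window constants use a single per-window n; extreme
  site-to-site missingness heterogeneity within a window is not modelled.
* The LD pruner is O(windows × window²) in pairwise correlations; it is
  intended for the pruned-input sizes of this analysis (10⁵–10⁶ SNPs), not
  whole-genome unfiltered variant sets.
* ADMIXTURE-style model-based ancestry, demographic model fitting, tree
  graph fitting and phasing are out of scope; their outputs are consumed,
  not produced.
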