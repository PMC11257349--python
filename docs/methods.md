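# Methods

`neowscan` detects fusions between a sex chromosome and an autosome in
female-heterogametic (ZW) taxa from population short-read data, and ships a
simulator that generates data under the same inheritance model so that every
stage of the inference can be validated against known truth.

## The inheritance model

In a ZW clade whose females are achiasmatic (no crossing over in female
meiosis — the rule in Lepidoptera), a W-autosome fusion creates a neo-sex
chromosome with a distinctive population-genomic footprint.  The fused copy
of the autosome is transmitted intact from mother to daughter and never
recombines, so:

1. every female carries exactly one fused haplotype and one ordinary
   (recombining) haplotype of that autosome, while males carry two ordinary
   haplotypes;
2. the fused haplotype accumulates derived mutations: those fixed before the
   clade's species split are shared by females of all descendant species,
   later ones are species-private;
3. at any such derived site all males are homozygous ancestral and all
   females heterozygous — an excess of female heterozygosity spread along
   the whole chromosome;
4. because females of different species share much of the fused haplotype,
   between-species differentiation (FST) measured in females drops on the
   fused chromosome while male FST is unaffected;
5. as the fused haplotype diverges, its reads eventually fail to map to an
   unfused reference: female depth falls toward half the autosomal value in
   degenerated segments, and heterozygosity vanishes there (only the
   ordinary haplotype is observed);
6. in Hi-C data from a female, the fused chromosomes form one molecule on
   exactly one haplotype, producing an excess of inter-chromosomal contacts
   that a male (ZZ) library does not show.

The package measures signatures 3-6 and a genealogical version of 1-2, and
integrates them into per-chromosome calls.

## Pipeline stages

**Genotype QC** (`site_filter.qc_filter`): site quality >= 30, genotypes
with depth < 5 set missing, site missingness < 5%, site-mean depth <= 1.5x
the genome-wide mean of site means (collapsed paralogs), and removal of
sites with heterozygote excess at p < 1e-5 under a one-sided Hardy-Weinberg
exact test (Levene/Haldane conditional distribution; only the excess side is
flagged because the purpose is paralog masking, and heterozygote *deficit*
is expected from population structure).  A normal-deviate screen (z > 2)
limits the exact-tail evaluation to sites that could conceivably fail; the
screened-out sites have p-values orders of magnitude above any cutoff in
use, so the screen does not change results.

**Candidate fusion sites** (`site_filter.candidate_fusion_sites`): a SNP is
a candidate for a clade when, in every clade species, (i) no male is
heterozygous, (ii) at least one female is heterozygous, and (iii) at most
one female is homozygous, with one additional female tolerated if her
genotype is half-called (one allele not called).  Candidates are thinned to
every k-th site (default k = 1000) before the genealogy test so the
evaluated sites spread along the chromosome.

**Windowed statistics** (`window_stats`): non-overlapping 50-kb windows.

* Heterozygosity proportion: per individual, #het / #called genotypes in
  the window (equivalently, nucleotide diversity computed with each
  individual as its own population); group value is the unweighted mean over
  individuals.  Windows with fewer than 50 sites are rejected — the
  FST-style site floor is not meaningful for a per-individual proportion,
  and 50 called genotypes keep its sampling error below ~0.07.
* FST/dxy/pi: per site, with n called allele copies of which x are
  alternate, pi = 2x(n-x)/(n(n-1)) per group and
  dxy = pA(1-pB) + pB(1-pA); window values are means over used sites
  (>= 2 called copies per group, variable in the pooled sample), and
  FST = 1 - mean(pi_A, pi_B)/dxy as a ratio of window means (Hudson-style).
  Windows with < 2500 used variable sites are rejected.  Negative estimates
  are reported as computed; note the exact identity-case value for two
  identical groups is -1/(n-1), which approaches the idealized 0 only as the
  sample grows.  Sex-stratified FST uses only the stated sex's samples from
  each group.
* Depth: per window, the mean over sites of the per-site group mean depth;
  500-bp windows for W-scaffold assignment.
* Rank tests: sexes are compared with a paired (by window) two-sided
  Wilcoxon signed-rank test (pairing is the default because both sexes are
  measured on the same windows; an unpaired mode is provided);
  chromosomes with a Kruskal-Wallis omnibus plus pairwise focal-vs-other
  rank-sum tests under Holm correction.

**Genealogy clade test** (`genealogy`): the prediction is that some clade of
the local genealogy contains exactly one haplotype from every clade female
and no male haplotype.  Instead of full ancestral-recombination-graph
inference, the package tests this set-membership property directly, in two
modes: *tree* mode builds a neighbor-joining tree (scikit-bio NJ on
normalized Hamming distances over the focal site +-50 SNPs, leaves ordered
lexicographically for deterministic ties, negative branch lengths clamped to
zero) and searches its bipartitions; *allele* mode uses the derived-allele
carrier set at the focal site itself (derived = the allele rarer in a
designated outgroup when given, else the minor allele) and therefore needs
no phasing — it is the default when the phasing switch-error rate is
unknown.  Verdicts: `full_pattern` (the set covers all clade species),
`partial_pattern` (the complete female-specific pattern holds within a
proper non-empty subset of species, which is recorded — a site private to
one species' matriline produces exactly this), else `mixed`.  Phasing switch
errors convert full patterns to mixed ones, which is how the mixed category
arises on real data; the simulator's switch-rate knob reproduces this
degradation.

**W-scaffold assignment** (`w_assignment`): per scaffold and sex, the
median of 500-bp-window mean depths, compared with the same-sex median over
designated autosomal scaffolds.  W-linked requires male median <= 0.1x the
male autosomal median AND female median >= 0.25x the female autosomal
median; both sexes within [0.5, 1.5]x is autosomal-like; anything else is
ambiguous.  Medians rather than means resist repeat-driven depth spikes; the
thresholds pass the expected hemizygous dosage (female ~ lambda/2, male ~ 0)
with wide margin and are configurable because no numeric standard exists for
this classification.  All rules are ratios, so calls are invariant to global
depth rescaling.

**Hi-C evidence** (`hic`): inter-chromosomal enrichment per chromosome pair,
with expected counts from the *median per-bin-pair trans rate* scaled by the
pair's bin-count product.  A marginal-product expectation
(T_a T_b / 2 T_trans) was considered and rejected: a junction that dominates
the trans signal inflates its own two marginals and the global total, which
caps the fused pair's score near 2 while pushing unrelated pairs above 1 —
it cannot isolate the fused pair at any threshold.  The median rate is
unmoved by one enriched pair, gives enrichment exactly 1 under uniform
trans noise, is invariant to uniform count scaling, and lets the fused
pair's score grow linearly with the junction signal.  A pair is flagged at
enrichment >= 5 with >= 100 observed trans contacts (no published numeric
threshold exists for this call; these defaults sit far above the Poisson
noise of any realistic library while flagging junctions that contribute at
least a few times the background).  With per-read-pair haplotype tags the
pooled female matrix is split into two haplotype matrices (untagged pairs
dropped and counted); count conservation (split1 + split2 + dropped =
pooled) is exact.

**Classifier** (`classify`): flags at p < 0.01 with required directions —
female het > male het (paired); focal female het > every other autosome
(omnibus + Holm post hoc, all significant); female FST < pooled
other-autosome female FST; female depth < male depth (advisory only: young
fusions show no mapping dropout, so depth reduction is supporting rather
than required evidence); genealogy full-pattern fraction >= 0.2 (bracketing
reported real-data fractions of roughly one quarter to one half).  A
chromosome is called `sex_linked_undetermined` when the two heterozygosity
flags hold together with the FST flag or the genealogy flag (single-group
clades cannot show the shared-haplotype FST signature and must supply the
genealogy flag).  Hi-C disambiguates W vs Z: the fused pair flagged in the
female (or fused-haplotype) matrix but not the male upgrades to `W_fused`;
flagged in the male upgrades to `Z_fused`; flagged in both is a recorded
conflict.  Resequencing-only runs can never exceed
`sex_linked_undetermined`, and every call carries the caveat that an
additional fusion of the ancestral Z to the neo-Z cannot be excluded.

## The simulator

`synthetic_data.simulate_dataset` draws, per chromosome: a background panel
of biallelic sites at uniform random positions with ancestral frequencies
from Beta(0.5, 0.5) (heavy at the extremes like a neutral frequency
spectrum) perturbed per species by Balding-Nichols Beta(p(1-t)/t,
(1-p)(1-t)/t); a fused lineage founded from one panel haplotype with
Poisson(mu (T_f - T_s) L) shared and Poisson(mu T_s L) species-private
derived mutations at new positions; diploid genotypes assembled from
haplotypes (females on fused chromosomes receive one panel + the species'
fused haplotype, in randomized emitted order recorded in the truth);
Poisson(lambda * copies/2) depth; 50-kb segmental dropout of the fused
haplotype with probability `p_degenerate` per segment (inside a degenerated
segment females become homozygous for the panel haplotype at half depth);
optional hemizygous Z (females emitted as homozygous diploid calls, as a
diploid caller would report them) and female-only W scaffolds; and phasing
switch errors applied to the emitted haplotypes at a per-interval rate.
Identical configurations (including the seed) are byte-identical.

Defaults (the package's study conditions): 5 autosomes x 2 Mb, 2 species,
10 females + 10 males per species, 160,000 background sites per chromosome,
mu = 2.9e-9 per site per generation and Ne = 1e7 (lepidopteran-scale
values), recombination 6 cM/Mb (metadata only — achiasmatic females do not
recombine, and background sites are drawn in linkage equilibrium),
theta = 0.2 (sister-species-level differentiation), one fusion on chr4 at
T_f = 2e6 generations with the species split at T_s = 5e5 (fusion ages are
free parameters, not estimates; these give ~220 shared derived sites per
50-kb window), depth lambda = 30, p_degenerate = 0.05 (a handful of dropout
windows per chromosome, the early-degeneration regime), switch rate 0
(swept explicitly in tests).  The site density is chosen so that default
50-kb windows retain ~2800 usable variable sites after Balding-Nichols
drift makes ~30% of sites monomorphic in a 40-haplotype sample — above the
2500-site rejection floor, so the FST signature is measurable under the
default conditions.  The Z chromosome and W scaffolds are opt-in
(`include_z`, `n_w_scaffolds`) so the default clade is the five-autosome
detection scenario; the sex-chromosome components are exercised with
explicit configurations.

Hi-C: bins of 50 kb; within a molecule the expected count between bins at
distance d (in bins) is alpha (1+d)^-gamma with alpha = 200, gamma = 1;
separate molecules share a uniform trans-noise floor (Poisson mean 0.5 per
bin pair per haplotype); on the fused haplotype the fused chromosomes form
one molecule in fusion-event order.  95% of read pairs carry a haplotype
tag; the rest are unassigned.

### What the generator does and does not emulate

It reproduces the moments the inference consumes: sex- and
species-stratified genotype frequencies, the matrilineal fused haplotype
with shared/private mutation layers, depth dosage, segmental mapping
dropout, phasing switch errors, and junction-driven Hi-C contacts.  It does
**not** simulate linkage disequilibrium among background sites (none of the
implemented signatures uses background LD; the fused haplotype's private
mutations supply the haplotype structure the genealogy test needs), nor
within-species matriline variation (one fused haplotype per species — the
expectation for a shared non-recombining lineage), nor inversions,
translocations, selection, drive or endosymbionts, nor mappability/GC
artifacts in depth.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every real
data artifact.

## Numerical and design notes

* Coordinates are 0-based half-open internally, 1-based at VCF boundaries;
  the conversion is its own tested function.
* Half-calls are a distinct genotype code; they satisfy criterion (iii)'s
  allowance but are treated as missing in allele-frequency statistics (the
  called allele's identity is not retained without a haplotype matrix).
* The "1.5x mean depth" paralog cap compares each site's across-sample mean
  depth with the genome-wide mean of those site means — per-site masking is
  the stated purpose of the rule.
* Window aggregation uses a single reduceat pass for non-overlapping
  windows and a cumulative-sum fallback for overlapping ones; both paths
  are tested against per-window loops.
* Subsampling takes 1-based ranks k, 2k, ... after sorting passing sites by
  (chromosome, position); fewer than k sites yield an empty subsample.
* The genealogy scan tightens k automatically when every-1000th would leave
  fewer than ~20 sites, so the clade fraction is estimated from ~100 sites.
* Degenerate inputs: all-zero paired differences give p = 1 with a note;
  chromosomes whose windows are all rejected get missing summaries with a
  warning; an empty candidate subsample yields an empty summary.

## Problem sizes used in the validation suite

The test suite and the acceptance script run the full pipeline at the
default conditions across seeds (20 seeds for detection, 20 for the null),
500 small no-signal replicates for rank-test calibration, 100 seeds for
W-scaffold assignment, and scaled-down configurations for the genealogy
sweep (one 500-kb chromosome, 5+5 samples per species) — sizes chosen so a
full validation completes on a single CPU in well under half an hour while
every check retains its statistical meaning.
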