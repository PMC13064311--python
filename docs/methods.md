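# Methods

This note records the statistical definitions the package implements, the
choices made where a convention was genuinely open, what the synthetic
data generator does and does not emulate, and the problem sizes used by
the default test suite and the acceptance script.

## Genotype model and filter cascade

Genotypes are held as a samples × variants alt-dosage matrix (0/1/2,
−1 missing) with variant metadata in a DataFrame; phased data additionally
carry a 2n × m haplotype matrix.  User-facing coordinates are 1-based
inclusive; interval arithmetic (feature overlap) converts to 0-based
half-open internally.

The filter cascade runs in three stages, in this order: hard filters on
INFO/QUAL annotations, then bi-allelic/SNP/autosome restriction, then the
joint genotyping-rate and minor-allele-count screen.

* A hard filter removes a variant only when the annotation is **present**
  and violates its threshold (strict inequalities; MQ = 40.0 survives
  MQ < 40.0).  Missing annotations never remove a variant but are counted
  in the report — the convention of the standard variant-filtration tools,
  which emit a warning rather than a FILTER flag when an annotation is
  absent.
* Multi-allelic records are retained at read time and removed by the site
  filter, so the filter report can count them.
* Call rate and MAC are computed jointly over all samples.  Both bounds
  are inclusive (call rate ≥ 0.5, MAC ≥ 2).  The cascade is idempotent.

## Diversity, heterozygosity, inbreeding

Per-site nucleotide diversity is the mean pairwise difference
2a(n−a)/(n(n−1)) for a alt copies among n called alleles.  Windowed π
sums site values over a 40 kb window sliding by 20 kb, anchored at
position 1 of each chromosome, and divides by the **full window span**
(invariant sites count in the denominator, matching the windowed-π
convention of the common VCF tools); values are reported in percent.
The anchor choice is ours — the grid origin is not a published
convention — and each SNP contributes to up to two windows.

Individual heterozygosity follows the method-of-moments accounting:
with allele frequency p and called allele count n at a site, the expected
per-site homozygosity is 1 − 2p(1−p)·n/(n−1); E_hom sums this over the
polymorphic sites at which the individual is called, O_hom counts its
homozygous calls there, and F = (O_hom − E_hom)/(S − E_hom).  F is
undefined (NaN) when S = E_hom.  Population H_e averages the unbiased
2p(1−p)·n/(n−1) over within-population polymorphic sites; the formula is
our choice, as the unbiased small-sample estimator.  Per-population
statistics always subset the sample set first, so frequencies are
within-population.

The shared/private partition assigns each SNP to the exact subset of
populations in which it carries both alleles; subset counts sum to the
number of SNPs polymorphic anywhere.

## Runs of homozygosity

A two-state HMM (NORMAL, AUTOZYGOUS) over the het/hom status of a
sample's calls at sites polymorphic within its population.  Emissions at
a site with population alt frequency p:

* P(het | NORMAL) = 2p(1−p)(1−e) + e(1−2p(1−p))
* P(het | AUTOZYGOUS) = e

with genotyping-error rate e = 1e−3.  Transitions between adjacent
informative markers d bp apart are 1 − exp(−t·d), with t_in = 1e−8 /bp
into and t_out = 1e−7 /bp out of the autozygous state; the initial
distribution is the stationary point of the two rates.  These three
parameters are not published values — the reference HMM's defaults live
in an external tool — and were set so that expected segment lengths are
in the Mb range; all are exposed in `HMMParams`.  Decoding is exact
Viterbi (checked against exhaustive path enumeration in the tests).
Missing calls are skipped with distance accumulating; monomorphic sites
carry no evidence and are excluded before decoding.

Segment coordinates are the first/last SNP positions of the decoded run —
reproducible from the SNP set alone, unlike midpoint conventions.
Filtering keeps segments ≥ 300 kb with ≥ 10 SNPs (both inclusive).
Length classes partition as [0.3,1), [1,2), [2,4), [4,8), [8,10),
[10,16), [16,∞) Mb; the first class is 0.3–1 Mb so the classes partition
(a "0.3–1.3" first bin would overlap the second).  Per-individual means
average over all individuals of a population, zero-carriers included.
F_ROH divides each individual's total ROH length by the autosomal genome
size, 960.8 Mb by default and configurable (simulated genomes pass their
true size).

## Weir–Cockerham F_ST

The two-population variance components per biallelic site, from sample
sizes n_i (diploids with calls), alt frequencies p_i and observed
heterozygote fractions h_i, with r = 2:

    n̄ = (n₁+n₂)/2,  n_c = (r·n̄ − Σn_i²/(r·n̄))/(r−1),
    p̄ = Σn_i p_i/(r·n̄),  s² = Σn_i(p_i−p̄)²/((r−1)n̄),  h̄ = Σn_i h_i/(r·n̄)
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
    c = h̄/2

Window and genome-wide values are **ratio-of-sums** Σa/Σ(a+b+c) over
informative sites (the "weighted" estimator), never means of per-window
ratios.  Sites with fewer than two called diploids in either population,
or monomorphic across both, are uninformative.  Negative estimates are
reported as computed.

For a two-deme equilibrium migration model this estimator converges to
1 − T_within/T_between = 1/(1 + 8Nm) (structured-coalescent pairwise
coalescence times T_within = 4N, T_between = 4N + 1/(2m)).  The
often-quoted island-model value 1/(1 + 4Nm·(d/(d−1))²) describes F_ST
against the pooled total of a d-deme metapopulation, which is a different
quantity; the test suite verifies the pairwise form against both the
forward simulator and an independent coalescent (msprime) oracle.

## Linkage disequilibrium

Decay uses genotype-mode r² (squared Pearson correlation of dosage
vectors over jointly called samples) by default — no phasing requirement,
matching the common decay tools; haplotype-mode r² = D²/(p_A q_A p_B q_B)
is available for phased data.  All intra-chromosomal pairs within 500 kb
are binned: per-bp resolution up to 1 kb, then 1 kb-wide bins.  An
optional pair-subsampling fraction exists for very dense panels and warns
when active.

Pruning replicates the 50-SNP window / 5-SNP step / r² > 0.2 greedy scan;
the later SNP of a violating pair is dropped (a deterministic tie-break;
the published procedure does not specify one).  The scan repeats over the
surviving SNPs until a fixed point, which makes pruning idempotent and
guarantees no surviving within-window pair violates the threshold.

## PCA and admixture

PCA standardizes each SNP as (g − 2p)/√(2p(1−p)), zeroes missing entries
after centring (the convention of the standard genotype-PCA tools),
eigendecomposes the sample covariance, and reports each eigenvalue's
share of the positive spectrum.  Component signs are fixed so the
largest-magnitude sample loading is positive.

The admixture model maximizes the binomial log-likelihood
LL = Σ g ln θ + (2−g) ln(1−θ), θ = QF, by EM with the classic closed-form
updates (monotone in LL, asserted per iteration in tests), F clipped to
[1e−6, 1−1e−6], and five seeded restarts by default.  Missing genotypes
contribute nothing.  Model choice masks random non-missing **entries**
(not samples) into 20 folds, refits, and scores held-out entries by
binomial deviance against 2θ̂; the published workflow's CV internals are
not described, so entry-masking deviance is our design.  Best k minimizes
mean CV error.

## Selection scans

EHH partitions the carriers of a focal core allele by their allele string
from the core out to a marker; EHH(x) = Σ_g C(s_g,2)/C(n,2).  Curves
start at 1.0 at the core and truncate before the first marker where EHH
drops below the floor (0.05).  iHH integrates EHH trapezoidally against
physical position over both flanks; integration is over bp, as no genetic
map is part of the pipeline.  The allele-agnostic variant used for
XP-EHH partitions all haplotypes of a population starting from the whole
set at the core (so EHH(core) = 1 by construction).

iHS = ln(iHH_ancestral/iHH_derived) at cores with known ancestral
orientation and MAF ≥ 0.05, standardized within derived-allele-frequency
bins of width 0.025 (sample SD; bins with fewer than two scores stay
undefined).  The MAF floor, EHH floor and bin width are the widely used
defaults of the haplotype-scan literature and configurable.  XP-EHH =
ln(iHH_A/iHH_B) standardized genome-wide; positive scores mean longer
haplotypes in the first-named (reference) population, and swapping the
populations negates raw scores exactly.

Window aggregation averages |standardized score| in the 40 kb / 20 kb
grid; windows with fewer than 10 **scored** SNPs are dropped (only scored
SNPs contribute to the mean, so they are what is counted).  The outlier
threshold is the nearest-rank (1 − 0.001) empirical quantile of the
analysed windows (computed after dropping under-filled windows — the
distribution "for the respective comparison" is the analysed one), and
windows strictly above it are flagged.  Overlapping or abutting flagged
windows merge into sweep regions; windows separated by any gap stay
separate.  Regions are annotated with all overlapping features
(half-open overlap after coordinate normalization; BED is 0-based
half-open, GFF3 1-based inclusive); gene-void regions report the nearest
feature by edge distance, with ties reporting all.

## The simulator and the study fixture

Forward-in-time Wright–Fisher: discrete non-overlapping generations,
parents drawn uniformly (no selfing), per-gamete Poisson crossovers with
no interference plus independent assortment at chromosome boundaries,
per-generation Poisson infinite-sites mutations on a continuous
coordinate, and optional additive viability selection (rejection
sampling on offspring fitness 1, 1+hs, 1+s at the sweep site).  A
forward simulator was chosen over a coalescent one so that selection,
non-random mating and pedigree inbreeding are exact by construction;
msprime appears only as an independent oracle in one test.  Pedigree
inbreeding is tracked through the deme's kinship matrix, so each sampled
individual's F is exact; a configurable reference generation restarts the
bookkeeping so F measures recent inbreeding.  Two mating-system knobs
exist: a sib-mating probability, and a monogamous breeding-pair structure
(offspring multinomially assigned to a small number of pairs, as in
closed lines with few sires and dams) under which sib-bias applies to
pair formation.  The founder deme can start monomorphic or at the neutral
equilibrium frequency spectrum (expected site count θL/i at derived count
i); the SFS start is at mutation–drift equilibrium for heterozygosity but
at linkage equilibrium, so a burn-in builds short-range LD.

`emulate_study(seed)` produces the six-population design with sample
sizes 49, 25, 20, 20, 23, 24: an outgroup at the ancestral size (most
diverse), two intermediate commercial lines, two inbred lines (long-term
N = 50 plus a recent 15-generation bottleneck to 8 breeding pairs with
sib-bias 0.3 — long ROH and slow LD decay without starving the ROH HMM of
informative markers), and a focal population carrying a hard sweep
(s = 0.5, h = 0.5) introduced 30 generations before sampling at the
centre of chromosome 3, re-run internally if lost until the derived
allele reaches 90 %.  The genome is 5 chromosomes × 5 Mb (so the window
grid exceeds 1000 windows and the top-0.1 % rule flags at least one
window), μ = 8e−8 and r = 8e−8 per bp per generation, with the sweep
chromosome recombining four times faster — chicken macro- and
microchromosomes genuinely span such a range, and the faster map keeps
the sweep's hitchhiking footprint well inside the chromosome so the scan
can localize it.  The recorded truth interval spans the establishment-
phase hitchhiking radius 2s/(r·ln 2N) around the sweep site, capped at
1 Mb.

These parameters reproduce the *orderings* of the motivating study design
(outgroup most diverse; inbred lines most ROH-burdened and slowest LD
decay; sweep recoverable by XP-EHH) — not absolute genome-scale values,
which would require hundreds of samples and a 1 Gb genome.  The generator
also does not emulate: genotype-likelihood uncertainty (missingness and
genotype error are optional flat rates), reference bias, variable
mutation/recombination along chromosomes beyond the per-chromosome
multipliers, gene conversion, overlapping generations, or sex
chromosomes.  Passing recovery tests therefore show that the statistics
respond correctly to planted demography and selection at desk scale, not
that real-data preprocessing artifacts are handled.

## Numerical choices and problem sizes

Viterbi and EHH walks run in log/stable space via numba kernels; the test
suite holds them to exhaustive-enumeration oracles (≤ 12 sites for the
trellis, ≤ 16 haplotypes × 30 markers at 1e−12 for EHH/iHH).  EM clips
frequencies at 1e−6 to avoid log(0).  Quantiles use the nearest-rank
convention with strict ">" flagging, so a reported threshold reads like a
"top 0.1 %, value > t" rule.  Table summaries use sample (n−1) standard
deviations; rounding is display-only.

Default problem sizes: the recovery suite runs 20 study replicates
(~19,000 SNPs, 161 samples each) plus 10-seed LD-ordering and 10-seed
admixture-CV fixtures; closed-form checks use 50 neutral replicates
(N = 200, 1 Mb, 10N burn-in) and 20 two-deme replicates (N = 100, 1 Mb,
2000 generations).  The acceptance script runs one study replicate,
20 neutral and 8 island replicates, and 3 CV fixtures.  All randomness
flows from explicitly passed seeds through numpy Generators; numba
kernels receive pre-drawn random arrays, so results are bit-reproducible
for a given seed.

## Known limitations

* The ROH HMM needs within-population polymorphism around autozygous
  tracts; in populations reduced to a few hundred informative sites per
  genome its recall drops (visible in the extreme-bottleneck regime).
* W&C components are implemented for the two-population case only (all
  pipeline uses are pairwise); r is kept symbolic in the formulas for
  readability.
* iHS requires known ancestral orientation; sites with unknown ancestral
  state are silently ineligible rather than folded.
* Entry-masking CV differs from sample-holdout CV; with very few SNPs it
  favours small k (underfitting), so model choice needs a few hundred
  pruned SNPs to be reliable.
* The VCF writer emits uncompressed VCF 4.2 with GT only; genotype
  likelihoods and BCF are out of scope.
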