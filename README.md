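# popkit

Post-variant-calling population genomics for resequencing panels of
structured populations — built around the kind of question a conservation
or livestock geneticist asks of a local breed: how diverse is it, how
inbred, how distinct from commercial lines and from the wild progenitor,
and which genomic regions carry signatures of selection.

Starting from a jointly genotyped multi-sample VCF and a sample→population
map, the package provides:

* **SNP filtering** — GATK-style hard filters (QD < 2.0, QUAL < 30, SOR > 3,
  FS > 60, MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8.0), restriction
  to bi-allelic autosomal SNPs, genotyping rate ≥ 50 %, minor allele count ≥ 2.
* **Diversity and inbreeding** — nucleotide diversity π in 40 kb / 20 kb
  sliding windows (percent of window span), individual observed
  heterozygosity H_o, unbiased expected heterozygosity H_e, and the
  method-of-moments inbreeding coefficient
  F = (O_hom − E_hom)/(S − E_hom).
* **Runs of homozygosity** — a two-state (autozygous / normal) HMM with
  distance-dependent transitions and error-tolerant emissions, Viterbi
  decoding, filtering at ≥ 300 kb and ≥ 10 SNPs, length-class tables, and
  F_ROH = total ROH length / autosomal genome size (960.8 Mb default).
* **Differentiation** — Weir–Cockerham variance components a, b, c per
  site; windowed and genome-wide *weighted* F_ST = Σa / Σ(a+b+c);
  pairwise population matrices.
* **Linkage disequilibrium** — r² decay curves to 500 kb (full resolution
  below 1 kb, 1 kb bins beyond) and PLINK-style `--indep-pairwise 50 5 0.2`
  pruning.
* **Structure** — PCA on standardized genotypes, and a binomial-likelihood
  admixture model fit by EM with entry-masking 20-fold cross-validation
  over k.
* **Selection scans** — EHH, integrated haplotype homozygosity, iHS
  (standardized within derived-allele-frequency bins) and XP-EHH
  (standardized genome-wide), |score| averaged in 40 kb / 20 kb windows
  with ≥ 10 SNPs, empirical top-0.1 % outlier calling, merging of adjacent
  candidate windows into sweep regions, and annotation against gene / QTL
  intervals (BED or GFF3), including nearest-feature reporting for
  gene-void regions.
* **A forward Wright–Fisher simulator** — discrete generations, Poisson
  crossovers and infinite-sites mutations, viability selection at a sweep
  locus, sib-mating and breeding-pair structure for autozygosity, exact
  pedigree inbreeding via kinship tracking, and a six-population study
  design (`simulate.emulate_study`) with a planted sweep and known truth.

## Worked example

```python
import numpy as np
from popkit import simulate, diversity, fst, roh, selection

gm, pops, truth = simulate.emulate_study(seed=1)

pi = {p: diversity.windowed_pi(gm, pops, p).data["value"].mean()
      for p in pops.populations()}
print({p: round(v, 5) for p, v in pi.items()})

segs = roh.filter_roh(roh.detect_roh_population(gm, pops))
froh = roh.f_roh(segs, "inbredA_0", genome_size=25_000_000)
print(f"F_ROH(inbredA_0) = {froh.f_roh:.3f}")

hs = selection.HaplotypeSet.from_genotypes(gm, pops)
track = selection.xpehh_scan(hs, "focal", "outgroup")
wins = selection.window_scores(track, gm.chrom_lengths)
thr, flagged = selection.call_candidates(wins)
for r in selection.merge_regions(flagged):
    print(f"candidate sweep {r.chrom}:{r.start}-{r.end}  "
          f"|XP-EHH|_w max {r.max_score:.2f}")
print("true sweep interval:", truth.sweep_interval)
```

Output (seed 1):

```
{'focal': 0.00414, 'outgroup': 0.00654, 'commercialA': 0.00491,
 'commercialB': 0.00481, 'inbredA': 0.0017, 'inbredB': 0.00085}
F_ROH(inbredA_0) = 0.187
candidate sweep 3:2000001-2040000  |XP-EHH|_w max 3.40
true sweep interval: ('3', 1910192, 3089810)
```

The outgroup is the most diverse population, the two inbred lines the
least; the inbred sample's F_ROH reflects its recent breeding-pair
bottleneck; and the flagged top-0.1 % XP-EHH window falls inside the
planted sweep's hitchhiking interval on chromosome 3.

A `popkit` console command exposes the same steps
(`popkit filter|diversity|roh|fst|ld|structure|scan|summarize`, plus
`popkit simulate --config sim.yaml` for arbitrary demographies and
`popkit emulate-study` to write the study bundle as
VCF + popmap + truth JSON).

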