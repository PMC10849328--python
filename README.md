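# gamescan

Population-genetic scans for cohorts of fighting chickens (gamecocks) and
chickens bred for other purposes. Gamecocks around the world share a
selected haplotype — in the real birds, a ~1.6 Mb region on Chromosome 2
peaking in an intron of *ISPD* — whose "game" allele sits at high frequency
in gamecocks and low frequency in nongame birds. This package implements
the analysis chain that finds such a locus from a multi-sample VCF, plus a
cohort simulator so the whole chain runs, and is tested, with no external
sequencing data.

The pipeline:

- **Hard filtering** — per-genotype masks (DP < 4, GQ < 30,
  DP ≥ 1.65 × the sample's mean autosomal depth, heterozygous calls with
  AD < 2 for either allele or allele balance outside [0.25, 0.75]),
  per-site drops (indels, multiallelics, MQ < 50, MQ0F > 0.1, sites ≤ 3 bp
  from an indel, mapability-mask exclusion, > 20% missingness), per-sample
  QC (> 30% missing genotypes; advisory mitochondrial-contamination flag).
- **Selection scans** in variant-count windows:
  - Hudson's F<sub>ST</sub> as a ratio of averages,
    N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
    D = p₁(1−p₂) + p₂(1−p₁), window value ΣN/ΣD;
  - the population branch statistic
    PBS = (T_{f,c1} + T_{f,c2} − T_{c1,c2})/2 with T = −ln(1−F_ST);
  - observed heterozygosity (het calls / called calls);
  - pixy-style nucleotide diversity π = Σdiffs/Σcomps over all sites
    including invariant ones, robust to missing genotypes.
- **Stratified GWAS** — pairwise identity-by-state distance,
  complete-linkage clustering into K strata with K chosen by genomic
  inflation λ (ties → more samples in strata containing both phenotypes),
  Cochran–Mantel–Haenszel 1-df χ² on per-stratum allele-count tables,
  genomic control (λ = median χ²/0.4549, floored at 1), and 10,000
  within-cluster permutations (pointwise and family-wise max-T p).
- **Structure** — LD pruning (r² ≤ 0.2 within 50 kb), allele-frequency
  standardised genotype PCA, Fisher exact and Mann–Whitney U contrasts.
- **Simulator** — Balding–Nichols demes (population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F)) around a Beta-distributed ancestral
  frequency, a selected locus overridden per phenotype group, a swept
  linked haplotype block, Poisson DP / binomial AD / monotone GQ read
  evidence, and missingness.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_filter_qc.py
python analysis/03_selection_scans.py
python analysis/04_association.py
```

On the default cohort (48 gamecocks, 62 nongame chickens in three demes;
selected locus at 1,000,000 bp, frequencies 0.895 vs 0.037) this prints:

```
selected locus at 1,000,000 bp: game-allele frequency 0.902 in gamecocks,
    0.041 in nongame (configured 0.895 / 0.037)
...
top PBS window: 964,259-1,016,536 bp (PBS=0.408); selected locus at 1,000,000 bp inside
gamecock heterozygosity minimum: 991,776-1,034,662 bp (H_obs=0.1664)
nongame heterozygosity minimum: 413,615-466,870 bp (H_obs=0.2131)
pi in block (gamecock): 0.1421 over 146 usable sites
pi in block (nongame): 0.1963 over 146 usable sites
block diversity reduction in gamecocks: 27.6%
```

i.e. the selection scans localise the swept block in gamecocks (top PBS
window and lowest gamecock heterozygosity both straddle the locus; nongame
birds dip elsewhere), and in-block diversity is reduced only in gamecocks.
The association driver then reports λ per K, the chosen stratification,
and the locus as the top genomic-control hit with only in-block variants
passing the family-wise permutation threshold.

The same stages are available as a single command over a TOML config:

```
gamescan run --config run.toml        # simulate → filter → scan → assoc → pca
gamescan simulate --out sim.vcf --sheet samples.tsv --seed 1
gamescan filter --vcf in.vcf --sheet samples.tsv --out out.vcf --report rep.tsv
```

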