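# quidsig

Somatic mutational-signature and CpG-island enrichment analysis for
tongue-carcinoma cohorts — in particular, cohorts associated with betel-quid
(areca nut) chewing, whose genomes carry a characteristic GCG>GTG
(CpG-deamination-like) substitution pattern and an elevated mutation rate in
CpG islands.

The package is aimed at cancer-genomics analysts who have somatic SNV calls
(VCF or MAF), a reference genome (FASTA) and a region annotation (BED) and
want a tested, reproducible implementation of the following analysis chain:

1. **Context classification** — every somatic single-base substitution
   (SBS) is collapsed onto the pyrimidine strand and assigned to one of the
   96 classes (6 substitution types × 16 flanking-base contexts), giving a
   samples × 96 count matrix.
2. **Signature extraction** — nonnegative matrix factorization
   `M ≈ P·E` (multiplicative updates, Frobenius objective) with the number
   of processes `K` chosen from bootstrap signature **stability** (mean
   silhouette width of re-extracted signatures clustered by cosine
   distance) together with the Frobenius reconstruction error over
   `K = 1..15`.  Consensus signatures are matched to a reference panel by
   cosine similarity and complete-linkage hierarchical clustering; exposures
   are refit by nonnegative least squares.
3. **CpG-island enrichment** — mutation rates are compared between island
   *core* windows (island ± 50 nt) and *flank* windows (501–1000 nt outward
   from each edge) as a rate ratio
   `fold = (n_core/core_bp) / (n_flank/flank_bp)` with a two-sided Fisher's
   exact test, for all mutations, the 6 substitution types and the 16 C>T
   context classes.
4. **Cohort statistics** — per-sample mutation loads (one-way ANOVA),
   GCG/TCN context-pattern proportions and strand-preference tests, exposure
   comparisons (unpaired t-test), and gene mutation-frequency 2×2 Fisher
   tests.

Because the original patient genomes are not publicly deposited, the package
ships a **synthetic-data module** (`quidsig.simulate`) that emulates the
cohorts' statistical structure — genome-scale SBS loads, a three-process
signature mixture (an NCG>NTG-dominated process, a TCN-concentrated
APOBEC-like process, and a flat background process) and a configurable
CpG-island rate multiplier — so every stage of the pipeline is testable
end-to-end without any download.

## Worked example

```python
import numpy as np
from quidsig import simulate as sim
from quidsig.context import build_context_matrix
from quidsig.enrichment import build_windows, per_class_enrichment
from quidsig.signatures import extract_signatures, match_to_reference

profile = sim.PROFILES["bq_tc"]            # 15-sample betel-quid profile
cohort = sim.simulate_cohort(profile, seed=7, n_mut_per_sample=3000)

windows = build_windows(cohort.islands, cohort.genome)
table = per_class_enrichment(cohort.catalog, windows, cohort.genome)
row = table.loc["all"]
print(f"island fold change: {row['fold']:.2f}  (p = {row['p_value']:.2e}, "
      f"{row['n_core']} core / {row['n_flank']} flank mutations)")
ct = table.loc["C>T"]
print(f"C>T share of core mutations: {100 * ct['n_core'] / row['n_core']:.1f}%")

matrix = build_context_matrix(cohort.catalog, cohort.genome)
signatures, exposures, info = extract_signatures(matrix, k=3, n_bootstrap=50, seed=7)
print(f"signature stability: {info['stability']:.2f}")
_, best, _ = match_to_reference(signatures, sim.synthetic_reference_panel(30))
print(best.round(3))
```

prints

```
island fold change: 2.18  (p = 1.93e-68, 1551.0 core / 646.0 flank mutations)
C>T share of core mutations: 48.6%
signature stability: 0.80
      best_match  cosine    tie
query
S1         REF01   0.984  False
S2         REF02   0.764  False
S3         REF01   0.859  False
```

The simulated cohort's islands carry mutations at about twice the flanking
rate (the profile's configured multiplier is 2.05), roughly half of the
island mutations are C>T, and the extraction recovers the dominant
NCG>NTG-concentrated process essentially perfectly (S1 vs its generating
signature, cosine 0.98).  The weak APOBEC-like process (9% mean exposure) is
recovered only approximately (S2, cosine 0.76) and the flat background
signature (S3) absorbs part of the dominant process — a faithful picture of
how hard minor processes are to decipher at this cohort size.

## Command line

```sh
quidsig simulate --profile bq_tc --seed 7 --out simdir/   # FASTA+BED+VCFs+truth
quidsig matrix   --vcf simdir/bq_tc_01.vcf --sample bq_tc_01 \
                 --ref simdir/genome.fa --out matrix.tsv
quidsig extract  --matrix matrix.tsv --kmin 1 --kmax 15 --bootstrap 100 --seed 7
quidsig enrich   --bed simdir/islands.bed --vcf simdir/bq_tc_01.vcf \
                 --sample bq_tc_01 --ref simdir/genome.fa --out enrichment.tsv
quidsig compare  --maf cohort.maf --cohorts cohorts.tsv
```

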