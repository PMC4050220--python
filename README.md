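# snpbarcode

Particle swarm search for **SNP barcodes** — combinations of single-nucleotide
polymorphisms with fixed genotypes whose carrier frequency differs maximally
between a high- and a low-phenotype group.

## The problem

Case-control SNP association studies often find no significant single-SNP
effects even when joint (epistatic) effects exist. Given n subjects scored on
a continuous phenotype and genotyped at m SNPs (each coded 1/2/3 for the two
homozygotes and the heterozygote), subjects are dichotomized at the phenotype
mean into HIGH (score > mean) and LOW (score ≤ mean) groups. A *barcode*
B = {(s₁, g₁), …, (s_k, g_k)} selects k distinct SNPs with one genotype each;
a subject carries B when its genotype equals gⱼ at every sⱼ. The objective is

    F(B) = |HIGH ∩ B| − |LOW ∩ B|

the signed difference in carrier counts. Exhaustive search over C(m,k)·3^k
candidates is exact for small panels; for larger ones a particle swarm
optimizer (PSO) searches the space: each particle is a continuous vector of
2k coordinates decoded to a barcode, moved by

    v ← w·v + c₁r₁(pbest − x) + c₂r₂(gbest − x),    x ← x + v

with inertia w decreasing linearly from 0.9 to 0.4, c₁ = c₂ = 2, population
50, 100 iterations. The best barcode is then evaluated as a 2×2 table
(carriers vs. others × HIGH vs. LOW): odds ratio (ad)/(bc), Woolf 95%
confidence interval, uncorrected Pearson chi-square P, and post-hoc power
from the noncentral chi-square distribution.

This is aimed at statistical geneticists and psychiatric-genetics groups
exploring SNP-SNP interactions on small candidate panels.

## Worked example

Simulate a 182-subject, 5-SNP dataset with a planted two-SNP interaction
(carrier rates 0.337 vs 0.194), search it, and evaluate the best barcode:

```bash
snpbarcode simulate --seed 1 --out synth.csv
# wrote 182 subjects x 5 SNPs (mean-split groups: 89 high / 93 low)

snpbarcode search --input synth.csv --k 2..3 --seed 1 --out report.tsv
# k=2: SNPs(1,4) 3-3  high=30 low=10 difference=20
# k=3: SNPs(1,4,5) 3-3-3  high=21 low=6 difference=15

snpbarcode evaluate --input synth.csv --barcode "1:3,4:3" --out eval.tsv
# SNPs(1,4) 3-3: high=30 low=10 OR=4.220 (1.916 to 9.296) P=0.000 power=0.962
```

The search recovered the planted barcode SNPs(1,4) with genotypes 3-3: 30 of
89 HIGH subjects carry it against 10 of 93 LOW subjects (difference 20). Its
odds ratio of 4.22 means carriers have ~4-fold higher odds of being in the
high-phenotype group; the interval excluding 1 marks a significant
association. On other seeds the sampling noise can favour a different
barcode — see the methods note on identifiability at this sample size.
`snpbarcode exhaustive --input synth.csv --k 2 --out ranking.tsv` writes the
full 90-barcode ranking for comparison.

In Python the same workflow is three calls:

```python
from snpbarcode import SyntheticSpec, SwarmConfig, generate, run_pso, evaluate_barcode
ds = generate(SyntheticSpec(seed=1))
res = run_pso(ds, SwarmConfig(k=2, seed=1))
print(evaluate_barcode(ds, res.barcode))
```

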