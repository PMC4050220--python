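# Methods

## Model and procedure

Subjects scored on a continuous phenotype are split at the arithmetic mean
of all scores: strictly above the mean is HIGH, at or below is LOW. Ties at
exactly the mean therefore go LOW, and when every score is equal the whole
sample is LOW. Genotypes are categorical codes 1/2/3 per SNP (codes 1 and 2
the two homozygotes as listed in the optional genotype dictionary, 3 the
heterozygote); no dosage or dominance model is imposed — a barcode matches
only on exact genotype equality at every selected SNP, which is the only
carrier definition consistent with genotype-specific barcodes.

The objective of a barcode B is the signed carrier-count difference
F(B) = n_HIGH(B) − n_LOW(B). Signed maximization is the default because
every best barcode of interest favours the HIGH group; an `absolute` mode is
available when direction is irrelevant. A subject with a missing genotype at
any barcode SNP counts as a non-carrier (conservative; missingness carries
no information here).

Search is either exhaustive (all C(m,k)·3^k candidates, capped at 10^6) or
by particle swarm. The swarm encodes a candidate as 2k continuous
coordinates — k SNP slots in [1, m], k genotype slots in [1, 3] — updated by
the classic velocity/position rules with a linearly decreasing inertia
weight. One independent swarm is run per barcode size k; k is never varied
within a run.

Statistical evaluation of a barcode forms the 2×2 table (carriers vs.
others) × (HIGH vs. LOW) and reports:

- odds ratio (a·d)/(b·c), undefined when b·c = 0 unless the opt-in
  Haldane–Anscombe +0.5 correction is enabled;
- Woolf confidence interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) — the log-OR
  normal approximation, chosen over exact conditional intervals because it
  is the convention this analysis style reports;
- Pearson chi-square without Yates continuity correction (a `yates` flag
  exists but is off by default — the uncorrected statistic is what matches
  the reported P values for tables of this size);
- post-hoc power from the noncentral chi-square distribution with 1 df and
  noncentrality λ equal to the observed statistic (equivalently effect size
  w = √(χ²/N) at the observed N): power = P(χ²₁(λ) > χ²₁,₀.₉₅). This is the
  standard analytic convention; other power tools implement variants whose
  settings are rarely stated, so published power figures computed elsewhere
  are not expected to reproduce under it. λ = 0 returns exactly α.
- a Bonferroni-adjusted P across the barcodes actually tested is included in
  reports as a clearly separated extension; the headline P values are raw.

## Swarm parameters

| parameter | default | notes |
|---|---|---|
| population size | 50 | standard for small discrete panels |
| iterations | 100 | termination is iteration count only |
| w_max → w_min | 0.9 → 0.4 | linear schedule, w(0)=0.9, w(T)=0.4 |
| c1, c2 | 2.0 | equal pull toward pbest and gbest |
| v_max | dimension range | m−1 for SNP slots, 2 for genotype slots |
| objective | signed | `absolute` optional |
| stochastic scope | per dimension | `per_particle` optional (see below) |

Numerical choices, in decoding order:

- **Rounding**: continuous slots are rounded half away from zero, then
  clamped to [1, m] / [1, 3]; so 2.5 → 3 deterministically.
- **Repair**: if two SNP slots decode to the same index, the later slot is
  redrawn uniformly among the unused indices and the continuous coordinate
  is overwritten with the repaired integer, so every decoded barcode has
  distinct SNPs at all times.
- **Bookkeeping**: pbest and gbest advance only on *strict* improvement
  (ties keep the incumbent), and gbest is reset once per iteration after the
  whole population has moved. Both choices make runs reproducible from the
  single seeded RNG stream; the seed is echoed into report metadata.
- **r1/r2 scope**: the stochastic factors are drawn per dimension (the
  canonical swarm formulation). A per-particle scalar mode is provided for
  comparison, but on this small discrete landscape it collapses the swarm's
  diversity noticeably faster and measurably lowers the chance of reaching
  the exhaustive optimum, so per-dimension is the default.
- **Ranking tie-break** (reports and exhaustive search): fitness descending,
  then (snp_indices, genotype_codes) lexicographic — stable and total.

## Synthetic data

`SyntheticSpec` defaults encode the study conditions the package targets:
89 HIGH / 93 LOW subjects, five SNPs, a planted two-SNP barcode at SNPs
(1, 4) with genotypes 3-3, carried with probability 30/89 ≈ 0.337 in the
HIGH group and 18/93 ≈ 0.194 in the LOW group. Background genotypes are
drawn independently per SNP; at m = 5 the default frequencies are the
pooled marginals of the 182-subject reference panel shipped with the
fixture, otherwise uniform thirds. Non-carriers are rejection-sampled
against the *full* planted combination, so the carrier probabilities are
exact rather than lower bounds. Phenotypes come from N(100, 2.5) for
intended-HIGH and N(81.5, 2.5) for intended-LOW subjects: each group sits
about 3.8σ from the pooled mean, so the mean split reproduces the intended
labels in roughly 98% of datasets (per-subject flip probability ≈ 8×10⁻⁵).

What the generator does **not** emulate: linkage disequilibrium between
SNPs, Hardy–Weinberg-constrained sampling, genotype–phenotype effect sizes
(group membership is the only phenotype signal), and missing calls. Passing
tests on this generator therefore show the *search and statistics* behave
correctly, not that the method is well powered on real, correlated panels.

**Identifiability at this scale.** The planted difference is distributed as
Bin(89, 0.337) − Bin(93, 0.194): mean 12 but standard deviation ≈ 5.9.
Moreover any two-SNP barcode that keeps one planted SNP and pairs it with a
common genotype elsewhere inherits a fraction of the carrier signal (mean up
to 12 × the largest background code frequency) plus background noise. At
n = 182 the exact planted barcode consequently tops the exhaustive ranking
in only roughly half to two-thirds of replicates, whichever background
family is used; this is a property of the study scale, not of the search
(the swarm finds whatever the exhaustive optimum is in ≳95% of runs, and
whenever the planted barcode is the strict optimum the swarm returns it).
The acceptance script measures and reports both rates.

The `reference_panel_fixture` dataset reproduces the reference panel's 30
per-SNP, per-group genotype counts exactly; its joint genotype structure is
filled in by a seeded within-group shuffle, so multi-SNP carrier counts on
the fixture are synthetic and no published joint counts are claimed. (In
the panel as printed the group whose columns sum to 93 subjects is the HIGH
group; the fixture follows the printed cells.)

## Problem sizes

The simulation studies run at the defaults above (m = 5, n = 182, 90
candidate barcodes at k = 2) with 100 replicates for the agreement and
recovery rates and 200 replicates for the null-calibration check in the
test suite — sizes at which the exhaustive oracle is exact and instant.

## Known limitations

- Input is a coded delimited table, not VCF/PLINK; no allele-level QC,
  phasing or Hardy–Weinberg filtering is performed.
- The reported post-hoc power follows the analytic noncentral chi-square
  convention described above and is not comparable across tools without
  knowing their test-family settings.
- No multiple-testing control beyond the clearly-marked Bonferroni column;
  raw P values are the headline statistics by design.
- Permutation-based empirical P values and alternative metaheuristics are
  out of scope.
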