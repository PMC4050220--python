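"""Synthetic genotype/phenotype data with a planted SNP-SNP interaction.

The generator emulates the case-control structure the search assumes: two
phenotype groups of fixed size, a planted multi-SNP genotype barcode carried
with a higher probability in the high group than in the low group, and
independent per-SNP background genotype frequencies everywhere else.
Non-carriers are rejection-sampled at the barcode level — a background draw
that happens to equal the full planted combination is redrawn — so the
planted carrier probabilities are exact, not lower bounds.

Phenotype scores are drawn from two well-separated normals so that a mean
split recovers the intended group labels with high probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .barcode import Barcode
from .genotype_io import HIGH, GenotypeDataset, dichotomize_by_mean

# Pooled per-SNP genotype counts of a 182-subject, 5-SNP reference panel
# (codes 1/2/3); used as the default background frequencies at m = 5.
_PANEL_SNPS = ["rs1130233", "rs1858830", "rs2237717", "rs41735", "rs42336"]
_PANEL_POOLED = np.array(
    [
        [55, 36, 91],
        [79, 86, 17],
        [53, 41, 88],
        [54, 36, 92],
        [37, 52, 93],
    ],
    dtype=float,
)

# Per-group genotype counts (rows: SNP, columns: codes 1/2/3) of the same
# reference panel; the group whose columns sum to 93 is labelled HIGH.
_PANEL_HIGH = np.array(
    [[22, 21, 50], [42, 44, 7], [25, 18, 50], [25, 17, 51], [17, 24, 52]]
)
_PANEL_LOW = np.array(
    [[33, 15, 41], [37, 42, 10], [28, 23, 38], [29, 19, 41], [20, 28, 41]]
)


def default_background(m: int) -> np.ndarray:
    """Background genotype frequency triples: the reference-panel marginals
    at m = 5, uniform thirds otherwise."""
    if m == 5:
        return _PANEL_POOLED / _PANEL_POOLED.sum(axis=1, keepdims=True)
    return np.full((m, 3), 1.0 / 3.0)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the reference study scale: 89 high / 93 low subjects,
    five SNPs, a two-SNP planted barcode at SNPs (1, 4) with genotype 3-3,
    carried at 30/89 in the high group and 18/93 in the low group.
    """

    n_high: int = 89
    n_low: int = 93
    m: int = 5
    planted_barcode: Optional[Barcode] = field(
        default_factory=lambda: Barcode((1, 4), (3, 3))
    )
    carrier_prob_high: float = 30 / 89
    carrier_prob_low: float = 18 / 93
    background_genotype_freqs: Optional[np.ndarray] = None  # (m, 3), rows sum to 1
    mu_high: float = 100.0
    mu_low: float = 81.5
    sigma: float = 2.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("group sizes must be positive")
        for p in (self.carrier_prob_high, self.carrier_prob_low):
            if not 0 <= p <= 1:
                raise ValueError("carrier probabilities must be in [0, 1]")
        if self.background_genotype_freqs is None:
            self.background_genotype_freqs = default_background(self.m)
        bg = np.asarray(self.background_genotype_freqs, dtype=float)
        if bg.shape != (self.m, 3):
            raise ValueError(f"background frequencies must have shape ({self.m}, 3)")
        if not np.allclose(bg.sum(axis=1), 1.0):
            raise ValueError("each background triple must sum to 1")
        self.background_genotype_freqs = bg
        if self.planted_barcode is not None:
            if max(self.planted_barcode.snp_indices) > self.m:
                raise ValueError("planted barcode references SNPs beyond m")


def generate(spec: SyntheticSpec) -> GenotypeDataset:
    """Draw one dataset under ``spec``; deterministic given ``spec.seed``.

    Returns the dataset already dichotomized at the phenotype mean.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_genotype_freqs
    n = spec.n_high + spec.n_low

    geno = np.empty((n, spec.m), dtype=np.int64)
    for j in range(spec.m):
        geno[:, j] = rng.choice([1, 2, 3], size=n, p=bg[j])

    if spec.planted_barcode is not None:
        bc = spec.planted_barcode.canonical()
        cols = np.array(bc.snp_indices) - 1
        codes = np.array(bc.genotype_codes)
        # background probability of drawing the exact planted combination
        p_bg = float(np.prod([bg[c, g - 1] for c, g in zip(cols, codes)]))
        if p_bg > 0.999:
            raise ValueError(
                "background mass concentrates on the planted combination; "
                "rejection sampling for non-carriers is infeasible"
            )
        probs = np.r_[
            np.full(spec.n_high, spec.carrier_prob_high),
            np.full(spec.n_low, spec.carrier_prob_low),
        ]
        carrier = rng.uniform(size=n) < probs
        geno[np.ix_(carrier, cols)] = codes
        # non-carriers: redraw planted columns until != the full combination
        for i in np.flatnonzero(~carrier):
            while np.array_equal(geno[i, cols], codes):
                for c in cols:
                    geno[i, c] = rng.choice([1, 2, 3], p=bg[c])

    phenotype = np.r_[
        rng.normal(spec.mu_high, spec.sigma, size=spec.n_high),
        rng.normal(spec.mu_low, spec.sigma, size=spec.n_low),
    ]
    snp_names = _PANEL_SNPS if spec.m == 5 else [f"snp{j + 1}" for j in range(spec.m)]
    ds = GenotypeDataset(
        subject_ids=[f"S{i + 1:04d}" for i in range(n)],
        phenotype=phenotype,
        genotypes=geno,
        snp_names=list(snp_names),
    )
    return dichotomize_by_mean(ds)


def reference_panel_fixture(seed: int = 0) -> GenotypeDataset:
    """Deterministic 182-subject, 5-SNP dataset reproducing the reference
    panel's per-SNP, per-group genotype counts exactly.

    Only the marginal counts are constrained; the joint genotype structure
    is filled in by independently shuffling each SNP column within each
    group with a seeded RNG, so multi-SNP carrier counts are synthetic.
    """
    rng = np.random.default_rng(seed)
    n_high = int(_PANEL_HIGH[0].sum())   # 93
    n_low = int(_PANEL_LOW[0].sum())     # 89

    def _group_block(counts: np.ndarray, n: int) -> np.ndarray:
        block = np.empty((n, 5), dtype=np.int64)
        for j in range(5):
            col = np.repeat([1, 2, 3], counts[j])
            rng.shuffle(col)
            block[:, j] = col
        return block

    geno = np.vstack([_group_block(_PANEL_HIGH, n_high), _group_block(_PANEL_LOW, n_low)])
    phenotype = np.r_[np.full(n_high, 95.0), np.full(n_low, 85.0)]
    ds = GenotypeDataset(
        subject_ids=[f"S{i + 1:04d}" for i in range(n_high + n_low)],
        phenotype=phenotype,
        genotypes=geno,
        snp_names=list(_PANEL_SNPS),
    )
    ds = dichotomize_by_mean(ds)
    assert (ds.group[:n_high] == HIGH).all() and (ds.group[n_high:] != HIGH).all()
    return ds
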