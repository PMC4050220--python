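"""SNP barcodes and the group-difference objective.

A *SNP barcode* is a combination of k distinct SNPs together with one fixed
genotype per SNP.  A subject *carries* the barcode when its genotype equals
the barcode's genotype at every selected SNP; genotypes are categorical codes
1/2/3 (the two homozygotes and the heterozygote).  The objective of the
search is the signed difference between the number of carriers in the
high-phenotype group and in the low-phenotype group — the barcode carried by
many high-group subjects but few low-group subjects scores highest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genotype_io import GenotypeDataset, HIGH

VALID_CODES = (1, 2, 3)


@dataclass(frozen=True)
class Barcode:
    """An ordered set of distinct 1-based SNP indices with one genotype each.

    Canonical form sorts the SNP indices ascending with the genotype codes
    permuted in lockstep; carrier status does not depend on slot order.
    """

    snp_indices: tuple[int, ...]
    genotype_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.snp_indices) != len(self.genotype_codes):
            raise ValueError("snp_indices and genotype_codes lengths differ")
        if len(self.snp_indices) < 1:
            raise ValueError("barcode needs at least one SNP")
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise ValueError(f"SNPs cannot be repeatedly selected: {self.snp_indices}")
        if any(i < 1 for i in self.snp_indices):
            raise ValueError("SNP indices are 1-based")
        if any(g not in VALID_CODES for g in self.genotype_codes):
            raise ValueError(f"genotype codes must be in {VALID_CODES}")

    @property
    def k(self) -> int:
        return len(self.snp_indices)

    def canonical(self) -> "Barcode":
        order = np.argsort(self.snp_indices, kind="stable")
        return Barcode(
            tuple(self.snp_indices[i] for i in order),
            tuple(self.genotype_codes[i] for i in order),
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "Barcode":
        snps, codes = zip(*pairs)
        return cls(tuple(snps), tuple(codes))

    def __str__(self) -> str:
        # Report form matching the field's convention, e.g. "SNPs(1,4) 3-3".
        idx = ",".join(str(i) for i in self.snp_indices)
        geno = "-".join(str(g) for g in self.genotype_codes)
        return f"SNPs({idx}) {geno}"


def count_matches(ds: GenotypeDataset, bc: Barcode) -> tuple[int, int]:
    """Count barcode carriers in the HIGH and LOW groups.

    A subject with a missing genotype at any barcode SNP never matches
    (conservative non-carrier policy).

    Returns
    -------
    (n_high, n_low) : carrier counts in each phenotype group.
    """
    if ds.group is None:
        raise ValueError("dataset must be dichotomized before counting matches")
    m = ds.genotypes.shape[1]
    for i in bc.snp_indices:
        if not 1 <= i <= m:
            raise IndexError(f"SNP index {i} out of range 1..{m}")
    cols = np.asarray(bc.snp_indices) - 1
    codes = np.asarray(bc.genotype_codes)
    carrier = np.all(ds.genotypes[:, cols] == codes, axis=1)
    high = ds.group == HIGH
    n_high = int(np.count_nonzero(carrier & high))
    n_low = int(np.count_nonzero(carrier & ~high))
    return n_high, n_low


def fitness(n_high: int, n_low: int, objective: str = "signed") -> int:
    """Barcode objective: difference in carrier counts between groups.

    ``signed`` (default) returns n_high - n_low, so the search favours
    barcodes enriched in the high group; ``absolute`` returns the magnitude
    regardless of direction.
    """
    if n_high < 0 or n_low < 0:
        raise ValueError("counts must be non-negative")
    diff = n_high - n_low
    if objective == "signed":
        return diff
    if objective == "absolute":
        return abs(diff)
    raise ValueError(f"unknown objective {objective!r}")
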