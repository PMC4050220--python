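"""Brute-force enumeration of SNP barcodes — the ground-truth baseline.

For m SNPs and barcode size k there are C(m, k) * 3^k candidate barcodes;
small panels are enumerable outright, giving the exact optimum against which
the swarm search is validated and full rankings of every candidate.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb
from typing import Iterator

from .barcode import Barcode, count_matches, fitness
from .genotype_io import GenotypeDataset

DEFAULT_CAP = 10**6


def enumerate_barcodes(m: int, k: int, cap: int = DEFAULT_CAP) -> Iterator[Barcode]:
    """Yield every canonical k-SNP barcode over m SNPs exactly once.

    Refuses when C(m,k) * 3^k exceeds ``cap`` — use the swarm search there.
    """
    if k > m:
        raise ValueError(f"k={k} exceeds m={m}")
    if k < 1:
        raise ValueError("k must be >= 1")
    total = comb(m, k) * 3**k
    if total > cap:
        raise ValueError(
            f"{total} barcodes exceed the enumeration cap ({cap}); "
            "use the PSO search for panels this large"
        )
    for snps in combinations(range(1, m + 1), k):
        for genos in product((1, 2, 3), repeat=k):
            yield Barcode(snps, genos)


def exhaustive_best(
    ds: GenotypeDataset, k: int, objective: str = "signed", cap: int = DEFAULT_CAP
) -> list[tuple[Barcode, int, int, int]]:
    """Evaluate every barcode and rank by fitness descending.

    Ties are broken by (snp_indices, genotype_codes) lexicographically.
    Returns (barcode, n_high, n_low, fitness) tuples; the head is the
    global optimum.
    """
    if ds.group is None:
        raise ValueError("dataset must be dichotomized")
    rows = []
    for bc in enumerate_barcodes(ds.n_snps, k, cap=cap):
        n_high, n_low = count_matches(ds, bc)
        rows.append((bc, n_high, n_low, fitness(n_high, n_low, objective)))
    rows.sort(key=lambda r: (-r[3], r[0].snp_indices, r[0].genotype_codes))
    return rows
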