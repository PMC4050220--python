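"""Association statistics for a SNP barcode.

Carriers of a barcode versus all other subjects form a 2x2 contingency
table against the HIGH/LOW phenotype groups:

              HIGH    LOW
    carrier     a      b
    other       c      d

The barcode's effect is summarized by the odds ratio (a*d)/(b*c) with a
Woolf (log-OR normal approximation) confidence interval, an uncorrected
Pearson chi-square test, and a post-hoc power computed from the noncentral
chi-square distribution with noncentrality equal to the observed statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats as st

from .barcode import Barcode, count_matches
from .genotype_io import GenotypeDataset


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: barcode carriers vs others by phenotype group."""

    a: int  # HIGH carriers
    b: int  # LOW carriers
    c: int  # HIGH others
    d: int  # LOW others

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_haldane(self) -> "_CorrectedTable":
        """Haldane-Anscombe correction: add 0.5 to every cell."""
        return _CorrectedTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class _CorrectedTable:
    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def build_contingency(ds: GenotypeDataset, bc: Barcode) -> ContingencyTable:
    """Carrier counts from the dataset; others fill the margins."""
    n_high_match, n_low_match = count_matches(ds, bc)
    n_high, n_low = ds.group_sizes()
    return ContingencyTable(
        a=n_high_match,
        b=n_low_match,
        c=n_high - n_high_match,
        d=n_low - n_low_match,
    )


def odds_ratio(t: ContingencyTable, haldane: bool = False) -> float:
    """OR = (a*d)/(b*c); with ``haldane`` the 0.5-corrected cells are used."""
    if haldane:
        t = t.with_haldane()
    if t.b * t.c == 0:
        raise ZeroDivisionError(
            "odds ratio undefined for zero b*c; enable the Haldane correction"
        )
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(
    t: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    """Woolf confidence interval for the odds ratio.

    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)) at the two-sided
    ``level``; requires every cell positive unless ``haldane``.
    """
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    if haldane:
        t = t.with_haldane()
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise ZeroDivisionError(
            "Woolf CI undefined with a zero cell; enable the Haldane correction"
        )
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = st.norm.ppf((1 + level) / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def pearson_chi2_p(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on the 2x2 table (1 df).

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); ``yates`` applies the
    continuity correction (off by default).  Returns (chi2, p).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ZeroDivisionError("chi-square undefined: a margin is zero")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - t.n / 2, 0.0)
    chi2 = t.n * num**2 / margins
    p = float(st.chi2.sf(chi2, df=1))
    return float(chi2), p


def posthoc_power(t: ContingencyTable, alpha: float = 0.05) -> float:
    """Post-hoc power of the 1-df chi-square test at ``alpha``.

    Takes the observed chi-square as the noncentrality parameter
    (equivalently, effect size w = sqrt(chi2/N) at the observed N):
    power = P(ncx2(1, chi2) > chi2 critical value).  Reduces to ``alpha``
    when the observed statistic is zero.
    """
    chi2, _ = pearson_chi2_p(t)
    crit = st.chi2.ppf(1 - alpha, df=1)
    return float(st.ncx2.sf(crit, df=1, nc=chi2)) if chi2 > 0 else alpha


@dataclass
class EvaluatedBarcode:
    """A barcode with its carrier counts and full Table-style statistics."""

    barcode: Barcode
    snp_names: list[str]
    genotype_codes: list[int]
    n_high: int
    n_low: int
    difference: int
    chi2: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    power: float
    bonferroni_p: Optional[float] = None  # extension: adjusted across tested barcodes

    @property
    def k(self) -> int:
        return self.barcode.k


def evaluate_barcode(
    ds: GenotypeDataset,
    bc: Barcode,
    alpha: float = 0.05,
    level: float = 0.95,
    haldane: bool = False,
    yates: bool = False,
) -> EvaluatedBarcode:
    """Full statistical evaluation of one barcode against the dataset.

    Degenerate tables (zero cells without ``haldane``) yield NaN for the
    odds ratio / CI rather than raising, so ranking reports never abort.
    """
    t = build_contingency(ds, bc)
    bc = bc.canonical()
    try:
        orr = odds_ratio(t, haldane=haldane)
        lo, hi = woolf_ci(t, level=level, haldane=haldane)
    except ZeroDivisionError:
        orr, lo, hi = float("nan"), float("nan"), float("nan")
    try:
        chi2, p = pearson_chi2_p(t, yates=yates)
        power = posthoc_power(t, alpha=alpha)
    except ZeroDivisionError:
        chi2, p, power = float("nan"), float("nan"), float("nan")
    return EvaluatedBarcode(
        barcode=bc,
        snp_names=[ds.snp_names[i - 1] for i in bc.snp_indices],
        genotype_codes=list(bc.genotype_codes),
        n_high=t.a,
        n_low=t.b,
        difference=t.a - t.b,
        chi2=chi2,
        p_value=p,
        odds_ratio=orr,
        ci_low=lo,
        ci_high=hi,
        power=power,
    )


def bonferroni_adjust(results: list[EvaluatedBarcode]) -> None:
    """Fill ``bonferroni_p`` across the barcodes actually tested (in place)."""
    k = len(results)
    for r in results:
        r.bonferroni_p = min(1.0, r.p_value * k) if not math.isnan(r.p_value) else float("nan")
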