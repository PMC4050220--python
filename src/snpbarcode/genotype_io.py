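"""Read, validate and dichotomize genotype/phenotype tables; write reports.

The input is a plain delimited table — one row per subject with an
identifier, a continuous phenotype score and one categorical genotype code
per SNP (1 and 2 the two homozygotes, 3 the heterozygote, as listed in the
optional genotype dictionary).  Subjects are split into HIGH and LOW
phenotype groups at the arithmetic mean of the score: strictly above the
mean is HIGH, at or below is LOW.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

HIGH = "HIGH"
LOW = "LOW"
MISSING = -1  # internal sentinel for a missing genotype call

_VALID = frozenset({1, 2, 3})


class GenotypeFormatError(ValueError):
    """Malformed table structure (header, column count, types)."""


class GenotypeValidationError(ValueError):
    """Structurally sound table containing invalid values."""


@dataclass
class GenotypeDataset:
    """Subjects x SNPs categorical genotype matrix with phenotype scores.

    genotypes holds codes in {1,2,3} with -1 marking a missing call;
    group is filled by :func:`dichotomize_by_mean`.
    """

    subject_ids: list[str]
    phenotype: np.ndarray          # float, one score per subject
    genotypes: np.ndarray          # int, shape (n_subjects, n_snps)
    snp_names: list[str]
    genotype_dictionary: Optional[dict[str, dict[int, str]]] = None
    group: Optional[np.ndarray] = field(default=None)  # HIGH/LOW per subject

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, m = self.genotypes.shape
        if len(self.subject_ids) != n or len(self.phenotype) != n:
            raise GenotypeValidationError("subject count mismatch across fields")
        if len(self.snp_names) != m:
            raise GenotypeValidationError("snp_names length != genotype columns")
        if len(set(self.snp_names)) != m:
            raise GenotypeValidationError("snp_names must be unique")
        bad = ~np.isin(self.genotypes, list(_VALID) + [MISSING])
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise GenotypeValidationError(
                f"invalid genotype code {self.genotypes[r, c]} at row {r + 1}, "
                f"SNP {self.snp_names[c]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def group_sizes(self) -> tuple[int, int]:
        """(n_high, n_low); requires dichotomization."""
        if self.group is None:
            raise ValueError("dataset not dichotomized")
        n_high = int(np.count_nonzero(self.group == HIGH))
        return n_high, self.n_subjects - n_high


def read_genotype_table(
    path: str | Path,
    dialect: str = "csv",
    missing: Sequence[str] = ("NA", ""),
) -> GenotypeDataset:
    """Read a delimited genotype table: header ``id,phenotype,<snp1>,...``.

    ``dialect`` is ``csv`` or ``tsv``; ``missing`` lists the sentinel strings
    parsed as a missing genotype call.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise GenotypeFormatError(
            "expected header 'id,phenotype,<snp1>,...' with at least one SNP"
        )
    id_col, pheno_col, *snp_cols = df.columns
    if id_col.lower() != "id" or pheno_col.lower() != "phenotype":
        raise GenotypeFormatError(
            f"first two columns must be 'id' and 'phenotype', got "
            f"{id_col!r}, {pheno_col!r}"
        )
    try:
        phenotype = df[pheno_col].astype(float).to_numpy()
    except ValueError as exc:
        raise GenotypeValidationError(f"non-numeric phenotype: {exc}") from exc

    geno = np.empty((len(df), len(snp_cols)), dtype=np.int64)
    for j, col in enumerate(snp_cols):
        for i, raw in enumerate(df[col]):
            s = raw.strip()
            if s in missing:
                geno[i, j] = MISSING
                continue
            try:
                code = int(s)
            except ValueError:
                code = -999
            if code not in _VALID:
                raise GenotypeValidationError(
                    f"invalid genotype code {raw!r} at row {i + 1}, SNP {col}"
                )
            geno[i, j] = code
    return GenotypeDataset(
        subject_ids=df[id_col].tolist(),
        phenotype=phenotype,
        genotypes=geno,
        snp_names=list(snp_cols),
    )


def read_genotype_dictionary(path: str | Path) -> dict[str, dict[int, str]]:
    """Load a YAML/JSON map {snp_name: {code: allele-pair}}, e.g.
    {"rs1130233": {1: "AA", 2: "GG", 3: "AG"}}."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, dict[int, str]] = {}
    for snp, codes in raw.items():
        out[snp] = {int(c): str(allele) for c, allele in codes.items()}
        if not set(out[snp]) <= _VALID:
            raise GenotypeValidationError(f"dictionary codes for {snp} outside 1..3")
    return out


def write_genotype_table(
    ds: GenotypeDataset, path: str | Path, dialect: str = "csv",
    missing_sentinel: str = "NA",
) -> None:
    """Inverse of :func:`read_genotype_table` (round-trip safe)."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    geno = ds.genotypes.astype(object)
    geno[geno == MISSING] = missing_sentinel
    df = pd.DataFrame(geno, columns=ds.snp_names)
    df.insert(0, "phenotype", ds.phenotype)
    df.insert(0, "id", ds.subject_ids)
    df.to_csv(path, sep=sep, index=False)


def dichotomize_by_mean(ds: GenotypeDataset) -> GenotypeDataset:
    """Split subjects at the arithmetic mean of the phenotype.

    HIGH where score > mean, LOW where score <= mean (every subject with all
    scores equal is LOW).  Returns a new dataset with group labels set.
    """
    if ds.n_subjects == 0:
        raise ValueError("cannot dichotomize an empty dataset")
    if np.isnan(ds.phenotype).any():
        raise GenotypeValidationError("phenotype missing for some subjects")
    mean = float(np.mean(ds.phenotype))
    group = np.where(ds.phenotype > mean, HIGH, LOW)
    return replace(ds, group=group)


def write_report(results: Sequence, path: str | Path, config=None, seed=None) -> None:
    """Write evaluated barcodes as TSV, plus a JSON sidecar with run metadata.

    ``results`` are :class:`snpbarcode.stats.EvaluatedBarcode` records.  Rows
    are sorted by carrier-count difference descending, ties broken by
    (snp_names, genotype_codes) lexicographically so output is stable.
    """
    if not results:
        raise ValueError("no results to report")
    rows = sorted(
        results,
        key=lambda r: (-r.difference, tuple(r.snp_names), tuple(r.genotype_codes)),
    )
    df = pd.DataFrame(
        {
            "k": [r.k for r in rows],
            "snp_names": [",".join(r.snp_names) for r in rows],
            "genotype_codes": ["-".join(map(str, r.genotype_codes)) for r in rows],
            "n_high_match": [r.n_high for r in rows],
            "n_low_match": [r.n_low for r in rows],
            "difference": [r.difference for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p_value": [r.p_value for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "power": [r.power for r in rows],
            "bonferroni_p": [r.bonferroni_p for r in rows],
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    meta = {"seed": seed}
    if config is not None:
        meta["config"] = {k: v for k, v in vars(config).items()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
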