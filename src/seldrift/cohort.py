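"""Cohort genotype panels and per-cohort allele statistics.

A :class:`CohortPanel` holds one cohort's diploid dosage matrix
(individuals x SNPs, values 0/1/2 counting ``allele_b``, NaN for missing)
plus per-SNP metadata.  Minor alleles are assigned once from a designated
reference cohort and shared by every downstream statistic, so the same
allele is tracked in all cohorts even where its frequency exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "CohortPanel",
    "MinorAlleleMap",
    "MafTable",
    "LdMatrix",
    "assign_minor_alleles",
    "compute_maf",
    "pairwise_r2",
]


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for a single bi-allelic SNP."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    is_candidate: bool = False

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ, got {self.allele_a!r} twice")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")


@dataclass
class CohortPanel:
    """One cohort's dosage matrix with SNP metadata.

    ``dosages`` has shape (n_individuals, n_snps); entries count copies of
    ``allele_b`` and are 0, 1, 2 or NaN (missing).
    """

    cohort_id: str
    snps: list[SnpRecord]
    dosages: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} columns "
                f"but {len(self.snps)} SNP records"
            )
        if self.dosages.shape[0] < 1:
            raise ValueError("panel must contain at least one individual")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must be 0/1/2/missing; found {bad[:5]}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate snp_id {dup!r} in panel {self.cohort_id!r}")
        if not self.individual_ids:
            self.individual_ids = [
                f"{self.cohort_id}_{i + 1}" for i in range(self.dosages.shape[0])
            ]
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise ValueError("individual_ids length does not match dosage rows")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"{snp_id!r} not in panel {self.cohort_id!r}") from None

    def subset(self, snp_ids: list[str]) -> "CohortPanel":
        """Return a new panel restricted to ``snp_ids``, in the given order."""
        idx = [self.snp_index(s) for s in snp_ids]
        return CohortPanel(
            cohort_id=self.cohort_id,
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            individual_ids=list(self.individual_ids),
        )

    def call_rates(self) -> np.ndarray:
        """Per-SNP fraction of nonmissing genotypes."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortPanel):
            return NotImplemented
        return (
            self.cohort_id == other.cohort_id
            and self.snps == other.snps
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass
class MinorAlleleMap:
    """Minor/major allele per SNP, fixed by a reference cohort.

    ``frame`` is indexed by snp_id with columns ``minor_allele``,
    ``major_allele``, ``tie_broken``.
    """

    reference_cohort: str
    frame: pd.DataFrame

    def minor_allele(self, snp_id: str) -> str:
        return self.frame.at[snp_id, "minor_allele"]

    def major_allele(self, snp_id: str) -> str:
        return self.frame.at[snp_id, "major_allele"]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.frame.index)


@dataclass
class MafTable:
    """Per-SNP minor-allele statistics for one cohort.

    ``frame`` is indexed by snp_id with columns:

    m          minor-allele frequency (NaN if no data)
    s2         unbiased sample variance of minor-allele dosage
    n_geno     nonmissing genotype count
    x_count    minor-allele count
    n_hap      nonmissing haplotype count (2 * n_geno, autosomal diploid)
    call_rate  fraction of nonmissing genotypes
    """

    cohort_id: str
    frame: pd.DataFrame

    def maf(self, snp_id: str) -> float:
        return float(self.frame.at[snp_id, "m"])

    @property
    def snp_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, snp_ids: list[str]) -> "MafTable":
        return MafTable(self.cohort_id, self.frame.loc[list(snp_ids)].copy())


@dataclass
class LdMatrix:
    """Pairwise squared dosage correlations for one cohort.

    ``r2`` is a symmetric snp x snp DataFrame; undefined entries (a
    monomorphic member or < 2 complete observations) are NaN and are
    treated as 0 by LD pruning.
    """

    cohort_id: str
    r2: pd.DataFrame

    def value(self, snp_i: str, snp_j: str) -> float:
        return float(self.r2.at[snp_i, snp_j])


def _allele_b_frequency(panel: CohortPanel) -> tuple[np.ndarray, np.ndarray]:
    """Frequency of allele_b among nonmissing haplotypes, plus n_geno."""
    d = panel.dosages
    n_geno = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * n_geno)
    return freq, n_geno


def assign_minor_alleles(reference_panel: CohortPanel) -> MinorAlleleMap:
    """Assign per-SNP minor alleles from the reference cohort.

    The minor allele is the allele with frequency <= 0.5 among the
    reference cohort's nonmissing haplotypes.  An exact 0.5 tie picks the
    lexically smaller allele symbol and flags ``tie_broken``.  A
    monomorphic reference SNP assigns the absent allele as minor (m = 0).

    Raises
    ------
    ValueError
        If any SNP has zero nonmissing genotypes in the reference cohort.
    """
    freq_b, n_geno = _allele_b_frequency(reference_panel)
    no_data = [s.snp_id for s, n in zip(reference_panel.snps, n_geno) if n == 0]
    if no_data:
        raise ValueError(
            f"minor allele undefined (zero nonmissing genotypes in reference "
            f"cohort {reference_panel.cohort_id!r}) for SNPs: {no_data}"
        )
    rows = []
    for snp, fb in zip(reference_panel.snps, freq_b):
        tie = False
        if fb < 0.5:
            minor, major = snp.allele_b, snp.allele_a
        elif fb > 0.5:
            minor, major = snp.allele_a, snp.allele_b
        else:
            minor, major = sorted((snp.allele_a, snp.allele_b))
            tie = True
        rows.append((snp.snp_id, minor, major, tie))
    frame = pd.DataFrame(
        rows, columns=["snp_id", "minor_allele", "major_allele", "tie_broken"]
    ).set_index("snp_id")
    return MinorAlleleMap(reference_cohort=reference_panel.cohort_id, frame=frame)


def minor_dosages(panel: CohortPanel, minor_map: MinorAlleleMap) -> np.ndarray:
    """Dosage matrix re-oriented to count the mapped minor allele."""
    flip = np.array(
        [minor_map.minor_allele(s.snp_id) != s.allele_b for s in panel.snps]
    )
    d = panel.dosages.copy()
    d[:, flip] = 2.0 - d[:, flip]
    return d


def compute_maf(panel: CohortPanel, minor_map: MinorAlleleMap) -> MafTable:
    """Per-SNP minor-allele frequency, dosage variance and counts.

    Frequencies use the minor allele fixed by ``minor_map``; in a
    non-reference cohort m may exceed 0.5.  SNPs with zero nonmissing
    genotypes get m = NaN.  The dosage variance uses the unbiased (n-1)
    estimator and is NaN when fewer than 2 genotypes are observed.
    """
    missing = [s for s in panel.snp_ids if s not in minor_map.frame.index]
    if missing:
        raise KeyError(f"SNPs absent from minor-allele map: {missing}")
    d = minor_dosages(panel, minor_map)
    n_geno = (~np.isnan(d)).sum(axis=0)
    x_count = np.nansum(d, axis=0)
    n_hap = 2 * n_geno
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(n_hap > 0, x_count / np.maximum(n_hap, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.array(
            [
                np.var(col[~np.isnan(col)], ddof=1) if n >= 2 else np.nan
                for col, n in zip(d.T, n_geno)
            ]
        )
    frame = pd.DataFrame(
        {
            "m": m,
            "s2": s2,
            "n_geno": n_geno.astype(int),
            "x_count": x_count.astype(int),
            "n_hap": n_hap.astype(int),
            "call_rate": n_geno / panel.n_individuals,
        },
        index=pd.Index(panel.snp_ids, name="snp_id"),
    )
    return MafTable(cohort_id=panel.cohort_id, frame=frame)


def pairwise_r2(panel: CohortPanel) -> LdMatrix:
    """Squared Pearson correlation of dosage vectors for every SNP pair.

    Correlations are computed over individuals nonmissing at both SNPs
    (composite, unphased).  Pairs with fewer than 2 complete observations
    or a constant dosage vector are undefined (NaN); callers treat NaN as
    r2 = 0.  The diagonal is 1 for polymorphic SNPs.
    """
    if panel.n_snps < 2:
        raise ValueError("pairwise r2 requires at least 2 SNPs")
    df = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    r2 = df.corr(min_periods=2) ** 2
    return LdMatrix(cohort_id=panel.cohort_id, r2=r2)
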