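"""Cross-cohort MAF-change test with an exhaustive 3-subset empirical null.

For each SNP j the change in minor-allele frequency between two cohorts
is dm[j] = m_a[j] - m_b[j].  The test statistic for a 3-SNP set is the
mean dm (or the mean of a variance-adjusted Welch-type t per SNP), and
its null distribution is the same statistic over every possible 3-SNP
subset of the post-filter panel.  The empirical P is the proportion of
subsets whose statistic is at least as small as the candidate set's
(tie rule <=, so the candidate subset itself is counted and P >= 1/C(n,3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MafTable

__all__ = [
    "DeltaTable",
    "SelectionTestResult",
    "delta_maf",
    "mean_delta",
    "welch_t",
    "empirical_p",
    "count_combinations",
    "count_triple_subsets",
]


@dataclass
class DeltaTable:
    """Per-SNP MAF change with audit components.

    ``frame`` is indexed by snp_id with columns delta_m, m_a, m_b, s2_a,
    s2_b, n_a, n_b and (after :func:`welch_t`) t_stat.
    """

    cohort_a: str
    cohort_b: str
    frame: pd.DataFrame


@dataclass
class SelectionTestResult:
    """Outcome of an exhaustive 3-subset empirical-null test."""

    statistic_cd: float
    n_subsets: int
    n_at_least_as_small: int
    p_empirical: float
    adjusted: bool
    candidate_ids: tuple[str, str, str]
    n_snps: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_cd,
            "n_subsets": self.n_subsets,
            "n_extreme": self.n_at_least_as_small,
            "p": self.p_empirical,
            "adjusted": self.adjusted,
            "candidate_ids": list(self.candidate_ids),
            "n_snps": self.n_snps,
        }


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k) by integer arithmetic."""
    if k < 0 or n < 0:
        raise ValueError(f"n and k must be nonnegative, got n={n}, k={k}")
    if k > n:
        raise ValueError(f"k must not exceed n, got n={n}, k={k}")
    return math.comb(n, k)


def delta_maf(maf_a: MafTable, maf_b: MafTable) -> DeltaTable:
    """Per-SNP MAF change m_a - m_b over the shared SNP set.

    Both tables must cover the same SNPs (minor alleles assigned from the
    shared reference cohort upstream).
    """
    ids_a, ids_b = set(maf_a.snp_ids), set(maf_b.snp_ids)
    if ids_a != ids_b:
        raise KeyError(
            f"SNP sets differ: only in {maf_a.cohort_id}: {sorted(ids_a - ids_b)}; "
            f"only in {maf_b.cohort_id}: {sorted(ids_b - ids_a)}"
        )
    a = maf_a.frame
    b = maf_b.frame.loc[a.index]
    frame = pd.DataFrame(
        {
            "delta_m": a["m"] - b["m"],
            "m_a": a["m"],
            "m_b": b["m"],
            "s2_a": a["s2"],
            "s2_b": b["s2"],
            "n_a": a["n_geno"],
            "n_b": b["n_geno"],
        },
        index=a.index,
    )
    return DeltaTable(cohort_a=maf_a.cohort_id, cohort_b=maf_b.cohort_id, frame=frame)


def mean_delta(delta: DeltaTable, snp_set: list[str]) -> float:
    """Arithmetic mean of delta_m over ``snp_set``."""
    if not snp_set:
        raise ValueError("snp_set must be non-empty")
    missing = [s for s in snp_set if s not in delta.frame.index]
    if missing:
        raise KeyError(f"SNPs absent from delta table: {missing}")
    return float(delta.frame.loc[list(snp_set), "delta_m"].mean())


def welch_t(delta: DeltaTable) -> DeltaTable:
    """Fill the variance-adjusted statistic t[j].

    t[j] = dm[j] / sqrt(s2_a[j]/(4 n_a[j]) + s2_b[j]/(4 n_b[j])), the
    dosage sample variances converted to variances of the frequency
    estimate.  When both variances are 0 the statistic is 0 for dm = 0
    and +/-inf otherwise (degenerate, flagged by the inf itself).  The
    empirical P is invariant to any global rescaling of the variances,
    so the constant 4 never affects significance.
    """
    f = delta.frame
    if (f[["s2_a", "s2_b"]] < 0).any().any():
        bad = f.index[(f["s2_a"] < 0) | (f["s2_b"] < 0)].tolist()
        raise ValueError(f"negative dosage variance at SNPs: {bad}")
    denom = np.sqrt(f["s2_a"] / (4.0 * f["n_a"]) + f["s2_b"] / (4.0 * f["n_b"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = f["delta_m"] / denom
    t = t.where(denom > 0, np.sign(f["delta_m"]) * np.inf)
    t = t.where(~((denom == 0) & (f["delta_m"] == 0)), 0.0)
    out = f.copy()
    out["t_stat"] = t
    return DeltaTable(cohort_a=delta.cohort_a, cohort_b=delta.cohort_b, frame=out)


def count_triple_subsets(
    values: np.ndarray, candidate_idx: tuple[int, int, int], strict: bool = False
) -> tuple[float, int, int]:
    """Enumerate all 3-subsets of ``values`` and rank the candidate triple.

    Streams over every C(n,3) subset (vectorized per anchor index) and
    counts subsets whose value sum is <= (or < when ``strict``) the
    candidate triple's sum.  Sums are accumulated in the same association
    order for subsets and candidate, so the candidate subset ranks
    consistently under either tie rule.

    Returns (candidate_sum, count, n_subsets).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError(f"need at least 3 SNPs, got {n}")
    i0, i1, i2 = sorted(candidate_idx)
    if len({i0, i1, i2}) != 3:
        raise ValueError("candidate indices must be distinct")
    cand_sum = v[i0] + (v[i1] + v[i2])
    count = 0
    n_subsets = 0
    for i in range(n - 2):
        rest = v[i + 1:]
        pair = rest[:, None] + rest[None, :]
        iu = np.triu_indices(rest.size, k=1)
        sums = v[i] + pair[iu]
        n_subsets += sums.size
        if strict:
            count += int(np.count_nonzero(sums < cand_sum))
        else:
            count += int(np.count_nonzero(sums <= cand_sum))
    return float(cand_sum), count, n_subsets


def empirical_p(
    delta: DeltaTable,
    candidate_set: list[str],
    use_adjusted: bool = False,
    strict: bool = False,
) -> SelectionTestResult:
    """Exhaustive 3-subset empirical P for the candidate SNP set.

    Enumerates all C(n, 3) subsets of the delta table's SNPs (candidates
    included in the enumeration universe).  The statistic is the mean
    delta_m, or the mean Welch-type t when ``use_adjusted``.  With the
    default tie rule (<=) P is the proportion of subsets at least as
    small as the candidate set's statistic.
    """
    if len(candidate_set) != 3:
        raise ValueError(f"candidate set must have exactly 3 SNPs, got {len(candidate_set)}")
    col = "t_stat" if use_adjusted else "delta_m"
    if col not in delta.frame.columns:
        raise ValueError("adjusted test requires welch_t() to be applied first")
    values = delta.frame[col].to_numpy()
    if np.isnan(values).any():
        bad = delta.frame.index[np.isnan(values)].tolist()
        raise ValueError(f"undefined statistic at SNPs (exclude upstream): {bad}")
    index = {s: i for i, s in enumerate(delta.frame.index)}
    missing = [s for s in candidate_set if s not in index]
    if missing:
        raise KeyError(f"candidate SNPs absent from delta table: {missing}")
    idx = tuple(index[s] for s in candidate_set)
    cand_sum, count, n_subsets = count_triple_subsets(values, idx, strict=strict)
    expected = count_combinations(len(values), 3)
    assert n_subsets == expected, "streaming enumerator disagrees with C(n,3)"
    return SelectionTestResult(
        statistic_cd=cand_sum / 3.0,
        n_subsets=n_subsets,
        n_at_least_as_small=count,
        p_empirical=count / n_subsets,
        adjusted=use_adjusted,
        candidate_ids=tuple(candidate_set),
        n_snps=len(values),
    )
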