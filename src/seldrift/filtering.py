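"""SNP filtering cascades.

Two cascades are provided, both applying stages in the fixed order
call-rate -> monomorphic -> LD:

* :func:`filter_pairwise` — for a two-cohort comparison: SNPs below the
  call-rate threshold in either cohort are removed, SNPs monomorphic in
  either cohort are removed, then greedy LD pruning drops one SNP of
  every pair with r2 >= threshold in either cohort.
* :func:`filter_threeway` — for the three-cohort model: low-call-rate
  SNPs are masked wholly missing per cohort (not removed), SNPs
  monomorphic across all cohorts are removed, then LD pruning runs
  across all three cohorts.

LD pruning keeps the SNP earlier in panel order and removes the later,
except that protected SNPs (e.g. the candidate set) are never removed
when paired with an unprotected SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortPanel, pairwise_r2

__all__ = ["FilterReport", "filter_pairwise", "filter_threeway", "nonmissing_subset"]

THREEWAY_ROLES = ("G", "C", "M")


@dataclass
class FilterReport:
    """Per-stage removal counts and retained SNPs for one cascade run."""

    comparison_id: str
    n_input: int
    removed_call_rate: int
    removed_monomorphic: int
    removed_ld: int
    retained: list[str]
    stagewise_removed_ids: dict[str, list[str]]
    masked: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = self.n_input - self.removed_call_rate - self.removed_monomorphic - self.removed_ld
        if expect != len(self.retained):
            raise ValueError(
                f"filter report arithmetic broken: {self.n_input} - "
                f"{self.removed_call_rate} - {self.removed_monomorphic} - "
                f"{self.removed_ld} != {len(self.retained)}"
            )

    def to_dict(self) -> dict:
        return {
            "comparison_id": self.comparison_id,
            "n_input": self.n_input,
            "removed_call_rate": self.removed_call_rate,
            "removed_monomorphic": self.removed_monomorphic,
            "removed_ld": self.removed_ld,
            "n_retained": len(self.retained),
            "retained": list(self.retained),
            "stagewise_removed_ids": {k: list(v) for k, v in self.stagewise_removed_ids.items()},
            "masked": {k: list(v) for k, v in self.masked.items()},
        }


def _monomorphic_mask(panel: CohortPanel) -> np.ndarray:
    """True where only one allele is observed among nonmissing genotypes.

    A SNP is monomorphic in a cohort when all nonmissing dosages are 0
    (only allele_a seen) or all are 2 (only allele_b).  SNPs with zero
    nonmissing genotypes are counted as monomorphic (no frequency
    information).
    """
    d = panel.dosages
    n = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        total = np.nansum(d, axis=0)
    return (total == 0) | (total == 2 * n)


def _pooled_monomorphic(panels: list[CohortPanel], snp_ids: list[str]) -> np.ndarray:
    """True where, pooling all cohorts, only one allele is observed."""
    total = np.zeros(len(snp_ids))
    n = np.zeros(len(snp_ids))
    for p in panels:
        sub = p.subset(snp_ids)
        total += np.nansum(sub.dosages, axis=0)
        n += (~np.isnan(sub.dosages)).sum(axis=0)
    return (total == 0) | (total == 2 * n)


def _combined_r2(panels: list[CohortPanel], snp_ids: list[str]) -> np.ndarray:
    """Elementwise max r2 across cohorts; undefined entries count as 0."""
    out = np.zeros((len(snp_ids), len(snp_ids)))
    for p in panels:
        r2 = pairwise_r2(p.subset(snp_ids)).r2.to_numpy()
        out = np.fmax(out, np.nan_to_num(r2, nan=0.0))
    return out


def _ld_prune(
    panels: list[CohortPanel],
    snp_ids: list[str],
    r2_threshold: float,
    protected: set[str],
) -> list[str]:
    """Greedy prune: scan pairs in panel order, drop the later of each
    offending pair (earlier if the later is protected and the earlier is
    not; pairs of two protected SNPs are kept)."""
    if len(snp_ids) < 2:
        return []
    r2 = _combined_r2(panels, snp_ids)
    alive = dict.fromkeys(range(len(snp_ids)), True)
    removed: list[str] = []
    for i in range(len(snp_ids) - 1):
        if not alive[i]:
            continue
        for j in range(i + 1, len(snp_ids)):
            if not alive[j] or r2[i, j] < r2_threshold:
                continue
            i_prot = snp_ids[i] in protected
            j_prot = snp_ids[j] in protected
            if i_prot and j_prot:
                continue
            victim = i if (j_prot and not i_prot) else j
            alive[victim] = False
            removed.append(snp_ids[victim])
            if victim == i:
                break
    return removed


def filter_pairwise(
    panel_a: CohortPanel,
    panel_b: CohortPanel,
    call_threshold: float = 0.9,
    r2_threshold: float = 0.8,
    protected: set[str] | None = None,
    comparison_id: str | None = None,
) -> FilterReport:
    """Run the two-cohort filtering cascade on the shared SNP set.

    Only SNPs present in both panels are considered (n_input counts the
    intersection, in panel_a order).  Stages: call rate < threshold in
    either cohort; monomorphic in either cohort; LD pruning at
    r2 >= threshold in either cohort.
    """
    protected = protected or set()
    b_ids = set(panel_b.snp_ids)
    shared = [s for s in panel_a.snp_ids if s in b_ids]
    if not shared:
        raise ValueError(
            f"panels {panel_a.cohort_id!r} and {panel_b.cohort_id!r} share no SNPs"
        )
    sub_a, sub_b = panel_a.subset(shared), panel_b.subset(shared)

    low_call = np.minimum(sub_a.call_rates(), sub_b.call_rates()) < call_threshold
    removed_call = [s for s, bad in zip(shared, low_call) if bad]
    stage1 = [s for s in shared if s not in set(removed_call)]

    sub_a, sub_b = panel_a.subset(stage1), panel_b.subset(stage1)
    mono = _monomorphic_mask(sub_a) | _monomorphic_mask(sub_b)
    removed_mono = [s for s, bad in zip(stage1, mono) if bad]
    stage2 = [s for s in stage1 if s not in set(removed_mono)]

    removed_ld = _ld_prune([panel_a, panel_b], stage2, r2_threshold, protected)
    retained = [s for s in stage2 if s not in set(removed_ld)]

    return FilterReport(
        comparison_id=comparison_id or f"{panel_a.cohort_id}_vs_{panel_b.cohort_id}",
        n_input=len(shared),
        removed_call_rate=len(removed_call),
        removed_monomorphic=len(removed_mono),
        removed_ld=len(removed_ld),
        retained=retained,
        stagewise_removed_ids={
            "call_rate": removed_call,
            "monomorphic": removed_mono,
            "ld": removed_ld,
        },
    )


def mask_low_call_rate(panel: CohortPanel, snp_ids: list[str]) -> CohortPanel:
    """Return a copy of ``panel`` with the given SNP columns set wholly missing."""
    out = panel.subset(panel.snp_ids)
    for s in snp_ids:
        out.dosages[:, out.snp_index(s)] = np.nan
    return out


def filter_threeway(
    panels: dict[str, CohortPanel],
    call_threshold: float = 0.9,
    r2_threshold: float = 0.8,
    protected: set[str] | None = None,
    comparison_id: str = "threeway",
) -> FilterReport:
    """Run the three-cohort cascade.

    ``panels`` must be keyed by exactly the roles G, C, M.  Low-call-rate
    SNPs are masked (recorded per cohort in ``report.masked``) rather
    than removed; SNPs monomorphic across all three cohorts are removed;
    LD pruning removes a pair member when r2 >= threshold in any cohort.
    """
    if set(panels) != set(THREEWAY_ROLES):
        raise ValueError(
            f"three-way filtering needs roles {set(THREEWAY_ROLES)}, got {set(panels)}"
        )
    protected = protected or set()
    ordered = [panels[r] for r in THREEWAY_ROLES]
    common = set(ordered[0].snp_ids)
    for p in ordered[1:]:
        common &= set(p.snp_ids)
    shared = [s for s in ordered[0].snp_ids if s in common]
    if not shared:
        raise ValueError("panels share no SNPs")

    masked: dict[str, list[str]] = {}
    masked_panels: list[CohortPanel] = []
    for role, panel in zip(THREEWAY_ROLES, ordered):
        sub = panel.subset(shared)
        low = [s for s, cr in zip(shared, sub.call_rates()) if cr < call_threshold]
        masked[role] = low
        masked_panels.append(mask_low_call_rate(sub, low))

    mono = _pooled_monomorphic(masked_panels, shared)
    removed_mono = [s for s, bad in zip(shared, mono) if bad]
    stage2 = [s for s in shared if s not in set(removed_mono)]

    removed_ld = _ld_prune(masked_panels, stage2, r2_threshold, protected)
    retained = [s for s in stage2 if s not in set(removed_ld)]

    return FilterReport(
        comparison_id=comparison_id,
        n_input=len(shared),
        removed_call_rate=0,
        removed_monomorphic=len(removed_mono),
        removed_ld=len(removed_ld),
        retained=retained,
        stagewise_removed_ids={
            "call_rate": [],
            "monomorphic": removed_mono,
            "ld": removed_ld,
        },
        masked=masked,
    )


def nonmissing_subset(report: FilterReport, panels: dict[str, CohortPanel]) -> list[str]:
    """Retained SNPs with call data in every cohort after masking.

    Excludes SNPs masked in any cohort by :func:`filter_threeway` and
    SNPs with zero nonmissing genotypes in any cohort.
    """
    masked_any = {s for ids in report.masked.values() for s in ids}
    out = []
    for snp in report.retained:
        if snp in masked_any:
            continue
        if all(
            np.count_nonzero(~np.isnan(p.dosages[:, p.snp_index(snp)])) > 0
            for p in panels.values()
        ):
            out.append(snp)
    return out
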