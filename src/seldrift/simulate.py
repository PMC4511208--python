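"""Synthetic three-cohort genotype panels.

The generative model mirrors the analysis assumptions: each SNP has an
ancestral frequency p_A drawn uniformly on a configurable interval; each
cohort's frequency p_X is beta-distributed around p_A with variance
d_X p_A (1 - p_A); diploid genotypes are binomial(2, p_X) draws with
uniform missingness.  LD blocks are created by copying a block-seed
SNP's genotypes and resampling a fraction of entries; selection is an
absolute downward shift of p_X at designated (SNP, cohort) pairs.

Every stochastic stage draws from its own named substream of the global
seed, so adding a stage never perturbs earlier draws.

Deterministic fixture builders engineer panels on which the filtering
cascades remove exactly a requested number of SNPs per stage.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortPanel, SnpRecord

__all__ = [
    "SimConfig",
    "simulate_three_cohorts",
    "make_filter_fixture",
    "make_threeway_fixture",
    "make_paper_like_scenario",
    "TABLE2_TARGETS",
]

ROLES = ("G", "C", "M")

# Candidate-SNP minor-allele frequency targets per cohort role for the
# headline scenario: role -> (snp1, snp2, snp3).
TABLE2_TARGETS = {
    "G": (0.09, 0.18, 0.12),
    "M": (0.23, 0.40, 0.15),
    "C": (0.29, 0.46, 0.43),
}


@dataclass
class SimConfig:
    n_snps: int = 214
    n_individuals: tuple[int, int, int] = (241, 159, 95)
    drift: tuple[float, float, float] = (0.05, 0.05, 0.05)
    p_a_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # list of (block_size, within-block target r2); blocks occupy
    # consecutive SNP indices from the start of the panel
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    # list of (snp_index, role, absolute frequency reduction)
    selection: list[tuple[int, str, float]] = field(default_factory=list)
    candidate_indices: tuple[int, ...] = ()
    cohort_ids: tuple[str, str, str] = ("G", "C", "M")
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in self.missing_rate:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate must be in [0,1], got {rate}")
        for _, r2 in self.ld_blocks:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"LD target r2 must be in [0,1], got {r2}")
        for _, role, _ in self.selection:
            if role not in ROLES:
                raise ValueError(f"selection role must be one of {ROLES}, got {role!r}")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: independent, stable under stage addition."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def _snp_records(n_snps: int, candidate_indices=()) -> list[SnpRecord]:
    cand = set(candidate_indices)
    return [
        SnpRecord(
            snp_id=f"snp{i + 1:04d}",
            chrom="1",
            pos=(i + 1) * 10_000,
            allele_a="A",
            allele_b="G",
            is_candidate=i in cand,
        )
        for i in range(n_snps)
    ]


def _draw_cohort_freqs(p_a: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return p_a.copy()
    scale = (1.0 - d) / d
    return rng.beta(p_a * scale, (1.0 - p_a) * scale)


def simulate_three_cohorts(config: SimConfig) -> dict[str, CohortPanel]:
    """Simulate the three cohorts; returns panels keyed by role G/C/M."""
    seed = config.seed
    p_a = _stage_rng(seed, "p_a").uniform(*config.p_a_range, size=config.n_snps)

    freqs: dict[str, np.ndarray] = {}
    for role, d in zip(ROLES, config.drift):
        freqs[role] = _draw_cohort_freqs(p_a, d, _stage_rng(seed, f"p_x_{role}"))

    for snp_idx, role, reduction in config.selection:
        shifted = freqs[role][snp_idx] - reduction
        if shifted < 0.0 or shifted > 1.0:
            warnings.warn(
                f"selection shift clipped at SNP index {snp_idx} cohort {role}",
                RuntimeWarning,
            )
        freqs[role][snp_idx] = np.clip(shifted, 0.0, 1.0)

    snps = _snp_records(config.n_snps, config.candidate_indices)
    panels: dict[str, CohortPanel] = {}
    for role, cohort_id, n_ind, miss in zip(
        ROLES, config.cohort_ids, config.n_individuals, config.missing_rate
    ):
        rng = _stage_rng(seed, f"genotypes_{role}")
        dosages = rng.binomial(2, freqs[role], size=(n_ind, config.n_snps)).astype(float)

        offset = 0
        ld_rng = _stage_rng(seed, f"ld_{role}")
        for size, r2_target in config.ld_blocks:
            seed_col = dosages[:, offset]
            resample_frac = 1.0 - np.sqrt(r2_target)
            for k in range(1, size):
                col = seed_col.copy()
                swap = ld_rng.random(n_ind) < resample_frac
                col[swap] = ld_rng.binomial(2, freqs[role][offset + k], size=int(swap.sum()))
                dosages[:, offset + k] = col
            offset += size

        if miss > 0:
            mask = _stage_rng(seed, f"missing_{role}").random(dosages.shape) < miss
            dosages[mask] = np.nan
        panels[role] = CohortPanel(cohort_id=cohort_id, snps=list(snps), dosages=dosages)
    return panels


def _repair_polymorphic(dosages: np.ndarray) -> None:
    """Force every column to show both alleles (flip two genotypes if needed)."""
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        if (obs == 0).all():
            col[np.flatnonzero(~np.isnan(col))[0]] = 1.0
        elif (obs == 2).all():
            col[np.flatnonzero(~np.isnan(col))[0]] = 1.0


def _engineer_ld_pairs(
    panels: list[CohortPanel],
    seeds_idx: list[int],
    victims_idx: list[int],
    rng: np.random.Generator,
    flip_frac: float = 0.02,
) -> None:
    """Overwrite victim columns with near-copies of their seed columns.

    Guarantees r2 >= 0.8 in every cohort by falling back to an exact copy
    if the perturbed copy correlates too weakly (checked explicitly).
    """
    for si, vi in zip(seeds_idx, victims_idx):
        for panel in panels:
            src = panel.dosages[:, si]
            col = src.copy()
            swap = np.flatnonzero(rng.random(col.size) < flip_frac)
            col[swap] = rng.integers(0, 3, size=swap.size)
            ok = ~(np.isnan(src) | np.isnan(col))
            if ok.sum() >= 2 and np.std(src[ok]) > 0 and np.std(col[ok]) > 0:
                r2 = np.corrcoef(src[ok], col[ok])[0, 1] ** 2
            else:
                r2 = 0.0
            if r2 < 0.85:  # margin above the 0.8 pruning threshold
                col = src.copy()
            panel.dosages[:, vi] = col


def _role_layout(n_snps: int, groups: dict[str, int], rng: np.random.Generator) -> dict:
    """Assign disjoint index sets for each engineered role, candidates first."""
    candidates = [n_snps // 8, n_snps // 2, n_snps - max(1, n_snps // 8)]
    pool = [i for i in range(n_snps) if i not in candidates]
    layout: dict[str, list[int]] = {"candidates": candidates}
    cursor = 0
    for name, count in groups.items():
        layout[name] = pool[cursor : cursor + count]
        cursor += count
        if cursor > len(pool):
            raise ValueError("role counts exceed panel size")
    layout["background"] = pool[cursor:]
    return layout


def make_filter_fixture(
    target_counts: tuple[int, int, int],
    n_snps: int = 214,
    n_individuals: tuple[int, int] = (241, 159),
    seed: int = 0,
) -> tuple[CohortPanel, CohortPanel, dict]:
    """Two-cohort fixture removing exactly ``target_counts`` per stage.

    ``target_counts`` = (call-rate failures, monomorphic-in-either,
    LD-removable).  The pairwise cascade at thresholds (0.9, 0.8) then
    retains exactly ``n_snps - sum(target_counts)`` SNPs.  Returns
    (panel_a, panel_b, manifest) with the manifest naming each SNP's
    engineered role.
    """
    n_call, n_mono, n_ld = target_counts
    if n_call + n_mono + 2 * n_ld + 3 > n_snps:
        raise ValueError("target counts exceed panel capacity")
    config = SimConfig(
        n_snps=n_snps,
        n_individuals=(*n_individuals, 10),
        drift=(0.02, 0.02, 0.0),
        p_a_range=(0.15, 0.85),
        seed=seed,
    )
    panels = simulate_three_cohorts(config)
    panel_a, panel_b = panels["G"], panels["C"]
    for p in (panel_a, panel_b):
        _repair_polymorphic(p.dosages)

    rng = _stage_rng(seed, "fixture")
    layout = _role_layout(
        n_snps, {"call_rate": n_call, "monomorphic": n_mono,
                 "ld_seeds": n_ld, "ld_victims": n_ld}, rng
    )
    # make victims later in panel order than their seeds
    pairs = [tuple(sorted(p)) for p in zip(layout["ld_seeds"], layout["ld_victims"])]
    layout["ld_seeds"] = [p[0] for p in pairs]
    layout["ld_victims"] = [p[1] for p in pairs]

    for idx in layout["call_rate"]:
        n_miss = int(np.ceil(0.15 * panel_a.n_individuals))
        rows = rng.choice(panel_a.n_individuals, size=n_miss, replace=False)
        panel_a.dosages[rows, idx] = np.nan
    for idx in layout["monomorphic"]:
        panel_a.dosages[:, idx] = 0.0
    _engineer_ld_pairs([panel_a, panel_b], layout["ld_seeds"], layout["ld_victims"], rng)

    cand_ids = [panel_a.snps[i].snp_id for i in layout["candidates"]]
    manifest = {
        name: [panel_a.snps[i].snp_id for i in idxs] for name, idxs in layout.items()
    }
    manifest["candidates"] = cand_ids
    mark_candidates(panel_a, cand_ids)
    mark_candidates(panel_b, cand_ids)
    return panel_a, panel_b, manifest


def mark_candidates(panel: CohortPanel, candidate_ids: list[str]) -> None:
    """Set the is_candidate flag in place for the given SNP ids."""
    cand = set(candidate_ids)
    panel.snps = [
        SnpRecord(s.snp_id, s.chrom, s.pos, s.allele_a, s.allele_b, s.snp_id in cand)
        for s in panel.snps
    ]


def make_threeway_fixture(
    n_snps: int = 214,
    n_mono_all: int = 2,
    n_ld: int = 38,
    n_masked: int = 0,
    n_individuals: tuple[int, int, int] = (241, 159, 95),
    seed: int = 0,
) -> tuple[dict[str, CohortPanel], dict]:
    """Three-cohort fixture for the three-way cascade.

    Engineers ``n_mono_all`` SNPs monomorphic in every cohort,
    ``n_ld`` LD-removable pairs (removed member later in panel order)
    and ``n_masked`` surviving background SNPs pushed below the 90%
    call-rate threshold in exactly one cohort (masked, not removed).
    The cascade retains ``n_snps - n_mono_all - n_ld`` SNPs of which
    ``n_masked`` fewer are nonmissing in all three cohorts.
    """
    if n_mono_all + 2 * n_ld + n_masked + 3 > n_snps:
        raise ValueError("target counts exceed panel capacity")
    config = SimConfig(
        n_snps=n_snps,
        n_individuals=n_individuals,
        drift=(0.02, 0.02, 0.02),
        p_a_range=(0.15, 0.85),
        seed=seed,
    )
    panels = simulate_three_cohorts(config)
    ordered = [panels[r] for r in ROLES]
    for p in ordered:
        _repair_polymorphic(p.dosages)

    rng = _stage_rng(seed, "fixture3")
    layout = _role_layout(
        n_snps, {"monomorphic_all": n_mono_all, "ld_seeds": n_ld,
                 "ld_victims": n_ld, "masked": n_masked}, rng
    )
    pairs = [tuple(sorted(p)) for p in zip(layout["ld_seeds"], layout["ld_victims"])]
    layout["ld_seeds"] = [p[0] for p in pairs]
    layout["ld_victims"] = [p[1] for p in pairs]

    for idx in layout["monomorphic_all"]:
        for p in ordered:
            p.dosages[:, idx] = 0.0
    _engineer_ld_pairs(ordered, layout["ld_seeds"], layout["ld_victims"], rng)
    for k, idx in enumerate(layout["masked"]):
        panel = ordered[k % 3]
        n_miss = int(np.ceil(0.15 * panel.n_individuals))
        rows = rng.choice(panel.n_individuals, size=n_miss, replace=False)
        panel.dosages[rows, idx] = np.nan

    cand_ids = [ordered[0].snps[i].snp_id for i in layout["candidates"]]
    manifest = {
        name: [ordered[0].snps[i].snp_id for i in idxs] for name, idxs in layout.items()
    }
    manifest["candidates"] = cand_ids
    for p in ordered:
        mark_candidates(p, cand_ids)
    return panels, manifest


def make_paper_like_scenario(
    seed: int = 0,
    n_snps: int = 214,
    n_individuals: tuple[int, int, int] = (241, 159, 95),
    background_drift: float = 0.05,
) -> tuple[dict[str, CohortPanel], list[str]]:
    """Three cohorts whose 3 candidate SNPs hit the headline MAF targets.

    Background SNPs follow a common-drift null; the candidate SNPs'
    cohort frequencies are pinned to :data:`TABLE2_TARGETS` (frequencies
    of the EUR-role minor allele) before genotype sampling, so realized
    MAFs match the targets up to binomial noise.
    """
    cand_idx = (n_snps // 8, n_snps // 2, n_snps - max(1, n_snps // 8))
    config = SimConfig(
        n_snps=n_snps,
        n_individuals=n_individuals,
        drift=(background_drift,) * 3,
        p_a_range=(0.05, 0.95),
        candidate_indices=cand_idx,
        missing_rate=(0.01, 0.01, 0.01),
        seed=seed,
    )
    p_a = _stage_rng(seed, "p_a").uniform(*config.p_a_range, size=n_snps)
    freqs = {
        role: _draw_cohort_freqs(p_a, d, _stage_rng(seed, f"p_x_{role}"))
        for role, d in zip(ROLES, config.drift)
    }
    for role in ROLES:
        for k, idx in enumerate(cand_idx):
            freqs[role][idx] = TABLE2_TARGETS[role][k]

    snps = _snp_records(n_snps, cand_idx)
    panels: dict[str, CohortPanel] = {}
    for role, cohort_id, n_ind, miss in zip(
        ROLES, config.cohort_ids, config.n_individuals, config.missing_rate
    ):
        rng = _stage_rng(seed, f"genotypes_{role}")
        dosages = rng.binomial(2, freqs[role], size=(n_ind, n_snps)).astype(float)
        mask = _stage_rng(seed, f"missing_{role}").random(dosages.shape) < miss
        dosages[mask] = np.nan
        panels[role] = CohortPanel(cohort_id=cohort_id, snps=list(snps), dosages=dosages)
    candidate_ids = [snps[i].snp_id for i in cand_idx]
    return panels, candidate_ids
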