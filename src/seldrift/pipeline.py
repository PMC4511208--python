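"""End-to-end orchestration: ingest/simulate -> filter -> both tests.

:func:`run_all` executes the full comparison set — three pairwise
Method-1 runs (G vs C, G vs M, M vs C) and two Method-2 runs (target G,
target M) — and writes per-comparison statistics plus a summary table
with one row per comparison.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortPanel, MafTable, assign_minor_alleles, compute_maf
from .filtering import FilterReport, filter_pairwise, filter_threeway, nonmissing_subset
from .io import read_genotype_table, read_vcf, write_genotype_table
from .method1 import SelectionTestResult, delta_maf, empirical_p, welch_t
from .method2 import (
    GridSpec,
    Quadrature,
    SnpCounts,
    fit_drift_mle,
    method2_empirical_p,
    swap_target_cohort,
)
from .simulate import make_paper_like_scenario

__all__ = ["RunManifest", "run_all", "render_maf_table", "load_config"]

ROLES = ("G", "C", "M")

# comparison -> (cohort pair, null-hypothesis label template)
_M1_COMPARISONS = [
    ("G_vs_C", ("G", "C")),
    ("G_vs_M", ("G", "M")),
    ("M_vs_C", ("M", "C")),
]
_M2_TARGETS = ["G", "M"]


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    input_digests: dict[str, str]
    filter_reports: dict[str, dict]
    results: dict[str, dict]
    summary: list[dict]
    version: str = __version__
    seed: int | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_panel(path: str, cohort_id: str) -> CohortPanel:
    if str(path).endswith(".vcf"):
        return read_vcf(path, cohort_id)
    return read_genotype_table(path, cohort_id)


def _resolve_inputs(config: dict, out_dir: Path) -> tuple[dict[str, CohortPanel], list[str], dict[str, str]]:
    digests: dict[str, str] = {}
    if "panels" in config:
        panels = {
            role: _load_panel(config["panels"][role], config["panels"].get(f"{role}_id", role))
            for role in ROLES
        }
        digests = {role: _sha256(config["panels"][role]) for role in ROLES}
        candidates = list(config["candidates"])
    elif config.get("scenario") == "paper_like":
        panels, candidates = make_paper_like_scenario(seed=int(config.get("seed", 0)))
        for role, panel in panels.items():
            path = out_dir / f"panel_{role}.tsv"
            write_genotype_table(panel, path)
            digests[role] = _sha256(path)
    else:
        raise ValueError("config must provide 'panels' paths or scenario: paper_like")
    for role, panel in panels.items():
        missing = [c for c in candidates if c not in panel.snp_ids]
        if missing:
            raise ValueError(f"candidate SNPs absent from cohort {role}: {missing}")
    return panels, candidates, digests


def _m1_null_label(a: str, b: str) -> str:
    return f"candidate MAFs are not reduced in {a} compared with {b}"


def run_all(config: dict | str | os.PathLike, out_dir: str | os.PathLike = "seldrift_out") -> RunManifest:
    """Execute the five-comparison analysis described in the module docstring.

    ``config`` is a dict or a YAML path with keys: ``panels`` (role ->
    file) or ``scenario: paper_like``; ``candidates`` (3 snp_ids);
    optional ``call_threshold``, ``r2_threshold``, ``grid``,
    ``quadrature_nodes``, ``seed``.  Outputs land in ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    call_thr = float(config.get("call_threshold", 0.9))
    r2_thr = float(config.get("r2_threshold", 0.8))
    seed = config.get("seed")

    panels, candidates, digests = _resolve_inputs(config, out)
    protected = set(candidates)
    minor_map = assign_minor_alleles(panels["C"])

    filter_reports: dict[str, dict] = {}
    results: dict[str, dict] = {}
    summary: list[dict] = []

    for comp_id, (ra, rb) in _M1_COMPARISONS:
        pa, pb = panels[ra], panels[rb]
        report = filter_pairwise(
            pa, pb, call_threshold=call_thr, r2_threshold=r2_thr,
            protected=protected, comparison_id=comp_id,
        )
        filter_reports[comp_id] = report.to_dict()
        maf_a = compute_maf(pa.subset(report.retained), minor_map)
        maf_b = compute_maf(pb.subset(report.retained), minor_map)
        delta = welch_t(delta_maf(maf_a, maf_b))
        delta.frame.to_csv(out / f"m1_{comp_id}_stats.tsv", sep="\t")
        unadj = empirical_p(delta, candidates, use_adjusted=False)
        adj = empirical_p(delta, candidates, use_adjusted=True)
        results[comp_id] = {"unadjusted": unadj.to_dict(), "adjusted": adj.to_dict()}
        summary.append(
            {
                "comparison": comp_id,
                "method": "pairwise",
                "null_hypothesis": _m1_null_label(pa.cohort_id, pb.cohort_id),
                "n_snps": len(report.retained),
                "p_unadjusted": unadj.p_empirical,
                "p_adjusted": adj.p_empirical,
            }
        )

    report3 = filter_threeway(
        panels, call_threshold=call_thr, r2_threshold=r2_thr,
        protected=protected, comparison_id="threeway",
    )
    filter_reports["threeway"] = report3.to_dict()
    maf_by_role = {
        role: compute_maf(panels[role].subset(report3.retained), minor_map)
        for role in ROLES
    }
    # mask low-call-rate cohorts: zero their counts at masked SNPs
    for role in ROLES:
        for snp in report3.masked.get(role, []):
            if snp in maf_by_role[role].frame.index:
                maf_by_role[role].frame.loc[snp, ["x_count", "n_hap", "n_geno"]] = 0
    counts = SnpCounts.from_maf_tables(*(maf_by_role[r] for r in ROLES))
    grid = GridSpec(**config.get("grid", {}))
    quad = Quadrature(n_nodes=int(config.get("quadrature_nodes", 256)))
    drift = fit_drift_mle(counts, grid_spec=grid, quadrature=Quadrature(n_nodes=128))
    eligible = nonmissing_subset(report3, panels)
    counts_eligible = counts.subset(eligible)

    for target in _M2_TARGETS:
        tails = swap_target_cohort(counts_eligible, drift, target=target, quadrature=quad)
        tails.frame.to_csv(out / f"m2_target_{target}_q.tsv", sep="\t")
        res = method2_empirical_p(tails, candidates)
        others = "+".join(panels[r].cohort_id for r in ROLES if r != target)
        results[f"m2_target_{target}"] = {
            "drift": drift.to_dict(),
            "result": res.to_dict(),
            "n_eligible": len(eligible),
        }
        summary.append(
            {
                "comparison": f"{panels[target].cohort_id}_vs_({others})",
                "method": "drift_model",
                "null_hypothesis": _m1_null_label(panels[target].cohort_id, others),
                "n_snps": len(eligible),
                "p_permutation": res.p_empirical,
            }
        )

    summary_df = pd.DataFrame(summary)
    summary_df.to_csv(out / "summary.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config=dict(config),
        input_digests=digests,
        filter_reports=filter_reports,
        results=results,
        summary=summary,
        seed=seed,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def render_maf_table(
    maf_tables: dict[str, MafTable], minor_map, candidate_ids: list[str]
) -> pd.DataFrame:
    """Candidate-SNP MAF display table, one row per candidate.

    Columns: snp_id, ``minor (major)`` allele string and the per-cohort
    MAFs rounded to 2 decimals (Python round-half-even formatting; full
    precision lives in the MafTable exports).
    """
    rows = []
    for snp in candidate_ids:
        row = {
            "snp_id": snp,
            "alleles": f"{minor_map.minor_allele(snp)}({minor_map.major_allele(snp)})",
        }
        for role, table in maf_tables.items():
            row[f"maf_{table.cohort_id}"] = f"{table.maf(snp):.2f}"
        rows.append(row)
    columns = ["snp_id", "alleles"] + [
        f"maf_{t.cohort_id}" for t in maf_tables.values()
    ]
    return pd.DataFrame(rows, columns=columns)
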