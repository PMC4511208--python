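"""Beta-binomial population-drift model and conditional tail test.

Each cohort's minor-allele count X is binomial(n, p_X) with the cohort
frequency p_X beta-distributed around a shared ancestral frequency p_A:
mean p_A and variance d * p_A * (1 - p_A), where d is the cohort's drift
(the Balding-Nichols parameterization, alpha = p_A(1-d)/d,
beta = (1-p_A)(1-d)/d).  Integrating p_X analytically gives a
beta-binomial; p_A carries a uniform prior and is integrated numerically
by Gauss-Legendre quadrature on (0, 1).

Drift is estimated by maximizing the summed per-SNP log marginal
likelihood over a 3-D geometric grid, then the per-SNP conditional tail
probability q = Pr(X_target <= x_target | other cohorts' counts, drift)
feeds an exhaustive 3-subset empirical null (strict < tie rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp

from .cohort import MafTable
from .method1 import SelectionTestResult, count_combinations, count_triple_subsets

__all__ = [
    "GridSpec",
    "Quadrature",
    "SnpCounts",
    "DriftEstimate",
    "TailProbTable",
    "betabinom_logpmf",
    "snp_joint_likelihood",
    "fit_drift_mle",
    "gam_tail_prob",
    "swap_target_cohort",
    "method2_empirical_p",
]

ROLES = ("G", "C", "M")


@dataclass(frozen=True)
class GridSpec:
    """Geometric drift grid: ``n_points`` per axis spanning [low, high].

    ``refine`` adds local Cartesian refinement passes around the argmax,
    each spanning one coarse step either side with ``refine_points``
    geometric points per axis.
    """

    n_points: int = 40
    low: float = 1e-4
    high: float = 0.5
    refine: int = 1
    refine_points: int = 9

    def axis(self) -> np.ndarray:
        return np.geomspace(self.low, self.high, self.n_points)


@dataclass(frozen=True)
class Quadrature:
    """Fixed Gauss-Legendre rule on (0, 1), optionally doubled until the
    integral changes by less than ``tol`` (relative)."""

    n_nodes: int = 256
    adaptive: bool = False
    tol: float = 1e-8
    max_nodes: int = 4096

    def __post_init__(self) -> None:
        if self.n_nodes < 64:
            raise ValueError(f"quadrature needs >= 64 nodes, got {self.n_nodes}")

    def rule(self, n_nodes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        return _gauss_legendre_01(n_nodes or self.n_nodes)


@lru_cache(maxsize=16)
def _gauss_legendre_01(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * (x + 1.0), 0.5 * w


@dataclass
class SnpCounts:
    """Minor-allele and haplotype counts per SNP for the three cohorts.

    ``frame`` is indexed by snp_id with integer columns x_g, n_g, x_c,
    n_c, x_m, n_m; n = 0 marks a cohort with no data at that SNP.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for role in ROLES:
            x, n = f[f"x_{role.lower()}"], f[f"n_{role.lower()}"]
            if ((x < 0) | (x > n)).any():
                bad = f.index[(x < 0) | (x > n)].tolist()
                raise ValueError(f"counts out of range for cohort {role}: {bad}")

    @classmethod
    def from_maf_tables(
        cls, maf_g: MafTable, maf_c: MafTable, maf_m: MafTable
    ) -> "SnpCounts":
        frames = {}
        for role, table in zip(ROLES, (maf_g, maf_c, maf_m)):
            r = role.lower()
            frames[f"x_{r}"] = table.frame["x_count"]
            frames[f"n_{r}"] = table.frame["n_hap"]
        return cls(pd.DataFrame(frames).astype(int))

    @property
    def snp_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, snp_ids: list[str]) -> "SnpCounts":
        return SnpCounts(self.frame.loc[list(snp_ids)].copy())


@dataclass
class DriftEstimate:
    """Grid MLE of the per-cohort drift triple."""

    d_g: float
    d_c: float
    d_m: float
    grid_spec: GridSpec
    loglik_max: float
    on_boundary: bool = False
    loglik_surface: np.ndarray | None = None

    def by_role(self, role: str) -> float:
        return {"G": self.d_g, "C": self.d_c, "M": self.d_m}[role]

    def to_dict(self) -> dict:
        return {
            "d_g": self.d_g,
            "d_c": self.d_c,
            "d_m": self.d_m,
            "loglik_max": self.loglik_max,
            "on_boundary": self.on_boundary,
            "grid": {
                "n_points": self.grid_spec.n_points,
                "low": self.grid_spec.low,
                "high": self.grid_spec.high,
                "refine": self.grid_spec.refine,
            },
        }


@dataclass
class TailProbTable:
    """Per-SNP conditional tail probabilities q for one target cohort."""

    target: str
    frame: pd.DataFrame
    drift: DriftEstimate | None = None

    @property
    def snp_ids(self) -> list[str]:
        return list(self.frame.index)


def betabinom_logpmf(x, n, p_a, d):
    """Log pmf of the drift beta-binomial; broadcasts over array inputs.

    Parameters follow the Balding-Nichols form: alpha = p_a(1-d)/d,
    beta = (1-p_a)(1-d)/d, so the latent frequency has mean p_a and
    variance d p_a (1 - p_a).  d = 0 degenerates to binomial(n, p_a).
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any((p_a <= 0) | (p_a >= 1)):
        raise ValueError("p_a must lie strictly inside (0, 1)")
    if np.any((d < 0) | (d >= 1)):
        raise ValueError("d must lie in [0, 1)")
    x, n, p_a, d = np.broadcast_arrays(x, n, p_a, d)
    choose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    out = np.empty_like(choose)
    zero = d == 0
    if np.any(zero):
        out[zero] = (
            choose[zero]
            + x[zero] * np.log(p_a[zero])
            + (n[zero] - x[zero]) * np.log1p(-p_a[zero])
        )
    pos = ~zero
    if np.any(pos):
        scale = (1.0 - d[pos]) / d[pos]
        a = p_a[pos] * scale
        b = (1.0 - p_a[pos]) * scale
        out[pos] = (
            choose[pos]
            + betaln(x[pos] + a, n[pos] - x[pos] + b)
            - betaln(a, b)
        )
    return out if out.ndim else float(out)


def _betabinom_logcdf(x, n, p_nodes, d):
    """log Pr(X <= x) at each quadrature node; x, n scalars."""
    x = int(x)
    support = np.arange(x + 1)
    lp = betabinom_logpmf(support[:, None], n, p_nodes[None, :], d)
    return logsumexp(lp, axis=0)


def snp_joint_likelihood(
    x: dict[str, int],
    n: dict[str, int],
    drift: dict[str, float],
    quadrature: Quadrature = Quadrature(),
) -> float:
    """Marginal likelihood of one SNP's counts: the product of cohort
    beta-binomial terms integrated over a uniform ancestral frequency.

    Cohorts with n = 0 (missing) drop their factor from the product.
    With ``quadrature.adaptive`` the node count doubles until the value
    is stable to the requested relative tolerance.
    """
    roles = [r for r in ROLES if r in n and n[r] > 0]
    if not roles:
        raise ValueError("no cohort has data at this SNP")

    def evaluate(n_nodes: int) -> float:
        p, w = quadrature.rule(n_nodes)
        total = np.zeros_like(p)
        for r in roles:
            total += betabinom_logpmf(x[r], n[r], p, drift[r])
        if np.isnan(total).any():
            raise FloatingPointError(
                f"NaN integrand in joint likelihood (x={x}, n={n}, drift={drift})"
            )
        return float(np.exp(logsumexp(total, b=w)))

    nodes = quadrature.n_nodes
    value = evaluate(nodes)
    if quadrature.adaptive:
        while nodes < quadrature.max_nodes:
            nodes *= 2
            refined = evaluate(nodes)
            if abs(refined - value) <= quadrature.tol * max(abs(refined), 1e-300):
                return refined
            value = refined
    return value


def _cohort_tensor(x, n, d_axis, p_nodes):
    """Scaled likelihood tensor A[d, j, q] with per-(d, j) log scales.

    A is exp(logpmf - scale); SNPs with n = 0 contribute a unit factor.
    """
    present = n > 0
    lp = np.full((d_axis.size, x.size, p_nodes.size), 0.0)
    if present.any():
        block = betabinom_logpmf(
            x[present][None, :, None],
            n[present][None, :, None],
            p_nodes[None, None, :],
            d_axis[:, None, None],
        )
        lp[:, present, :] = block
    scale = lp.max(axis=2)
    a = np.exp(lp - scale[:, :, None])
    return a, scale


def _grid_loglik(counts: SnpCounts, axes: dict[str, np.ndarray], p_nodes, w):
    """Total log-likelihood over the Cartesian grid; shape (|G|,|C|,|M|)."""
    f = counts.frame
    tensors = {}
    scales = {}
    for role in ROLES:
        r = role.lower()
        a, s = _cohort_tensor(
            f[f"x_{r}"].to_numpy(float), f[f"n_{r}"].to_numpy(float), axes[role], p_nodes
        )
        tensors[role] = a
        scales[role] = s.sum(axis=1)  # summed over SNPs, shape (|axis|,)
    ag, ac, am = tensors["G"], tensors["C"], tensors["M"]
    n_g = axes["G"].size
    ll = np.empty((n_g, axes["C"].size, axes["M"].size))
    wq = w[None, :]
    with np.errstate(divide="ignore"):
        for gi in range(n_g):
            # T[c, m, j] = sum_q w_q Ag[gi,j,q] Ac[c,j,q] Am[m,j,q]
            t = np.einsum("jq,cjq,mjq->cmj", wq * ag[gi], ac, am, optimize=True)
            ll[gi] = np.log(t).sum(axis=2)
    ll += scales["G"][:, None, None]
    ll += scales["C"][None, :, None]
    ll += scales["M"][None, None, :]
    return ll


def fit_drift_mle(
    counts: SnpCounts,
    grid_spec: GridSpec = GridSpec(),
    quadrature: Quadrature = Quadrature(n_nodes=128),
    keep_surface: bool = False,
) -> DriftEstimate:
    """Maximize the summed log marginal likelihood over the drift grid.

    Evaluates the full Cartesian grid (deterministic), then optionally
    refines locally around the argmax; the refined maximum is never
    below the coarse one.  SNPs missing a cohort drop that cohort's
    factor.  An argmax on the grid boundary raises a warning and sets
    ``on_boundary``.
    """
    f = counts.frame
    has_data = (f[[f"n_{r.lower()}" for r in ROLES]] > 0).any(axis=1)
    if int(has_data.sum()) < 10:
        raise ValueError(f"need >= 10 SNPs with data, got {int(has_data.sum())}")
    for role in ROLES:
        if (f[f"n_{role.lower()}"] == 0).all():
            raise ValueError(f"cohort {role} has no data at any SNP")
    p_nodes, w = quadrature.rule()
    base_axis = grid_spec.axis()
    axes = {r: base_axis.copy() for r in ROLES}
    ll = _grid_loglik(counts, axes, p_nodes, w)
    best = {r: axes[r][i] for r, i in zip(ROLES, np.unravel_index(ll.argmax(), ll.shape))}
    best_ll = float(ll.max())
    surface = ll if keep_surface else None

    idx = np.unravel_index(ll.argmax(), ll.shape)
    on_boundary = any(i in (0, axes[r].size - 1) for r, i in zip(ROLES, idx))

    for _ in range(grid_spec.refine):
        local_axes = {}
        for r, i in zip(ROLES, idx):
            axis = axes[r]
            lo = axis[max(i - 1, 0)]
            hi = axis[min(i + 1, axis.size - 1)]
            local_axes[r] = np.geomspace(lo, hi, grid_spec.refine_points)
        local_ll = _grid_loglik(counts, local_axes, p_nodes, w)
        li = np.unravel_index(local_ll.argmax(), local_ll.shape)
        if float(local_ll.max()) >= best_ll:
            best_ll = float(local_ll.max())
            best = {r: local_axes[r][i] for r, i in zip(ROLES, li)}
        axes, idx = local_axes, li

    if on_boundary:
        warnings.warn(
            "drift MLE on the grid boundary; widen GridSpec bounds", RuntimeWarning
        )
    return DriftEstimate(
        d_g=float(best["G"]),
        d_c=float(best["C"]),
        d_m=float(best["M"]),
        grid_spec=grid_spec,
        loglik_max=best_ll,
        on_boundary=on_boundary,
        loglik_surface=surface,
    )


def _tail_prob_one(x, n, drift_by_role, target, p_nodes, w):
    """q = Pr(X_target <= x_target | conditioning counts, drift)."""
    others = [r for r in ROLES if r != target]
    log_w = np.log(w)
    cond = np.zeros_like(p_nodes)
    for r in others:
        cond += betabinom_logpmf(x[r], n[r], p_nodes, drift_by_role[r])
    log_den = logsumexp(cond + log_w)
    log_cdf = _betabinom_logcdf(x[target], n[target], p_nodes, drift_by_role[target])
    log_num = logsumexp(cond + log_cdf + log_w)
    return float(min(np.exp(log_num - log_den), 1.0))


def swap_target_cohort(
    counts: SnpCounts,
    drift: DriftEstimate,
    target: str = "G",
    quadrature: Quadrature = Quadrature(),
) -> TailProbTable:
    """Conditional tail probabilities with ``target`` in the tail position.

    For each SNP (all three cohorts must have data) computes
    q = Pr(X_target <= x_target | other two cohorts' counts, fitted
    drift), the ratio of two uniform-prior integrals over the ancestral
    frequency.  Computed in log space; q = 1 when x_target = n_target.
    """
    if target not in ROLES:
        raise ValueError(f"target must be one of {ROLES}, got {target!r}")
    f = counts.frame
    incomplete = f.index[(f[[f"n_{r.lower()}" for r in ROLES]] == 0).any(axis=1)]
    if len(incomplete):
        raise ValueError(
            f"tail probability needs data in all 3 cohorts; missing at {list(incomplete)}"
        )
    p_nodes, w = quadrature.rule()
    drift_by_role = {r: drift.by_role(r) for r in ROLES}
    qs = []
    for snp_id, row in f.iterrows():
        x = {r: int(row[f"x_{r.lower()}"]) for r in ROLES}
        n = {r: int(row[f"n_{r.lower()}"]) for r in ROLES}
        qs.append(_tail_prob_one(x, n, drift_by_role, target, p_nodes, w))
    frame = pd.DataFrame({"q": qs}, index=f.index)
    return TailProbTable(target=target, frame=frame, drift=drift)


def gam_tail_prob(
    counts: SnpCounts,
    drift: DriftEstimate,
    quadrature: Quadrature = Quadrature(),
) -> TailProbTable:
    """Tail probabilities with the G-role cohort as target (the default test)."""
    return swap_target_cohort(counts, drift, target="G", quadrature=quadrature)


def method2_empirical_p(
    tails: TailProbTable, candidate_set: list[str]
) -> SelectionTestResult:
    """Empirical P from the exhaustive 3-subset null over tail probabilities.

    The statistic is the mean q over the candidate triple; P is the
    proportion of all C(n, 3) subsets of eligible SNPs whose mean q is
    strictly smaller (so a uniquely minimal candidate triple gives P = 0).
    """
    if len(candidate_set) != 3:
        raise ValueError(f"candidate set must have exactly 3 SNPs, got {len(candidate_set)}")
    index = {s: i for i, s in enumerate(tails.frame.index)}
    missing = [s for s in candidate_set if s not in index]
    if missing:
        raise KeyError(f"candidate SNPs not eligible (missing data?): {missing}")
    values = tails.frame["q"].to_numpy()
    idx = tuple(index[s] for s in candidate_set)
    cand_sum, count, n_subsets = count_triple_subsets(values, idx, strict=True)
    assert n_subsets == count_combinations(len(values), 3)
    return SelectionTestResult(
        statistic_cd=cand_sum / 3.0,
        n_subsets=n_subsets,
        n_at_least_as_small=count,
        p_empirical=count / n_subsets,
        adjusted=False,
        candidate_ids=tuple(candidate_set),
        n_snps=len(values),
    )
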