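import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seldrift.cohort import MafTable, assign_minor_alleles, compute_maf
from seldrift.method2 import (
    DriftEstimate,
    GridSpec,
    Quadrature,
    SnpCounts,
    betabinom_logpmf,
    fit_drift_mle,
    gam_tail_prob,
    method2_empirical_p,
    snp_joint_likelihood,
    swap_target_cohort,
)
from seldrift.simulate import SimConfig, simulate_three_cohorts

from .conftest import maf_frame


def counts_table(rows):
    """rows: dict snp_id -> (x_g, n_g, x_c, n_c, x_m, n_m)"""
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["x_g", "n_g", "x_c", "n_c", "x_m", "n_m"]
    )
    frame.index.name = "snp_id"
    return SnpCounts(frame)


def sim_counts(n_snps, n_hap, drift, seed):
    """Simulate beta-binomial counts directly from the generative model."""
    rng = np.random.default_rng(seed)
    p_a = rng.uniform(0.05, 0.95, size=n_snps)
    rows = {}
    for j in range(n_snps):
        vals = []
        for d, n in zip(drift, n_hap):
            scale = (1 - d) / d
            p = rng.beta(p_a[j] * scale, (1 - p_a[j]) * scale)
            vals += [int(rng.binomial(n, p)), n]
        rows[f"s{j}"] = tuple(vals)
    return counts_table(rows)


class TestBetabinomLogpmf:
    def test_binomial_limit(self):
        assert betabinom_logpmf(1, 2, 0.5, 0.0) == pytest.approx(np.log(0.5))

    def test_normalizes_over_lattice(self):
        for n, p_a, d in itertools.product((5, 30), (0.1, 0.3, 0.7), (0.01, 0.1, 0.4)):
            total = np.exp(betabinom_logpmf(np.arange(n + 1), n, p_a, d)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_parameterization(self):
        p_a, d, n = 0.2, 0.05, 20
        a = p_a * (1 - d) / d
        b = (1 - p_a) * (1 - d) / d
        ours = betabinom_logpmf(np.arange(n + 1), n, p_a, d)
        ref = stats.betabinom.logpmf(np.arange(n + 1), n, a, b)
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_matches_two_stage_monte_carlo(self):
        # reduced-draw version of the sampling oracle (full scale in acceptance)
        x, n, p_a, d = 4, 20, 0.2, 0.05
        rng = np.random.default_rng(42)
        n_draws = 200_000
        scale = (1 - d) / d
        p = rng.beta(p_a * scale, (1 - p_a) * scale, size=n_draws)
        draws = rng.binomial(n, p)
        freq = (draws == x).mean()
        prob = np.exp(betabinom_logpmf(x, n, p_a, d))
        se = np.sqrt(prob * (1 - prob) / n_draws)
        assert abs(freq - prob) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="p_a"):
            betabinom_logpmf(1, 2, 1.0, 0.1)
        with pytest.raises(ValueError, match="d must"):
            betabinom_logpmf(1, 2, 0.5, 1.0)


class TestSnpJointLikelihood:
    def test_closed_form_polynomial(self):
        # all cohorts x=0, n=2, d=0: integral of (1-p)^6 = 1/7
        v = snp_joint_likelihood(
            {"G": 0, "C": 0, "M": 0}, {"G": 2, "C": 2, "M": 2},
            {"G": 0.0, "C": 0.0, "M": 0.0},
        )
        assert v == pytest.approx(1 / 7, rel=1e-12)

    def test_quadrature_self_convergence(self):
        x = {"G": 12, "C": 40, "M": 9}
        n = {"G": 100, "C": 120, "M": 60}
        d = {"G": 0.05, "C": 0.1, "M": 0.02}
        v256 = snp_joint_likelihood(x, n, d, Quadrature(n_nodes=256))
        v512 = snp_joint_likelihood(x, n, d, Quadrature(n_nodes=512))
        assert abs(v512 - v256) < 1e-8

    def test_allele_relabeling_symmetry(self):
        x = {"G": 12, "C": 40, "M": 9}
        n = {"G": 100, "C": 120, "M": 60}
        d = {"G": 0.05, "C": 0.1, "M": 0.02}
        flipped = {r: n[r] - x[r] for r in x}
        v1 = snp_joint_likelihood(x, n, d)
        v2 = snp_joint_likelihood(flipped, n, d)
        assert v1 == pytest.approx(v2, rel=1e-10)

    def test_missing_cohort_drops_factor(self):
        full = snp_joint_likelihood(
            {"G": 3, "C": 10}, {"G": 20, "C": 40, "M": 0}, {"G": 0.1, "C": 0.1, "M": 0.1}
        )
        two = snp_joint_likelihood(
            {"G": 3, "C": 10}, {"G": 20, "C": 40}, {"G": 0.1, "C": 0.1}
        )
        assert full == pytest.approx(two, rel=1e-12)

    def test_minimum_node_count_enforced(self):
        with pytest.raises(ValueError, match="64"):
            Quadrature(n_nodes=32)


class TestFitDriftMle:
    def test_parameter_recovery(self):
        truth = (0.05, 0.10, 0.02)
        counts = sim_counts(500, (400, 400, 400), truth, seed=101)
        est = fit_drift_mle(
            counts, grid_spec=GridSpec(n_points=16), quadrature=Quadrature(n_nodes=64)
        )
        for d_hat, d_true in zip((est.d_g, est.d_c, est.d_m), truth):
            assert d_true / 1.5 < d_hat < d_true * 1.5

    def test_exchangeable_cohorts_similar_drift(self):
        counts = sim_counts(400, (300, 300, 300), (0.05, 0.05, 0.05), seed=7)
        est = fit_drift_mle(
            counts, grid_spec=GridSpec(n_points=16), quadrature=Quadrature(n_nodes=64)
        )
        # within two refined grid steps of each other
        assert abs(np.log(est.d_g / est.d_c)) < 0.5
        assert abs(np.log(est.d_g / est.d_m)) < 0.5

    def test_single_snp_smoke(self):
        rows = {f"s{j}": (5, 10, 5, 10, 5, 10) for j in range(10)}
        est = fit_drift_mle(
            counts_table(rows), grid_spec=GridSpec(n_points=8, refine=0),
            quadrature=Quadrature(n_nodes=64),
        )
        assert np.isfinite(est.loglik_max)

    def test_loglik_nondecreasing_under_refinement(self):
        counts = sim_counts(50, (100, 100, 100), (0.05, 0.05, 0.05), seed=3)
        coarse = fit_drift_mle(
            counts, grid_spec=GridSpec(n_points=10, refine=0),
            quadrature=Quadrature(n_nodes=64),
        )
        refined = fit_drift_mle(
            counts, grid_spec=GridSpec(n_points=10, refine=2),
            quadrature=Quadrature(n_nodes=64),
        )
        assert refined.loglik_max >= coarse.loglik_max

    def test_too_few_snps_rejected(self):
        rows = {f"s{j}": (1, 10, 1, 10, 1, 10) for j in range(5)}
        with pytest.raises(ValueError, match=">= 10"):
            fit_drift_mle(counts_table(rows))

    def test_all_missing_cohort_rejected(self):
        rows = {f"s{j}": (1, 10, 1, 10, 0, 0) for j in range(12)}
        with pytest.raises(ValueError, match="cohort M"):
            fit_drift_mle(counts_table(rows))


@pytest.fixture(scope="module")
def fitted_fixture():
    counts = sim_counts(60, (200, 160, 100), (0.05, 0.08, 0.03), seed=77)
    drift = DriftEstimate(0.05, 0.08, 0.03, GridSpec(), 0.0)
    return counts, drift


class TestTailProb:
    def test_full_support_gives_one(self, fitted_fixture):
        _, drift = fitted_fixture
        counts = counts_table({"s": (30, 30, 10, 40, 5, 20)})
        tails = gam_tail_prob(counts, drift)
        assert tails.frame.at["s", "q"] == pytest.approx(1.0)

    def test_monotone_in_target_count(self, fitted_fixture):
        _, drift = fitted_fixture
        qs = []
        for x_g in range(0, 51, 5):
            counts = counts_table({"s": (x_g, 50, 15, 40, 8, 20)})
            qs.append(gam_tail_prob(counts, drift).frame.at["s", "q"])
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_target_g_is_default(self, fitted_fixture):
        counts, drift = fitted_fixture
        q1 = gam_tail_prob(counts, drift).frame["q"]
        q2 = swap_target_cohort(counts, drift, target="G").frame["q"]
        np.testing.assert_array_equal(q1.to_numpy(), q2.to_numpy())

    def test_relabeling_symmetry(self, fitted_fixture):
        counts, _ = fitted_fixture
        drift = DriftEstimate(0.05, 0.08, 0.03, GridSpec(), 0.0)
        q_g = swap_target_cohort(counts, drift, target="G").frame["q"].to_numpy()
        # permute roles: make M's data play the G role and vice versa
        f = counts.frame
        swapped = SnpCounts(
            pd.DataFrame(
                {
                    "x_g": f["x_m"], "n_g": f["n_m"],
                    "x_c": f["x_c"], "n_c": f["n_c"],
                    "x_m": f["x_g"], "n_m": f["n_g"],
                },
                index=f.index,
            )
        )
        drift_sw = DriftEstimate(0.03, 0.08, 0.05, GridSpec(), 0.0)
        q_m = swap_target_cohort(swapped, drift_sw, target="M").frame["q"].to_numpy()
        np.testing.assert_allclose(q_g, q_m, rtol=1e-9)

    def test_values_in_unit_interval(self, fitted_fixture):
        counts, drift = fitted_fixture
        q = gam_tail_prob(counts, drift).frame["q"]
        assert ((q >= 0) & (q <= 1)).all()

    def test_invalid_target_rejected(self, fitted_fixture):
        counts, drift = fitted_fixture
        with pytest.raises(ValueError, match="target"):
            swap_target_cohort(counts, drift, target="Z")

    def test_missing_cohort_rejected(self, fitted_fixture):
        _, drift = fitted_fixture
        counts = counts_table({"s": (3, 30, 10, 40, 0, 0)})
        with pytest.raises(ValueError, match="all 3 cohorts"):
            gam_tail_prob(counts, drift)


class TestMethod2EmpiricalP:
    def _tails(self, qs):
        from seldrift.method2 import TailProbTable

        ids = [f"s{i}" for i in range(len(qs))]
        frame = pd.DataFrame({"q": qs}, index=pd.Index(ids, name="snp_id"))
        return TailProbTable("G", frame), ids

    def test_hand_enumeration_n6(self):
        qs = [0.05, 0.12, 0.30, 0.45, 0.60, 0.80]
        tails, ids = self._tails(qs)
        res = method2_empirical_p(tails, [ids[0], ids[1], ids[3]])
        target = qs[0] + qs[1] + qs[3]
        expected = sum(
            1
            for combo in itertools.combinations(range(6), 3)
            if qs[combo[0]] + qs[combo[1]] + qs[combo[2]] < target - 1e-12
        )
        assert res.n_subsets == 20
        assert res.n_at_least_as_small == expected
        assert res.p_empirical == expected / 20

    def test_strict_minimum_gives_zero(self):
        tails, ids = self._tails([0.01, 0.02, 0.03, 0.5, 0.6, 0.7, 0.8])
        res = method2_empirical_p(tails, ids[:3])
        assert res.p_empirical == 0.0

    def test_ineligible_candidate_rejected(self):
        tails, ids = self._tails([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(KeyError, match="rs999"):
            method2_empirical_p(tails, [ids[0], ids[1], "rs999"])


class TestEndToEndCountsFromPanels:
    def test_counts_built_from_maf_tables(self, sim_panels):
        mm = assign_minor_alleles(sim_panels["C"])
        maf = [compute_maf(sim_panels[r], mm) for r in ("G", "C", "M")]
        counts = SnpCounts.from_maf_tables(*maf)
        f = counts.frame
        assert (f[["x_g", "x_c", "x_m"]].to_numpy() <= f[["n_g", "n_c", "n_m"]].to_numpy()).all()
        assert len(f) == sim_panels["G"].n_snps
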