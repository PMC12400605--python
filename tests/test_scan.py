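"""Genome-scan tests: counts, Omega, XtX oracles, POD calibration, BFs."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from adaptscape.scan import (
    OmegaModel,
    bf_scan,
    consolidate_runs,
    default_tau,
    estimate_omega,
    pod_threshold,
    population_allele_counts,
    xtx_scan,
)
from adaptscape.simulate import (
    SimConfig,
    compound_symmetry,
    population_of_samples,
    simulate_frequencies,
    simulate_genotypes,
)

from conftest import counts_from_frequencies, toy_genotypes


class TestPopulationAlleleCounts:
    def test_allele_counting_two_inbred_individuals(self):
        gt = toy_genotypes([[0, 2]])
        assignment = pd.DataFrame({"accession": ["s0", "s1"], "population": ["p", "p"]})
        pac = population_allele_counts(gt, assignment, maf_floor=0.0)
        assert pac.counts[0, 0] == 2 and pac.totals[0, 0] == 4

    def test_haploid_counting_halves_totals(self):
        gt = toy_genotypes([[0, 2]])
        assignment = pd.DataFrame({"accession": ["s0", "s1"], "population": ["p", "p"]})
        pac = population_allele_counts(gt, assignment, maf_floor=0.0, haploid=True)
        assert pac.counts[0, 0] == 1 and pac.totals[0, 0] == 2

    def test_maf_floor_boundary(self):
        # 1 alt allele in 200 -> pooled frequency 0.005 < floor 0.01: dropped
        gt = toy_genotypes([[1] + [0] * 99, [2] + [0] * 99])
        assignment = pd.DataFrame(
            {"accession": [f"s{i}" for i in range(100)], "population": ["p"] * 100}
        )
        pac = population_allele_counts(gt, assignment, maf_floor=0.01)
        assert pac.n_snps == 1
        assert pac.drop_log["dropped_maf"] == 1

    def test_empty_population_rejected(self, small_gt):
        bad = pd.DataFrame({"accession": ["nobody"], "population": ["ghost"]})
        with pytest.raises(ValueError, match="ghost"):
            population_allele_counts(small_gt, bad)

    def test_counts_match_known_frequencies(self, small_dataset, small_pops):
        freqs, _, gt = small_dataset
        pac = population_allele_counts(gt, small_pops, maf_floor=0.0, haploid=True)
        # per-population observed frequency within 4 binomial sd of alpha
        n = 30
        obs = pac.frequencies
        sd = np.sqrt(freqs.freqs * (1 - freqs.freqs) / n)
        assert (np.abs(obs - freqs.freqs) < 4 * sd + 1e-9).mean() > 0.999


class TestEstimateOmega:
    def test_recovers_centred_drift_covariance(self):
        # closed-form target: M Omega M' with off-diagonals shrunk by 1-delta
        P, J = 6, 30_000
        omega = compound_symmetry(P, 0.05, 0.0)
        cfg = SimConfig(n_pops=P, n_snps=J, omega_spec=omega,
                        frac_differentiated=0.0, frac_associated=0.0, seed=17)
        freqs, _ = simulate_frequencies(cfg)
        model = estimate_omega(counts_from_frequencies(freqs.freqs))
        M = np.eye(P) - np.ones((P, P)) / P
        target = M @ omega @ M
        target = 0.95 * target + 0.05 * np.diag(np.diag(target))
        assert np.abs(model.omega - target).max() < 0.005

    def test_compound_symmetry_common_component_removed(self):
        # GLS centring removes the shared rho J component; the off-diagonal
        # converges to -sigma2 (1-rho)/P (shrunk), not to sigma2 rho
        P = 6
        omega = compound_symmetry(P, 0.1, 0.5)
        cfg = SimConfig(n_pops=P, n_snps=30_000, omega_spec=omega,
                        frac_differentiated=0.0, frac_associated=0.0, seed=18)
        freqs, _ = simulate_frequencies(cfg)
        model = estimate_omega(counts_from_frequencies(freqs.freqs))
        off = model.omega[~np.eye(P, dtype=bool)]
        expected_off = -0.1 * 0.5 / P * 0.95
        assert abs(off.mean() - expected_off) < 0.005

    def test_duplicated_population_correlation_magnitude(self):
        # two populations sampled from identical latent frequencies: after
        # GLS centring the two standardized deviations are exactly opposite,
        # so the estimated correlation approaches -1 in magnitude (the
        # centring consumes the shared component; shrinkage keeps it SPD)
        cfg = SimConfig(n_pops=1, n_snps=5_000, omega_spec=np.array([[0.05]]),
                        frac_differentiated=0.0, frac_associated=0.0, seed=19)
        freqs, _ = simulate_frequencies(cfg)
        dup = np.vstack([freqs.freqs, freqs.freqs])
        rng = np.random.default_rng(20)
        n = 200
        pac = counts_from_frequencies(dup, totals=n)
        pac.counts = rng.binomial(n, dup)
        model = estimate_omega(pac, correct_sampling=False)
        corr = model.omega[0, 1] / np.sqrt(model.omega[0, 0] * model.omega[1, 1])
        assert abs(abs(corr) - 1.0) < 0.06

    def test_too_few_snps_rejected(self):
        freqs = np.full((6, 100), 0.5)
        with pytest.raises(ValueError, match="too few"):
            estimate_omega(counts_from_frequencies(freqs))


class TestXtX:
    def test_zero_when_frequencies_equal_pi(self):
        pac = counts_from_frequencies(np.full((4, 320), 0.3))
        model = OmegaModel(np.eye(4), np.full(320, 0.3), 0.0, pac.populations)
        xtx = xtx_scan(pac, model).values["xtx"]
        np.testing.assert_allclose(xtx, 0.0, atol=1e-12)

    def test_hand_computed_identity_omega(self):
        pac = counts_from_frequencies(np.array([[0.8], [0.2]]), totals=10)
        model = OmegaModel(np.eye(2), np.array([0.5]), 0.0, pac.populations)
        xtx = xtx_scan(pac, model).values["xtx"]
        # z = (0.6, -0.6), XtX = 0.72
        assert xtx[0] == pytest.approx(0.72, abs=1e-12)

    def test_matrix_inverse_oracle_correlated_omega(self):
        pac = counts_from_frequencies(np.array([[0.8], [0.2]]), totals=10)
        omega = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = OmegaModel(omega, np.array([0.5]), 0.0, pac.populations)
        xtx = xtx_scan(pac, model).values["xtx"]
        z = np.array([0.6, -0.6])
        assert xtx[0] == pytest.approx(z @ np.linalg.inv(omega) @ z, abs=1e-12)
        assert xtx[0] == pytest.approx(1.44, abs=1e-12)

    def test_invariant_under_population_relabelling(self, small_dataset, small_pops):
        _, _, gt = small_dataset
        pac = population_allele_counts(gt, small_pops, haploid=True)
        model = estimate_omega(pac)
        x1 = xtx_scan(pac, model).values["xtx"]
        perm = [2, 0, 3, 1]
        pac2 = pac.take_pops([pac.populations[i] for i in perm])
        model2 = OmegaModel(
            model.omega[np.ix_(perm, perm)], model.pi, model.shrinkage,
            pac2.populations,
        )
        x2 = xtx_scan(pac2, model2).values["xtx"]
        np.testing.assert_allclose(x1, x2, rtol=1e-10)


class TestPOD:
    def _model(self, omega_scale=0.01, seed=1):
        rng = np.random.default_rng(seed)
        return OmegaModel(
            omega=omega_scale * np.eye(6),
            pi=rng.uniform(0.2, 0.8, 5_000),
            shrinkage=0.0,
            populations=[f"p{i}" for i in range(6)],
        )

    def test_chi_square_limit_at_small_drift_scale(self):
        # as Omega -> 0 truncation vanishes and XtX -> chi2(P-1) under GLS
        # centring; at Omega = 0.01 I the 99% POD quantile matches chi2(5)
        pod = pod_threshold(self._model(), sample_sizes=None, n_pod=100_000, seed=3)
        assert pod.threshold == pytest.approx(stats.chi2.ppf(0.99, 5), abs=0.3)

    def test_median_quantile_matches_sample_median(self):
        pod = pod_threshold(self._model(), None, n_pod=10_000, q=0.5, seed=4)
        assert pod.threshold == pytest.approx(np.median(pod.xtx_sample))

    def test_seed_reproducibility(self):
        a = pod_threshold(self._model(), None, n_pod=5_000, seed=5)
        b = pod_threshold(self._model(), None, n_pod=5_000, seed=5)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.xtx_sample, b.xtx_sample)

    def test_neutral_exceedance_calibrated_at_default_conditions(self):
        # fully neutral simulation at the default study conditions: the
        # fraction of SNPs above the calibrated POD 99% threshold is 1%
        # within the binomial 95% CI
        cfg = SimConfig(n_snps=20_000, frac_differentiated=0.0,
                        frac_associated=0.0, seed=9)
        freqs, _ = simulate_frequencies(cfg)
        gt = simulate_genotypes(freqs, cfg)
        pac = population_allele_counts(gt, population_of_samples(gt), haploid=True)
        model = estimate_omega(pac)
        xtx = xtx_scan(pac, model).values["xtx"]
        pod = pod_threshold(model, pac.sample_sizes(), n_pod=100_000, seed=10,
                            calibrate_xtx=xtx)
        rate = (xtx > pod.threshold).mean()
        ci = 1.96 * np.sqrt(0.01 * 0.99 / pac.n_snps)
        assert abs(rate - 0.01) <= ci


class TestBayesFactor:
    def _case(self, z, omega, c):
        """Counts realizing standardized deviations z at pi = 0.5.

        z is clipped so the frequencies stay in (0, 1); the effective z
        actually realized (after clipping and count rounding) is returned
        for the oracle.
        """
        pi = np.array([0.5])
        freqs = np.clip((pi + z * np.sqrt(pi * (1 - pi)))[:, None], 1e-6, 1 - 1e-6)
        pac = counts_from_frequencies(freqs, totals=10**9)
        z_eff = (pac.frequencies[:, 0] - 0.5) / 0.5
        model = OmegaModel(np.asarray(omega, float), pi, 0.0, pac.populations)
        return pac, model, z_eff

    @staticmethod
    def _quadrature_bf(z, omega, c, tau):
        """Independent oracle: numerical integration of the marginal likelihood."""
        L = np.linalg.cholesky(omega)
        y = np.linalg.solve(L, z)
        c = (c - c.mean()) / c.std()
        x = np.linalg.solve(L, c)

        def integrand(beta):
            resid = y - beta * x
            return np.exp(-0.5 * resid @ resid) * stats.norm.pdf(beta, scale=tau)

        m1, _ = integrate.quad(integrand, -50 * tau, 50 * tau, limit=200)
        m0 = np.exp(-0.5 * y @ y)
        return m1 / m0

    def test_small_case_matches_quadrature(self):
        z = np.array([-1.0, 0.0, 1.0])
        c = np.array([-1.225, 0.0, 1.225])
        pac, model, z_eff = self._case(z, np.eye(3), c)
        db = bf_scan(pac, model, c, tau=1.0).values["bf_db"][0]
        bf_quad = self._quadrature_bf(z_eff, np.eye(3), c, 1.0)
        assert 10 ** (db / 10) == pytest.approx(bf_quad, rel=1e-6)

    def test_random_instances_match_quadrature(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            P = rng.integers(3, 7)
            a = rng.standard_normal((P, P)) * 0.3
            omega = a @ a.T + np.eye(P) * rng.uniform(0.2, 1.0)
            z = rng.standard_normal(P) * rng.uniform(0.5, 2.0)
            c = rng.standard_normal(P)
            c = (c - c.mean()) / c.std()
            tau = rng.uniform(0.2, 2.0)
            pac, model, z_eff = self._case(z, omega, c)
            db = bf_scan(pac, model, c, tau=tau).values["bf_db"][0]
            assert 10 ** (db / 10) == pytest.approx(
                self._quadrature_bf(z_eff, omega, c, tau), rel=1e-6
            )

    def test_null_data_disfavours_association(self):
        z = np.zeros(4)
        c = np.array([-1.0, -0.5, 0.5, 1.0])
        pac, model, _ = self._case(z, np.eye(4), c)
        tau = 1.0
        db = bf_scan(pac, model, c, tau=tau).values["bf_db"][0]
        sxx = float(((c - c.mean()) / c.std()) @ ((c - c.mean()) / c.std()))
        assert db == pytest.approx(-5 * np.log10(1 + tau**2 * sxx), abs=1e-9)
        assert db <= 0

    def test_vanishing_prior_gives_unit_bayes_factor(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5)
        c = rng.standard_normal(5)
        pac, model, _ = self._case(z, np.eye(5), c)
        db = bf_scan(pac, model, c, tau=1e-9).values["bf_db"][0]
        assert db == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_covariate_rejected(self):
        pac, model, _ = self._case(np.zeros(3), np.eye(3), np.array([-1.0, 0, 1.0]))
        with pytest.raises(ValueError, match="covariate"):
            bf_scan(pac, model, np.ones(3))

    def test_default_tau_scaling(self):
        assert default_tau(sxx=6.0, n_pops=6) == pytest.approx(np.sqrt(0.1))


class TestConsolidate:
    def _scores(self, xtx):
        from adaptscape.scan import ScanScores

        snps = pd.DataFrame({"chrom": ["c"] * len(xtx), "pos": np.arange(len(xtx)),
                             "ref": "A", "alt": "T"})
        return ScanScores(snps=snps, values={"xtx": np.asarray(xtx, float)})

    def test_identical_runs_unchanged(self):
        runs = [self._scores([1.0, 2.0])] * 3
        out = consolidate_runs(runs)
        np.testing.assert_allclose(out.values["xtx"], [1.0, 2.0])
        np.testing.assert_allclose(out.sd["xtx"], 0.0)

    def test_mean_and_sd_arithmetic(self):
        out = consolidate_runs([self._scores([10.0]), self._scores([20.0])])
        assert out.values["xtx"][0] == pytest.approx(15.0)
        assert out.sd["xtx"][0] == pytest.approx(np.sqrt(50.0))

    def test_run_order_irrelevant(self):
        a, b = self._scores([1.0, 5.0]), self._scores([3.0, 2.0])
        np.testing.assert_allclose(
            consolidate_runs([a, b]).values["xtx"],
            consolidate_runs([b, a]).values["xtx"],
        )

    def test_mismatched_snp_sets_rejected(self):
        a = self._scores([1.0, 2.0])
        b = self._scores([1.0, 2.0])
        b.snps.loc[1, "pos"] = 999
        with pytest.raises(ValueError, match="disagree"):
            consolidate_runs([a, b])
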