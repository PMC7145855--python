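import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinpls import (
    CohortSpec,
    TraitSpec,
    build_pedigree,
    covariate_design,
    expected_relatedness,
    fit_bivariate,
    fit_univariate,
    implied_phenotypic_correlation,
    lrt_boundary_pvalue,
    polygenic_loglik,
    simulate_cohort,
)
from twinpls.pedigree import RelatednessMatrix
from twinpls.varcomp import PolygenicModel, UnidentifiableError

from conftest import random_pedigree_frame, twin_cohort


def _singleton_kinship(n=1):
    ids = [f"i{k}" for k in range(n)]
    return RelatednessMatrix(ids, np.eye(n), [np.array([k]) for k in range(n)])


def _mz_pair_kinship():
    ids = ["a", "b"]
    V = np.array([[1.0, 1.0], [1.0, 1.0]])
    return RelatednessMatrix(ids, V, [np.array([0, 1])])


def dense_loglik(y, X, K, h2, s2, beta):
    """Independent oracle: full-matrix multivariate-normal log-density."""
    mu = X @ beta if X is not None else np.zeros_like(y)
    cov = s2 * (h2 * K + (1 - h2) * np.eye(len(y)))
    return stats.multivariate_normal(mean=mu, cov=cov, allow_singular=False).logpdf(y)


def grid_search_h2(y, X, K, step=0.001):
    """Independent ML oracle: exhaustive h2 grid with dense-GLS profiling."""
    n = len(y)
    best = (-np.inf, 0.0)
    for h2 in np.arange(0.0, 1.0 + step / 2, step):
        h2 = min(h2, 1 - 1e-6)
        V = h2 * K + (1 - h2) * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = float(r @ Vi @ r) / n
        _, logdet = np.linalg.slogdet(V)
        ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
        if ll > best[0]:
            best = (ll, h2)
    return best[1]


class TestPolygenicLoglik:
    def test_single_standard_normal(self):
        K = _singleton_kinship()
        for h2 in (0.0, 0.3, 0.9):
            assert polygenic_loglik([0.0], None, K, h2, 1.0, [0.0]) == pytest.approx(
                -0.5 * np.log(2 * np.pi), abs=1e-4
            )

    def test_mz_pair_at_origin(self):
        # bivariate normal with correlation 0.5: -ln(2*pi) - 0.5*ln(0.75)
        K = _mz_pair_kinship()
        got = polygenic_loglik([0.0, 0.0], None, K, 0.5, 1.0, [0.0])
        assert got == pytest.approx(-np.log(2 * np.pi) - 0.5 * np.log(0.75), abs=1e-4)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        df = random_pedigree_frame(rng, max_n=20)
        ped = build_pedigree(df)
        K = expected_relatedness(ped)
        y = rng.standard_normal(len(ped))
        ll = polygenic_loglik(y, None, K, 0.4, 1.3, [0.0])
        perm = rng.permutation(len(ped))
        ped2 = build_pedigree(df.iloc[perm].reset_index(drop=True))
        K2 = expected_relatedness(ped2)
        ll2 = polygenic_loglik(y[perm], None, K2, 0.4, 1.3, [0.0])
        assert ll2 == pytest.approx(ll, abs=1e-10)

    def test_singular_block_reported(self):
        K = _mz_pair_kinship()
        with pytest.raises(np.linalg.LinAlgError, match="block"):
            polygenic_loglik([0.0, 0.0], None, K, 1.0, 1.0, [0.0])

    def test_matches_dense_oracle_on_random_cohorts(self):
        """Blockwise factorized likelihood equals dense MVN evaluation."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            df = random_pedigree_frame(rng, max_n=int(rng.integers(6, 31)))
            ped = build_pedigree(df)
            K = expected_relatedness(ped)
            n = len(ped)
            d = covariate_design(ped.ids, df["age"], df["sex"])
            beta = rng.standard_normal(d.k) * 0.1
            y = rng.standard_normal(n) + d.matrix @ beta
            h2 = float(rng.uniform(0, 0.95))
            s2 = float(rng.uniform(0.3, 3.0))
            got = polygenic_loglik(y, d, K, h2, s2, beta)
            want = dense_loglik(y, d.matrix, K.values, h2, s2, beta)
            assert got == pytest.approx(want, abs=1e-8)


class TestBoundaryLRT:
    @pytest.mark.parametrize("t,expected", [
        (0.0, 0.5),
        (-1e-8, 0.5),
        (3.84, 0.025022),
    ])
    def test_values(self, t, expected):
        assert lrt_boundary_pvalue(t) == pytest.approx(expected, abs=1e-4)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt_boundary_pvalue(-0.5)


class TestFitUnivariate:
    def test_perfect_mz_correlation_hits_boundary(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(50):
            for k in (1, 2):
                rows.append({"id": f"p{p}_{k}", "family_id": f"F{p}",
                             "pair_id": f"p{p}", "zygosity": "MZ"})
        ped = build_pedigree(pd.DataFrame(rows))
        K = expected_relatedness(ped)
        vals = np.repeat(rng.standard_normal(50), 2)  # co-twins identical
        res = fit_univariate(vals, None, K)
        assert res.h2 >= 0.99
        assert res.p_boundary < 1e-6

    def test_null_cohorts_estimate_near_zero(self):
        estimates = []
        for seed in range(20):
            K, design, y = twin_cohort(h2=0.0, n_mz=125, n_dz=125, n_sing=0,
                                       seed=seed)
            estimates.append(fit_univariate(y, design, K).h2)
        assert np.median(estimates) < 0.05

    def test_matches_grid_search_oracle_on_small_cohorts(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 20:
            df = random_pedigree_frame(rng, max_n=12)
            ped = build_pedigree(df)
            K = expected_relatedness(ped)
            if all(len(b) == 1 for b in K.blocks):
                continue
            n = len(ped)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            from twinpls.transforms import CovariateDesign
            d = CovariateDesign(ped.ids, ["intercept", "x"], X)
            L = np.linalg.cholesky(0.5 * K.values + 0.5 * np.eye(n))
            y = L @ rng.standard_normal(n) + X @ [0.2, -0.1]
            if n <= d.k + 2:
                continue
            got = fit_univariate(y, d, K).h2
            want = grid_search_h2(y, X, K.values)
            assert got == pytest.approx(want, abs=0.005)
            checked += 1

    def test_all_singletons_unidentifiable(self):
        K = _singleton_kinship(30)
        rng = np.random.default_rng(0)
        with pytest.raises(UnidentifiableError):
            PolygenicModel(rng.standard_normal(30), None, K)

    def test_affine_rescaling_invariance(self):
        K, design, y = twin_cohort(h2=0.5, n_mz=60, n_dz=40, n_sing=50, seed=9)
        r1 = fit_univariate(y, design, K)
        r2 = fit_univariate(3.7 * y - 12.0, design, K)
        assert r2.h2 == pytest.approx(r1.h2, abs=1e-6)
        assert r2.sigma_p2 == pytest.approx(3.7**2 * r1.sigma_p2, rel=1e-5)

    def test_recovery_bias_small(self):
        """Mean bias < 0.03 at 500 MZ + 500 DZ pairs across h2 levels."""
        for h2 in (0.2, 0.5, 0.8):
            est = [
                fit_univariate(*reversed(twin_cohort(
                    h2=h2, n_mz=500, n_dz=500, n_sing=0, seed=1000 + s))).h2
                for s in range(12)
            ]
            assert abs(np.mean(est) - h2) < 0.03


class TestImpliedPhenotypicCorrelation:
    @pytest.mark.parametrize("h2a,h2b,rg,re,expected", [
        (1.0, 1.0, 0.5, -0.9, 0.5),          # fully heritable: rho_e vanishes
        (0.3, 0.3, 0.4, 0.4, 0.4),           # equal weights sum to one
        (0.24, 0.66, 0.42, 0.19, 0.2637407), # hand-evaluated decomposition
    ])
    def test_examples(self, h2a, h2b, rg, re, expected):
        got = implied_phenotypic_correlation(h2a, h2b, rg, re)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_exactness(self):
        got = implied_phenotypic_correlation(0.24, 0.66, 0.42, 0.19)
        want = 0.42 * np.sqrt(0.24 * 0.66) + 0.19 * np.sqrt(0.76 * 0.34)
        assert got == pytest.approx(want, abs=1e-12)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            implied_phenotypic_correlation(1.2, 0.5, 0, 0)
        with pytest.raises(ValueError):
            implied_phenotypic_correlation(0.5, 0.5, 1.5, 0)


class TestFitBivariate:
    def test_trait_with_itself(self):
        K, design, y = twin_cohort(h2=0.6, n_mz=100, n_dz=60, n_sing=100, seed=2)
        res = fit_bivariate(y, y.copy(), design, K)
        assert res.rho_g == pytest.approx(1.0, abs=0.01)
        assert res.rho_e == pytest.approx(1.0, abs=0.01)

    def test_independent_traits_null(self):
        rgs, pgs = [], []
        for seed in range(20):
            spec = CohortSpec(
                n_mz_pairs=125, n_dz_pairs=125, n_singletons=0,
                traits=(TraitSpec("a", h2=0.5), TraitSpec("b", h2=0.5)),
            )
            ped, ph = simulate_cohort(spec, seed=3000 + seed)
            K = expected_relatedness(ped)
            d = covariate_design(ph["id"], ph["age"], ph["sex"])
            r = fit_bivariate(ph["a"].to_numpy(), ph["b"].to_numpy(), d, K,
                              seed=seed)
            rgs.append(abs(r.rho_g))
            pgs.append(r.p_rho_g)
        assert np.median(rgs) < 0.1
        # p-values roughly uniform under the null
        assert 0.15 < np.mean(pgs) < 0.85
        assert np.mean(np.array(pgs) < 0.05) <= 0.25

    def test_decomposition_identity_holds(self):
        K, design, _ = twin_cohort(h2=0.4, n_mz=80, n_dz=60, n_sing=60, seed=5)
        spec = CohortSpec(
            n_mz_pairs=80, n_dz_pairs=60, n_singletons=60,
            traits=(TraitSpec("a", h2=0.4), TraitSpec("b", h2=0.6)),
            rho_g=np.array([[1, 0.5], [0.5, 1]]),
            rho_e=np.array([[1, 0.2], [0.2, 1]]),
        )
        ped, ph = simulate_cohort(spec, seed=5)
        K = expected_relatedness(ped)
        d = covariate_design(ph["id"], ph["age"], ph["sex"])
        res = fit_bivariate(ph["a"].to_numpy(), ph["b"].to_numpy(), d, K, seed=5)
        want = implied_phenotypic_correlation(res.h2_a, res.h2_b, res.rho_g,
                                              res.rho_e)
        assert res.rho_p_model == pytest.approx(want, abs=1e-12)
        assert -1 <= res.rho_g <= 1 and -1 <= res.rho_e <= 1

    def test_genetic_correlation_recovery(self):
        """Generative rho_g = 0.4 recovered in the mean at 500+500 pairs."""
        spec = CohortSpec(
            n_mz_pairs=500, n_dz_pairs=500, n_singletons=0,
            traits=(TraitSpec("a", h2=0.6), TraitSpec("b", h2=0.6)),
            rho_g=np.array([[1, 0.4], [0.4, 1]]),
            rho_e=np.eye(2),
        )
        est = []
        for seed in range(12):
            ped, ph = simulate_cohort(spec, seed=4000 + seed)
            K = expected_relatedness(ped)
            d = covariate_design(ph["id"], ph["age"], ph["sex"])
            est.append(
                fit_bivariate(ph["a"].to_numpy(), ph["b"].to_numpy(), d, K,
                              seed=seed).rho_g
            )
        assert np.mean(est) == pytest.approx(0.4, abs=0.05)
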