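"""Maximum-likelihood polygenic variance decomposition on pedigrees.

The univariate model for a trait y is

    y ~ N(X beta, Omega),   Omega = sigma_p^2 * (h2 * K + (1 - h2) * I)

where K is the expected relatedness matrix (1 for MZ co-twins, 0.5 for
DZ/sibs) and h2 is the narrow-sense heritability.  Because K is block
diagonal by family, the likelihood factorizes over families; each block is
eigendecomposed once and beta, sigma_p^2 are profiled out in closed form
(GLS) at every h2, leaving a one-dimensional bounded optimization.

The bivariate model stacks two traits with covariance

    Omega = G (x) K-structure + E (x) I-structure

for 2x2 genetic and environmental covariance matrices G, E parameterized
through Cholesky-like factors (so both stay positive semi-definite).  The
genetic and environmental correlations rho_g, rho_e are read off G and E,
and the model-implied phenotypic correlation obeys

    rho_p = rho_g * sqrt(h1^2 h2^2) + rho_e * sqrt((1 - h1^2)(1 - h2^2)).

Significance: h2 is tested with a boundary likelihood-ratio test (50:50
mixture of chi^2_0 and chi^2_1); rho_g and rho_e are interior parameters
tested against plain chi^2_1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import RelatednessMatrix
from .transforms import CovariateDesign

__all__ = [
    "HeritabilityResults",
    "GeneticCorrelationResults",
    "PolygenicModel",
    "BivariatePolygenicModel",
    "polygenic_loglik",
    "fit_univariate",
    "fit_bivariate",
    "lrt_boundary_pvalue",
    "implied_phenotypic_correlation",
]

_H2_CAP = 1.0 - 1e-6  # h2=1 makes MZ blocks singular
_LOG2PI = float(np.log(2.0 * np.pi))


class UnidentifiableError(ValueError):
    """Variance components cannot be separated (e.g. no relative pairs)."""


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# small closed forms


def lrt_boundary_pvalue(lrt_stat: float) -> float:
    """Boundary LRT p-value for a variance component tested against 0.

    Null distribution is the 50:50 mixture of a point mass at zero and
    chi^2_1, so p = 0.5 * P(chi^2_1 >= T), and p = 0.5 at T = 0.  Small
    negative statistics (numerical noise) are clipped to zero.
    """
    if lrt_stat < -1e-6:
        raise ValueError(f"negative LRT statistic {lrt_stat}: fit inconsistency")
    t = max(lrt_stat, 0.0)
    if t == 0.0:
        return 0.5
    return float(0.5 * stats.chi2.sf(t, df=1))


def implied_phenotypic_correlation(
    h2_a: float, h2_b: float, rho_g: float, rho_e: float
) -> float:
    """Phenotypic correlation implied by the bivariate decomposition."""
    for h in (h2_a, h2_b):
        if not 0.0 <= h <= 1.0:
            raise ValueError("heritabilities must lie in [0, 1]")
    for r in (rho_g, rho_e):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    return rho_g * np.sqrt(h2_a * h2_b) + rho_e * np.sqrt((1 - h2_a) * (1 - h2_b))


# --------------------------------------------------------------------------
# blockwise machinery


@dataclass
class _BlockTransform:
    """Per-family eigendecompositions of K; rotating data into the eigenbasis
    diagonalizes Omega for every h2 simultaneously."""

    lam: np.ndarray                       # concatenated eigenvalues, length n
    blocks: list[tuple[np.ndarray, np.ndarray | None]]  # (indices, U or None)

    @classmethod
    def from_kinship(cls, K: RelatednessMatrix) -> "_BlockTransform":
        lam = np.empty(K.n)
        blocks: list[tuple[np.ndarray, np.ndarray | None]] = []
        for idx in K.blocks:
            if idx.size == 1:
                lam[idx] = 1.0
                blocks.append((idx, None))
            else:
                w, U = np.linalg.eigh(K.values[np.ix_(idx, idx)])
                lam[idx] = w
                blocks.append((idx, U))
        return cls(lam, blocks)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Apply blockwise U^T along axis 0 (works for vectors and matrices)."""
        out = np.array(v, dtype=float, copy=True)
        for idx, U in self.blocks:
            if U is not None:
                out[idx] = U.T @ out[idx]
        return out


def polygenic_loglik(
    trait,
    design: CovariateDesign | None,
    relatedness: RelatednessMatrix,
    h2: float,
    sigma_p2: float,
    beta,
) -> float:
    """Blockwise multivariate-normal log-likelihood of the polygenic model.

    Evaluates the log-density of ``trait`` with mean ``design . beta`` and
    covariance ``sigma_p2 * (h2*K + (1-h2)*I)`` family block by family
    block; equals dense evaluation up to numerical error.
    """
    y = np.asarray(trait, dtype=float)
    if sigma_p2 <= 0:
        raise ValueError("sigma_p2 must be positive")
    if design is not None:
        mu = design.matrix @ np.asarray(beta, dtype=float)
    else:
        b = np.atleast_1d(np.asarray(beta, dtype=float))
        mu = np.zeros_like(y) if not b.size or not b.any() else np.full_like(y, b[0])
    r = y - mu
    ll = 0.0
    for bi, idx in enumerate(relatedness.blocks):
        Kb = relatedness.values[np.ix_(idx, idx)]
        Ob = sigma_p2 * (h2 * Kb + (1.0 - h2) * np.eye(idx.size))
        w, U = np.linalg.eigh(Ob)
        if w.min() <= 1e-12 * max(1.0, w.max()):
            raise np.linalg.LinAlgError(
                f"singular covariance in family block {bi} (size {idx.size}, "
                f"h2={h2}): min eigenvalue {w.min():.3g}"
            )
        z = U.T @ r[idx]
        ll += -0.5 * (idx.size * _LOG2PI + np.log(w).sum() + (z**2 / w).sum())
    return float(ll)


# --------------------------------------------------------------------------
# univariate model


@dataclass
class HeritabilityResults:
    """ML heritability estimate for one trait on one pedigree."""

    trait: str
    h2: float
    se_h2: float
    sigma_p2: float
    beta: pd.Series
    loglik_full: float
    loglik_null: float
    p_boundary: float
    n_used: int

    @property
    def lrt_stat(self) -> float:
        return 2.0 * (self.loglik_full - self.loglik_null)

    def summary(self) -> str:
        lines = [
            "Polygenic variance decomposition (univariate ML)",
            f"  trait: {self.trait}    n used: {self.n_used}",
            f"  h2 = {self.h2:.4f}  (SE {self.se_h2:.4f})"
            if np.isfinite(self.se_h2)
            else f"  h2 = {self.h2:.4f}  (SE n/a: boundary)",
            f"  sigma_p^2 = {self.sigma_p2:.4f}",
            f"  logL full = {self.loglik_full:.4f}   logL(h2=0) = {self.loglik_null:.4f}",
            f"  boundary LRT p = {self.p_boundary:.4g}",
            "  fixed effects:",
        ]
        for name, val in self.beta.items():
            lines.append(f"    {name:>12s}  {val: .5f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": self.trait,
                    "estimate": self.h2,
                    "se": self.se_h2,
                    "sigma_p2": self.sigma_p2,
                    "loglik_full": self.loglik_full,
                    "loglik_null": self.loglik_null,
                    "p": self.p_boundary,
                    "n": self.n_used,
                }
            ]
        )


class PolygenicModel:
    """Univariate polygenic model for one trait on a pedigree.

    Parameters
    ----------
    endog : array-like
        Trait values aligned with ``kinship.ids``; NaNs are dropped
        listwise together with missing covariate rows.
    exog : CovariateDesign or None
        Fixed-effects design (intercept-only if None); estimated jointly
        with the variance components.
    kinship : RelatednessMatrix
        Expected relatedness on the 2*phi scale.
    """

    def __init__(self, endog, exog, kinship, trait_name: str = "trait"):
        y = np.asarray(endog, dtype=float)
        if y.shape[0] != kinship.n:
            raise ValueError("endog length does not match kinship")
        if exog is None:
            exog = CovariateDesign.intercept_only(kinship.ids)
        mask = ~np.isnan(y) & ~np.isnan(exog.matrix).any(axis=1)
        ids = [kinship.ids[i] for i in np.nonzero(mask)[0]]
        self.kinship = kinship.reindex(ids)
        self.endog = y[mask]
        self.exog = exog.subset(ids)
        self.trait_name = trait_name
        self.n_used = int(mask.sum())
        if self.n_used <= self.exog.k + 2:
            raise ValueError("too few observations for the design")
        self._tf = _BlockTransform.from_kinship(self.kinship)
        self._yt = self._tf.rotate(self.endog)
        self._Xt = self._tf.rotate(self.exog.matrix)
        if np.allclose(self._tf.lam, 1.0):
            raise UnidentifiableError(
                "h2 unidentifiable: pedigree contains no informative relative pairs"
            )

    # profile log-likelihood with beta, sigma_p2 solved by GLS at fixed h2
    def _profile(self, h2: float):
        d = h2 * self._tf.lam + (1.0 - h2)
        w = 1.0 / d
        Xw = self._Xt * w[:, None]
        A = self._Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ self._yt)
        r = self._yt - self._Xt @ beta
        n = self.n_used
        s2 = float((r * r * w).sum() / n)
        ll = -0.5 * (n * _LOG2PI + n * np.log(s2) + np.log(d).sum() + n)
        return float(ll), beta, s2

    def profile_loglik(self, h2: float) -> float:
        return self._profile(h2)[0]

    def fit(self) -> HeritabilityResults:
        # coarse grid guards against local optima, then bounded refinement
        grid = np.linspace(0.0, _H2_CAP, 21)
        vals = [self.profile_loglik(h) for h in grid]
        j = int(np.argmax(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda h: -self.profile_loglik(h),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h2 = float(res.x)
        ll_full, beta, s2 = self._profile(h2)
        # boundary candidates
        for cand in (0.0, _H2_CAP):
            ll_c = self.profile_loglik(cand)
            if ll_c > ll_full:
                h2, ll_full = cand, ll_c
                _, beta, s2 = self._profile(cand)
        ll_null = self.profile_loglik(0.0)
        se = self._se_h2(h2, ll_full)
        p = lrt_boundary_pvalue(2.0 * (ll_full - ll_null))
        return HeritabilityResults(
            trait=self.trait_name,
            h2=h2,
            se_h2=se,
            sigma_p2=s2,
            beta=pd.Series(beta, index=self.exog.columns),
            loglik_full=ll_full,
            loglik_null=ll_null,
            p_boundary=p,
            n_used=self.n_used,
        )

    def _se_h2(self, h2: float, ll_full: float) -> float:
        # curvature of the profile log-likelihood; unreliable at boundaries
        if h2 < 0.01 or h2 > 0.99:
            return float("nan")
        step = min(1e-3, h2 / 2, (1 - h2) / 2)
        d2 = (
            self.profile_loglik(h2 + step)
            - 2.0 * ll_full
            + self.profile_loglik(h2 - step)
        ) / step**2
        if d2 >= 0:
            return float("nan")
        return float(1.0 / np.sqrt(-d2))


def fit_univariate(trait, design, relatedness, trait_name="trait") -> HeritabilityResults:
    """ML heritability with covariates estimated inside the likelihood."""
    return PolygenicModel(trait, design, relatedness, trait_name).fit()


# --------------------------------------------------------------------------
# bivariate model


@dataclass
class GeneticCorrelationResults:
    """Joint ML decomposition of the covariance of a trait pair."""

    trait_a: str
    trait_b: str
    rho_g: float
    rho_e: float
    rho_p_model: float
    h2_a: float
    h2_b: float
    se_rho_g: float
    se_rho_e: float
    p_rho_g: float
    p_rho_e: float
    loglik_full: float
    n_used: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        return "\n".join(
            [
                "Bivariate polygenic decomposition (ML)",
                f"  traits: {self.trait_a} / {self.trait_b}    n used: {self.n_used}",
                f"  rho_g = {self.rho_g: .4f}  (SE {self.se_rho_g:.4f}, LRT p = {self.p_rho_g:.4g})",
                f"  rho_e = {self.rho_e: .4f}  (SE {self.se_rho_e:.4f}, LRT p = {self.p_rho_e:.4g})"
                "  [includes measurement error]",
                f"  implied rho_p = {self.rho_p_model: .4f}",
                f"  h2: {self.trait_a} = {self.h2_a:.4f}, {self.trait_b} = {self.h2_b:.4f}",
                f"  logL full = {self.loglik_full:.4f}",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait_a": self.trait_a,
                    "trait_b": self.trait_b,
                    "rho_g": self.rho_g,
                    "se_rho_g": self.se_rho_g,
                    "p_rho_g": self.p_rho_g,
                    "rho_e": self.rho_e,
                    "se_rho_e": self.se_rho_e,
                    "p_rho_e": self.p_rho_e,
                    "rho_p_model": self.rho_p_model,
                    "h2_a": self.h2_a,
                    "h2_b": self.h2_b,
                    "loglik_full": self.loglik_full,
                    "n": self.n_used,
                }
            ]
        )


def _unpack_theta(theta, fix_g=False, fix_e=False):
    """theta -> (G, E).  Genetic factor entries are free reals (G may hit
    zero); environmental diagonal goes through exp so E stays PD."""
    t = list(theta)
    a = t.pop(0)
    b = 0.0 if fix_g else t.pop(0)
    c = t.pop(0)
    d = np.exp(min(t.pop(0), 50.0))
    e = 0.0 if fix_e else t.pop(0)
    f = np.exp(min(t.pop(0), 50.0))
    g11, g12, g22 = a * a, a * b, b * b + c * c
    e11, e12, e22 = d * d, d * e, e * e + f * f
    return (g11, g12, g22), (e11, e12, e22)


class BivariatePolygenicModel:
    """Two-trait polygenic model yielding genetic/environmental correlations.

    Fixed effects for both traits are profiled out by GLS inside every
    likelihood evaluation; G and E are optimized through Cholesky factors
    by quasi-Newton with seeded random restarts.
    """

    def __init__(self, endog_a, endog_b, exog, kinship,
                 trait_names=("trait_a", "trait_b"), n_restarts: int = 5,
                 seed: int = 0):
        y1 = np.asarray(endog_a, dtype=float)
        y2 = np.asarray(endog_b, dtype=float)
        if y1.shape[0] != kinship.n or y2.shape[0] != kinship.n:
            raise ValueError("endog length does not match kinship")
        if exog is None:
            exog = CovariateDesign.intercept_only(kinship.ids)
        mask = (
            ~np.isnan(y1) & ~np.isnan(y2) & ~np.isnan(exog.matrix).any(axis=1)
        )
        ids = [kinship.ids[i] for i in np.nonzero(mask)[0]]
        self.kinship = kinship.reindex(ids)
        self.exog = exog.subset(ids)
        self.y = np.column_stack([y1[mask], y2[mask]])
        self.trait_names = tuple(trait_names)
        self.n_used = int(mask.sum())
        self.n_restarts = int(n_restarts)
        self.seed = int(seed)
        self._tf = _BlockTransform.from_kinship(self.kinship)
        if np.allclose(self._tf.lam, 1.0):
            raise UnidentifiableError(
                "variance components unidentifiable: no relative pairs"
            )
        self._y1t = self._tf.rotate(self.y[:, 0])
        self._y2t = self._tf.rotate(self.y[:, 1])
        self._Xt = self._tf.rotate(self.exog.matrix)
        self._lam = self._tf.lam

    # -- likelihood ---------------------------------------------------------

    def _negloglik(self, theta, fix_g=False, fix_e=False) -> float:
        (g11, g12, g22), (e11, e12, e22) = _unpack_theta(theta, fix_g, fix_e)
        lam = self._lam
        c11 = lam * g11 + e11
        c12 = lam * g12 + e12
        c22 = lam * g22 + e22
        det = c11 * c22 - c12 * c12
        if np.any(det <= 0) or np.any(c11 <= 0):
            return 1e12
        w11 = c22 / det
        w22 = c11 / det
        w12 = -c12 / det
        X = self._Xt
        p = X.shape[1]
        A = np.empty((2 * p, 2 * p))
        A[:p, :p] = X.T @ (w11[:, None] * X)
        A[p:, p:] = X.T @ (w22[:, None] * X)
        A[:p, p:] = X.T @ (w12[:, None] * X)
        A[p:, :p] = A[:p, p:].T
        rhs = np.concatenate(
            [
                X.T @ (w11 * self._y1t + w12 * self._y2t),
                X.T @ (w12 * self._y1t + w22 * self._y2t),
            ]
        )
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return 1e12
        r1 = self._y1t - X @ beta[:p]
        r2 = self._y2t - X @ beta[p:]
        n = self.n_used
        with np.errstate(over="ignore", invalid="ignore"):
            quad = w11 * r1 * r1 + 2.0 * w12 * r1 * r2 + w22 * r2 * r2
            nll = 0.5 * (2 * n * _LOG2PI + np.log(det).sum() + quad.sum())
        return float(nll) if np.isfinite(nll) else 1e12

    def loglik(self, theta) -> float:
        return -self._negloglik(theta)

    # -- initialization -----------------------------------------------------

    def _smart_start(self):
        fits = []
        for k in range(2):
            m = PolygenicModel(self.y[:, k], self.exog, self.kinship)
            fits.append(m.fit())
        # residual phenotypic correlation after fixed effects (OLS)
        X = self.exog.matrix
        B, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        R = self.y - X @ B
        rp = float(np.corrcoef(R[:, 0], R[:, 1])[0, 1])
        rp = float(np.clip(rp, -0.9, 0.9))
        sg = [max(f.h2, 0.02) * f.sigma_p2 for f in fits]
        se_ = [max(1 - f.h2, 0.02) * f.sigma_p2 for f in fits]
        G0 = np.array(
            [
                [sg[0], rp * np.sqrt(sg[0] * sg[1])],
                [rp * np.sqrt(sg[0] * sg[1]), sg[1]],
            ]
        )
        E0 = np.array(
            [
                [se_[0], rp * np.sqrt(se_[0] * se_[1])],
                [rp * np.sqrt(se_[0] * se_[1]), se_[1]],
            ]
        )
        Lg = np.linalg.cholesky(G0 + 1e-8 * np.eye(2))
        Le = np.linalg.cholesky(E0 + 1e-8 * np.eye(2))
        return np.array(
            [
                Lg[0, 0],
                Lg[1, 0],
                Lg[1, 1],
                np.log(Le[0, 0]),
                Le[1, 0],
                np.log(Le[1, 1]),
            ]
        )

    def _starts(self, theta0, fix_g, fix_e):
        def drop(th):
            th = list(th)
            out = [th[0]]
            if not fix_g:
                out.append(th[1])
            out.extend([th[2], th[3]])
            if not fix_e:
                out.append(th[4])
            out.append(th[5])
            return np.array(out)

        rng = np.random.default_rng(self.seed + 11)
        starts = [drop(theta0)]
        for _ in range(self.n_restarts - 1):
            pert = theta0 * (1 + 0.3 * rng.standard_normal(6)) + 0.1 * rng.standard_normal(6)
            starts.append(drop(pert))
        return starts

    def _optimize(self, fix_g=False, fix_e=False, theta0=None):
        if theta0 is None:
            theta0 = self._smart_start()
        best = None
        for x0 in self._starts(theta0, fix_g, fix_e):
            res = optimize.minimize(
                self._negloglik,
                x0,
                args=(fix_g, fix_e),
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
            raise ConvergenceError(
                f"bivariate fit failed to converge after {self.n_restarts} starts"
            )
        return best

    # -- fit ----------------------------------------------------------------

    def fit(self) -> GeneticCorrelationResults:
        theta0 = self._smart_start()
        full = self._optimize(theta0=theta0)
        (g11, g12, g22), (e11, e12, e22) = _unpack_theta(full.x)
        ll_full = -full.fun

        def corr(v11, v12, v22):
            denom = np.sqrt(v11 * v22)
            return float(v12 / denom) if denom > 1e-12 else 0.0

        rho_g = float(np.clip(corr(g11, g12, g22), -1.0, 1.0))
        rho_e = float(np.clip(corr(e11, e12, e22), -1.0, 1.0))
        h2_a = g11 / (g11 + e11)
        h2_b = g22 / (g22 + e22)

        rg0 = self._optimize(fix_g=True, theta0=theta0)
        re0 = self._optimize(fix_e=True, theta0=theta0)
        t_g = max(2.0 * (ll_full - (-rg0.fun)), 0.0)
        t_e = max(2.0 * (ll_full - (-re0.fun)), 0.0)
        p_g = float(stats.chi2.sf(t_g, df=1))
        p_e = float(stats.chi2.sf(t_e, df=1))

        se_g, se_e = self._correlation_ses(full.x, rho_g, rho_e, h2_a, h2_b)
        return GeneticCorrelationResults(
            trait_a=self.trait_names[0],
            trait_b=self.trait_names[1],
            rho_g=rho_g,
            rho_e=rho_e,
            rho_p_model=implied_phenotypic_correlation(h2_a, h2_b, rho_g, rho_e),
            h2_a=float(h2_a),
            h2_b=float(h2_b),
            se_rho_g=se_g,
            se_rho_e=se_e,
            p_rho_g=p_g,
            p_rho_e=p_e,
            loglik_full=float(ll_full),
            n_used=self.n_used,
            metadata={"rho_e_note": "includes measurement error"},
        )

    def _correlation_ses(self, theta, rho_g, rho_e, h2_a, h2_b):
        """Delta-method SEs from the numerical Hessian; NA near boundaries."""
        near_boundary = (
            min(h2_a, 1 - h2_a, h2_b, 1 - h2_b) < 0.01
            or max(abs(rho_g), abs(rho_e)) > 0.99
        )
        if near_boundary:
            return float("nan"), float("nan")
        k = len(theta)
        h = 1e-4 * np.maximum(np.abs(theta), 1.0)
        H = np.empty((k, k))
        f0 = self._negloglik(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = self._negloglik(theta + ei + ej)
                fpm = self._negloglik(theta + ei - ej)
                fmp = self._negloglik(theta - ei + ej)
                fmm = self._negloglik(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")

        def rho_of(th):
            (a11, a12, a22), (b11, b12, b22) = _unpack_theta(th)
            rg = a12 / np.sqrt(a11 * a22) if a11 * a22 > 1e-24 else 0.0
            re_ = b12 / np.sqrt(b11 * b22) if b11 * b22 > 1e-24 else 0.0
            return np.array([rg, re_])

        J = np.empty((2, k))
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            J[:, i] = (rho_of(theta + ei) - rho_of(theta - ei)) / (2 * h[i])
        var = np.einsum("ik,kl,jl->ij", J, cov, J)
        d = np.diag(var)
        se = np.sqrt(np.where(d > 0, d, np.nan))
        _ = f0
        return float(se[0]), float(se[1])


def fit_bivariate(
    trait_a, trait_b, design, relatedness,
    trait_names=("trait_a", "trait_b"), seed: int = 0,
) -> GeneticCorrelationResults:
    """Joint ML genetic/environmental correlation for a trait pair."""
    return BivariatePolygenicModel(
        trait_a, trait_b, design, relatedness, trait_names=trait_names, seed=seed
    ).fit()
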