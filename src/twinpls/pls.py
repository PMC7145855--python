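"""Partial-least-squares correlation between brain and behavior matrices.

PLS correlation takes an individuals x parcels thickness matrix X and an
individuals x traits behavior matrix Y (both residualized on covariates and
z-scored), forms the cross-covariance R = Y^T X / (n-1) and decomposes it
by SVD.  Each latent component pairs a behavioral salience (left singular
vector) with a brain salience (right singular vector); projecting
individuals onto the saliences yields composite scores whose covariance
the component maximizes.  Component significance comes from permuting
individual labels of Y; salience stability from bootstrap ratios
(original weight / bootstrap SE) with resampled saliences aligned to the
original by orthogonal Procrustes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import CovariateDesign, residualize

__all__ = [
    "PLSResults",
    "PLSInference",
    "PLSCorrelation",
    "prepare_matrices",
    "fit_pls",
    "permutation_pvalues",
    "bootstrap_ratios",
    "network_summary",
]

MIN_N_BOOT = 50  # below this bootstrap SEs are too unstable for ratios


def prepare_matrices(
    brain: pd.DataFrame | np.ndarray,
    behavior: pd.DataFrame | np.ndarray,
    design: CovariateDesign | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize every column on the design, then z-score it.

    With ``design=None`` this is plain column standardization.  Raises if a
    column is constant after residualization (e.g. a behavior column lying
    in the span of the design).
    """

    def prep(M, label):
        M = np.asarray(
            M.drop(columns="id") if isinstance(M, pd.DataFrame) and "id" in M.columns
            else M,
            dtype=float,
        )
        out = np.empty_like(M)
        for j in range(M.shape[1]):
            r = residualize(M[:, j], design)
            sd = r.std(ddof=0)
            if not np.isfinite(sd) or sd < 1e-12:
                raise ValueError(f"{label} column {j} constant after residualization")
            out[:, j] = (r - r.mean()) / sd
        return out

    X = prep(brain, "brain")
    Y = prep(behavior, "behavior")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("brain and behavior row counts differ")
    return X, Y


@dataclass
class PLSResults:
    """Fitted PLS correlation: saliences, singular values, scores."""

    brain_saliences: np.ndarray      # parcels x k
    behavior_saliences: np.ndarray   # traits x k
    singular_values: np.ndarray      # k, nonincreasing
    explained_cov: np.ndarray        # s_i^2 / sum s_j^2
    brain_scores: np.ndarray         # n x k
    behavior_scores: np.ndarray      # n x k
    latent_corr: np.ndarray          # Spearman corr of paired score columns
    inference: "PLSInference | None" = None

    @property
    def k(self) -> int:
        return self.singular_values.size

    def project(self, X_new: np.ndarray, Y_new: np.ndarray):
        """Project a new (prepared) sample onto the trained saliences.

        Returns (brain scores, behavior scores, per-component Spearman
        correlation of the paired scores).
        """
        X_new = np.asarray(X_new, dtype=float)
        Y_new = np.asarray(Y_new, dtype=float)
        if X_new.shape[1] != self.brain_saliences.shape[0]:
            raise ValueError("brain column count does not match the model")
        if Y_new.shape[1] != self.behavior_saliences.shape[0]:
            raise ValueError("behavior column count does not match the model")
        bx = X_new @ self.brain_saliences
        by = Y_new @ self.behavior_saliences
        corr = np.array(
            [stats.spearmanr(bx[:, i], by[:, i]).statistic for i in range(self.k)]
        )
        return bx, by, corr

    def summary(self) -> str:
        lines = ["PLS correlation (brain-behavior)",
                 f"  components: {self.k}"]
        for i in range(self.k):
            pi = ""
            if self.inference is not None:
                pi = f"  perm p = {self.inference.perm_p[i]:.4g}"
            lines.append(
                f"  LC{i + 1}: singular value {self.singular_values[i]:.4f}, "
                f"explained cov {100 * self.explained_cov[i]:.1f}%, "
                f"latent Spearman r = {self.latent_corr[i]:.3f}{pi}"
            )
        return "\n".join(lines)


@dataclass
class PLSInference:
    perm_p: np.ndarray
    bootstrap_ratios: np.ndarray | None
    n_perm: int
    n_boot: int
    seed: int
    meta: dict = field(default_factory=dict)


class PLSCorrelation:
    """PLS-correlation model over prepared matrices X (brain), Y (behavior).

    ``fit()`` returns :class:`PLSResults`; ``permutation_test`` and
    ``bootstrap`` attach inference.  ``family_blocks`` (optional list of
    index arrays) switches resampling/permutation to whole families for
    cohorts of relatives.
    """

    def __init__(self, X, Y, family_blocks=None):
        self.X = np.asarray(X, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("row mismatch between X and Y")
        if self.X.shape[0] < self.Y.shape[1]:
            raise ValueError("need at least as many individuals as traits")
        self.family_blocks = family_blocks

    @staticmethod
    def _svd(X, Y):
        n = X.shape[0]
        R = Y.T @ X / (n - 1)
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        return U, s, Vt.T, R

    def fit(self) -> PLSResults:
        U, s, V, R = self._svd(self.X, self.Y)
        if not s.any():
            warnings.warn("zero cross-covariance: all singular values are 0")
        # deterministic sign: largest-|entry| behavior weight made positive
        for i in range(s.size):
            j = int(np.argmax(np.abs(U[:, i])))
            if U[j, i] < 0:
                U[:, i] = -U[:, i]
                V[:, i] = -V[:, i]
        total = (s**2).sum()
        explained = s**2 / total if total > 0 else np.zeros_like(s)
        bx = self.X @ V
        by = self.Y @ U
        with np.errstate(invalid="ignore"):
            latent = np.array(
                [stats.spearmanr(bx[:, i], by[:, i]).statistic for i in range(s.size)]
            )
        return PLSResults(
            brain_saliences=V,
            behavior_saliences=U,
            singular_values=s,
            explained_cov=explained,
            brain_scores=bx,
            behavior_scores=by,
            latent_corr=latent,
        )

    # -- resampling index helpers ------------------------------------------

    def _permuted_rows(self, rng):
        n = self.X.shape[0]
        if self.family_blocks is None:
            return rng.permutation(n)
        # permute whole families (block order), keeping within-family order
        order = rng.permutation(len(self.family_blocks))
        return np.concatenate([self.family_blocks[i] for i in order])

    def _bootstrap_rows(self, rng):
        n = self.X.shape[0]
        if self.family_blocks is None:
            return rng.integers(0, n, size=n)
        picks = rng.integers(0, len(self.family_blocks), size=len(self.family_blocks))
        return np.concatenate([self.family_blocks[i] for i in picks])[:n]

    # -- inference ----------------------------------------------------------

    def permutation_test(self, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
        """Permutation p-values per component.

        Rows of Y are shuffled jointly; the i-th permuted singular value is
        compared with the i-th observed one (no Procrustes realignment):
        p_i = (1 + #{s_perm_i >= s_obs_i}) / (n_perm + 1).
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        _, s_obs, _, _ = self._svd(self.X, self.Y)
        exceed = np.zeros(s_obs.size)
        for _ in range(n_perm):
            perm = self._permuted_rows(rng)
            _, s_p, _, _ = self._svd(self.X, self.Y[perm])
            exceed += s_p >= s_obs
        return (1.0 + exceed) / (n_perm + 1.0)

    def bootstrap(self, results: PLSResults, n_boot: int = 1000, seed: int = 0):
        """Bootstrap ratios (salience / bootstrap SE) per parcel and component.

        Individuals are resampled with replacement; each resample's
        saliences are rotated onto the original by orthogonal Procrustes
        (computed on the behavior saliences, applied to both sides).
        Parcels with zero bootstrap SE get infinite BSR and should be
        excluded from thresholded sets.
        """
        if n_boot < MIN_N_BOOT:
            raise ValueError(f"n_boot must be >= {MIN_N_BOOT}")
        rng = np.random.default_rng(seed)
        V0 = results.brain_saliences
        U0 = results.behavior_saliences
        acc = np.zeros_like(V0)
        acc2 = np.zeros_like(V0)
        for _ in range(n_boot):
            rows = self._bootstrap_rows(rng)
            Ub, sb, Vb, _ = self._svd(self.X[rows], self.Y[rows])
            # Procrustes: rotate bootstrap saliences onto the original
            M = Ub.T @ U0
            P, _, Qt = np.linalg.svd(M)
            Rrot = P @ Qt
            Vb = Vb @ Rrot
            acc += Vb
            acc2 += Vb**2
        mean = acc / n_boot
        var = acc2 / n_boot - mean**2
        se = np.sqrt(np.clip(var, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = np.where(se > 0, V0 / se, np.sign(V0) * np.inf)
        return bsr


# --------------------------------------------------------------------------
# functional wrappers


def fit_pls(X, Y) -> PLSResults:
    """SVD of the cross-covariance of prepared matrices; k = n_traits."""
    return PLSCorrelation(X, Y).fit()


def permutation_pvalues(X, Y, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    return PLSCorrelation(X, Y).permutation_test(n_perm=n_perm, seed=seed)


def bootstrap_ratios(X, Y, results: PLSResults, n_boot: int = 1000, seed: int = 0):
    return PLSCorrelation(X, Y).bootstrap(results, n_boot=n_boot, seed=seed)


def network_summary(
    bsr, labels: pd.DataFrame | dict, threshold: float = 2.0
) -> pd.DataFrame:
    """Summarize one component's bootstrap ratios by functional network.

    Per network: mean BSR, and the positive/negative contributions — the
    fraction of parcels in the network exceeding +threshold (resp. below
    -threshold), divided by network size and renormalized to sum to 1
    across networks.  Infinite BSRs are excluded from thresholded counts.
    """
    bsr = np.asarray(bsr, dtype=float)
    if isinstance(labels, pd.DataFrame):
        lab = labels["network"].to_numpy()
    else:
        lab = np.asarray([labels[k] for k in sorted(labels)])
    if lab.size != bsr.size:
        raise ValueError("labels do not cover all parcels")
    networks = list(dict.fromkeys(lab))
    rows = []
    for net in networks:
        m = lab == net
        vals = bsr[m]
        finite = vals[np.isfinite(vals)]
        pos = float((finite > threshold).sum()) / m.sum()
        neg = float((finite < -threshold).sum()) / m.sum()
        rows.append(
            {"network": net, "mean_bsr": float(np.mean(finite)) if finite.size else 0.0,
             "pos_raw": pos, "neg_raw": neg, "size": int(m.sum())}
        )
    out = pd.DataFrame(rows)
    for col, new in (("pos_raw", "positive_contribution"),
                     ("neg_raw", "negative_contribution")):
        tot = out[col].sum()
        out[new] = out[col] / tot if tot > 0 else 0.0
    return out[["network", "size", "mean_bsr",
                "positive_contribution", "negative_contribution"]]
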