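"""Covariate-adjusted rank correlations with bootstrap CIs and FDR.

"Partial Spearman" here means residualize-then-rank: both variables are
residualized on the covariate design, then ranked (average ranks for ties)
and Pearson-correlated.  Confidence intervals come from a percentile
bootstrap over individuals; parcel-wise maps are corrected with the
Benjamini-Hochberg step-up procedure, one family per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .transforms import CovariateDesign, residualize

__all__ = [
    "AssociationResult",
    "spearman_partial",
    "fdr_bh",
    "parcelwise_association",
    "map_similarity",
]


@dataclass
class AssociationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    q: float = float("nan")


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_partial(
    x,
    y,
    design: CovariateDesign | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """Spearman correlation of covariate-residualized x and y.

    p-value from the t approximation t = r*sqrt((n-2)/(1-r^2)); 95% CI
    from a seeded percentile bootstrap resampling individuals (skipped when
    ``n_boot`` is 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    if design is not None:
        mask &= ~np.isnan(design.matrix).any(axis=1)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"only {n} complete observations; need >= 10")
    if design is not None:
        keep_ids = [design.ids[i] for i in np.nonzero(mask)[0]]
        sub = design.subset(keep_ids)
        xr = residualize(x[mask], sub)
        yr = residualize(y[mask], sub)
    else:
        xr, yr = x[mask], y[mask]
    r = _rank_corr(xr, yr)
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt((n - 2) / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    p = max(min(p, 1.0), np.finfo(float).tiny)

    ci_low = ci_high = float("nan")
    if n_boot:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rx = stats.rankdata(xr[idx], axis=1).astype(float)
        ry = stats.rankdata(yr[idx], axis=1).astype(float)
        rx -= rx.mean(axis=1, keepdims=True)
        ry -= ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
        ok = denom > 0
        boots = np.full(n_boot, np.nan)
        boots[ok] = (rx[ok] * ry[ok]).sum(axis=1) / denom[ok]
        boots = boots[~np.isnan(boots)]
        if boots.size:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return AssociationResult(r=r, ci_low=float(ci_low), ci_high=float(ci_high),
                             p=p, n_used=n)


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: reject all p(i) with i <= max{i : p(i) <= i*q/m}.

    Returns (reject mask, largest rejected p or NaN, BH-adjusted q-values).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("FDR level must be in (0, 1)")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    thresh = float(p[reject].max()) if reject.any() else float("nan")
    return reject, thresh, qvals


def parcelwise_association(
    brain: pd.DataFrame,
    y,
    design: CovariateDesign | None = None,
    q: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Partial Spearman of every parcel column against y, BH-corrected.

    ``brain`` is an id x parcel table (an ``id`` column is ignored for the
    math but preserved in alignment; rows must already align with y and the
    design).  Returns one row per parcel: parcel,r,ci_low,ci_high,p,q,n,
    significant.
    """
    parcels = [c for c in brain.columns if c != "id"]
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(parcels))
    for k, col in enumerate(parcels):
        res = spearman_partial(
            brain[col].to_numpy(dtype=float), y, design,
            n_boot=n_boot, seed=int(child_seeds[k] % (2**31)),
        )
        rows.append(
            {"parcel": col, "r": res.r, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p": res.p, "n": res.n_used}
        )
    out = pd.DataFrame(rows)
    reject, _, qvals = fdr_bh(out["p"].to_numpy(), q=q)
    out["q"] = qvals
    out["significant"] = reject
    return out


def map_similarity(map_a, map_b) -> float:
    """Spearman correlation of two parcel-wise maps (same parcel order)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parcel maps differ in length")
    if a.size < 10:
        raise ValueError("need at least 10 parcels")
    return _rank_corr(a, b)
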