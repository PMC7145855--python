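"""Deterministic trait preprocessing.

Rank-based inverse normal transformation (Blom plotting positions), trimmed
means for parcel summaries, BMI, and the fixed-effects covariate design
(age, sex, age x sex, age^2, age^2 x sex, plus optional extras such as
global thickness) used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CovariateDesign",
    "inverse_normal_transform",
    "trimmed_mean",
    "compute_bmi",
    "covariate_design",
    "residualize",
]


def inverse_normal_transform(values) -> np.ndarray:
    """Map values to normal quantiles of Blom plotting positions.

    Uses rank-based positions (r - 3/8) / (n + 1/4) with average ranks for
    ties; NaNs are ignored for ranking and stay NaN in the output.  Requires
    at least 3 non-missing values and a non-constant vector.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("inverse normal transform needs >= 3 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("constant vector: ranks carry no information")
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def trimmed_mean(values, trim: float = 0.10) -> float:
    """Mean after dropping floor(trim*n) values from each tail."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("trimmed_mean of empty vector")
    if not 0 <= trim < 0.5:
        raise ValueError("trim fraction must be in [0, 0.5)")
    k = int(np.floor(trim * x.size))
    if k:
        x = np.sort(x)[k:-k]
    return float(x.mean())


def compute_bmi(weight: float, height: float, units: str = "metric") -> float:
    """Body-mass index: kg/m^2 (metric) or 703*lb/in^2 (imperial)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    if units == "metric":
        return weight / height**2
    if units == "imperial":
        return 703.0 * weight / height**2
    raise ValueError(f"unknown units {units!r}")


@dataclass
class CovariateDesign:
    """Fixed-effects design matrix with named columns, intercept first."""

    ids: list
    columns: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape != (len(self.ids), len(self.columns)):
            raise ValueError("design shape does not match ids/columns")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.columns)

    def subset(self, ids) -> "CovariateDesign":
        pos = {j: i for i, j in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return CovariateDesign(list(ids), self.columns, self.matrix[idx])

    @classmethod
    def intercept_only(cls, ids) -> "CovariateDesign":
        return cls(list(ids), ["intercept"], np.ones((len(ids), 1)))


def covariate_design(ids, age, sex, extras: dict | None = None) -> CovariateDesign:
    """Standard covariate scheme: [1, age, sex, age*sex, age^2, age^2*sex].

    ``extras`` (e.g. global thickness, BMI, IQ, depression) are appended in
    insertion order.  Sex must be coded {0,1}.
    """
    ids = list(ids)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if len(age) != len(ids) or len(sex) != len(ids):
        raise ValueError("age/sex length mismatch with ids")
    valid = sex[~np.isnan(sex)]
    if not np.isin(valid, (0.0, 1.0)).all():
        raise ValueError("sex must be coded 0/1")
    cols = {
        "intercept": np.ones(len(ids)),
        "age": age,
        "sex": sex,
        "age_x_sex": age * sex,
        "age2": age**2,
        "age2_x_sex": age**2 * sex,
    }
    for name, vec in (extras or {}).items():
        vec = np.asarray(vec, dtype=float)
        if len(vec) != len(ids):
            raise ValueError(f"extra covariate {name!r} length mismatch")
        cols[name] = vec
    return CovariateDesign(ids, list(cols), np.column_stack(list(cols.values())))


def residualize(values, design: CovariateDesign | None) -> np.ndarray:
    """Least-squares residuals of ``values`` on the design columns.

    ``design=None`` returns the values unchanged (no adjustment).  The design
    must be full column rank; residuals are orthogonal to every column.
    Rows with missing values in ``values`` propagate NaN and are excluded
    from the fit.
    """
    y = np.asarray(values, dtype=float)
    if design is None:
        return y.copy()
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("values length does not match design")
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if mask.sum() <= X.shape[1]:
        raise ValueError("not enough observations to residualize")
    rank = np.linalg.matrix_rank(X[mask])
    if rank < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
    out = np.full_like(y, np.nan)
    out[mask] = y[mask] - X[mask] @ beta
    return out
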