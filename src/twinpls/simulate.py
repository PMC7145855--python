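"""Synthetic twin cohorts with known generative genetics.

Generates extended-twin pedigrees (MZ pairs, DZ pairs, singletons) and
multivariate traits following the polygenic model exactly: each trait is
covariate effects + g + e, where across individuals the genetic vector g
has covariance h2*sigma^2*K (K the expected relatedness matrix) and across
traits correlation rho_g; the environmental part e is family-independent
with cross-trait correlation rho_e.  A parcel matrix with planted low-rank
brain-behavior covariance exercises the PLS stage.  Everything is driven by
one seed and is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelatednessMatrix, build_pedigree, expected_relatedness
from .varcomp import implied_phenotypic_correlation

__all__ = ["TraitSpec", "PlantedComponent", "CohortSpec", "simulate_cohort",
           "simulate_parcel_data", "default_cohort_spec"]


@dataclass
class TraitSpec:
    name: str
    h2: float
    mean: float = 0.0
    variance: float = 1.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_age_sex: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 out of [0,1] for trait {self.name}")
        if self.variance <= 0:
            raise ValueError(f"nonpositive variance for trait {self.name}")


@dataclass
class PlantedComponent:
    """One low-rank brain-behavior component planted into the parcel matrix.

    The individual score is a unit-variance mix of the (standardized)
    behavioral traits weighted by ``behavior_loading``, optionally blended
    with a heritable latent trait of heritability ``score_h2``; the parcel
    pattern is ``strength * score * brain_loading^T``.
    """

    brain_loading: np.ndarray
    behavior_loading: np.ndarray
    strength: float = 1.0
    score_h2: float = 0.0

    def __post_init__(self):
        self.brain_loading = np.asarray(self.brain_loading, dtype=float)
        self.behavior_loading = np.asarray(self.behavior_loading, dtype=float)
        nb = np.linalg.norm(self.brain_loading)
        if nb > 0:
            self.brain_loading = self.brain_loading / nb
        nv = np.linalg.norm(self.behavior_loading)
        if nv > 0:
            self.behavior_loading = self.behavior_loading / nv
        if self.strength < 0:
            raise ValueError("component strength must be >= 0")


# default trait set mirrors the five analyzed phenotypes with heritabilities
# at the HCP twin-sample point estimates
DEFAULT_TRAITS = (
    TraitSpec("sleep_duration", h2=0.24, mean=6.8, variance=1.2**2),
    TraitSpec("psqi_total", h2=0.12, mean=4.8, variance=2.8**2),
    TraitSpec("bmi", h2=0.68, mean=26.5, variance=5.2**2),
    TraitSpec("iq", h2=0.66, mean=121.8, variance=14.6**2),
    TraitSpec("depression", h2=0.24, mean=53.9, variance=5.7**2),
)


@dataclass
class CohortSpec:
    """Generative description of a synthetic twin cohort."""

    n_mz_pairs: int = 143
    n_dz_pairs: int = 85
    n_singletons: int = 650
    traits: tuple = DEFAULT_TRAITS
    rho_g: np.ndarray | None = None   # trait x trait genetic correlations
    rho_e: np.ndarray | None = None   # trait x trait environmental correlations
    age_range: tuple = (22.0, 37.0)
    n_parcels: int = 200
    planted_components: list = field(default_factory=list)
    parcel_noise_sd: float = 1.0

    def __post_init__(self):
        t = len(self.traits)
        if self.rho_g is None:
            self.rho_g = np.eye(t)
        if self.rho_e is None:
            self.rho_e = np.eye(t)
        self.rho_g = np.asarray(self.rho_g, dtype=float)
        self.rho_e = np.asarray(self.rho_e, dtype=float)
        for name, M in (("rho_g", self.rho_g), ("rho_e", self.rho_e)):
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 1.0):
                raise ValueError(f"{name} must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(M).min() < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def implied_phenotypic_corr(self, i: int, j: int) -> float:
        """Closed-form phenotypic correlation of traits i, j (after
        covariate effects), per the bivariate decomposition."""
        return implied_phenotypic_correlation(
            self.traits[i].h2, self.traits[j].h2,
            self.rho_g[i, j], self.rho_e[i, j],
        )


def default_cohort_spec(**overrides) -> CohortSpec:
    """HCP-scale default: 143 MZ pairs, 85 DZ pairs, 650 singletons."""
    return CohortSpec(**overrides)


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = M for PSD (possibly singular) M."""
    w, U = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _build_pedigree_frame(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    fam = 0
    for z, npairs in (("MZ", spec.n_mz_pairs), ("DZ", spec.n_dz_pairs)):
        for p in range(npairs):
            fam += 1
            pid = f"{z}{p + 1:04d}"
            for k in (1, 2):
                rows.append(
                    {"id": f"{pid}_{k}", "family_id": f"F{fam:05d}",
                     "pair_id": pid, "zygosity": z}
                )
    for s in range(spec.n_singletons):
        fam += 1
        rows.append(
            {"id": f"S{s + 1:05d}", "family_id": f"F{fam:05d}",
             "pair_id": "", "zygosity": "NONE"}
        )
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec, seed: int) -> tuple[Pedigree, pd.DataFrame]:
    """Draw one cohort: pedigree plus a phenotype table.

    Genetic draws use the exact Kronecker construction per family block:
    z ~ N(0, I), g = (Lg_traits (x) L_Kb) z, where Lg_traits factors the
    trait-level genetic covariance and L_Kb the block's relatedness.
    Returns (Pedigree, DataFrame with id, sex, age and one trait column
    each); ages uniform over ``age_range``, sex Bernoulli(1/2).
    """
    rng = np.random.default_rng(seed)
    frame = _build_pedigree_frame(spec)
    n = len(frame)
    t = len(spec.traits)
    frame["sex"] = rng.integers(0, 2, size=n)
    frame["age"] = rng.uniform(*spec.age_range, size=n)
    pedigree = build_pedigree(frame)
    K = expected_relatedness(pedigree)

    sd_g = np.array([np.sqrt(tr.h2 * tr.variance) for tr in spec.traits])
    sd_e = np.array([np.sqrt((1 - tr.h2) * tr.variance) for tr in spec.traits])
    Gtr = spec.rho_g * np.outer(sd_g, sd_g)
    Etr = spec.rho_e * np.outer(sd_e, sd_e)
    Lg = _psd_factor(Gtr)
    Le = _psd_factor(Etr)

    G = np.zeros((n, t))
    for idx in K.blocks:
        m = idx.size
        if m == 1:
            Lk = np.ones((1, 1))
        else:
            Lk = _psd_factor(K.values[np.ix_(idx, idx)])
        z = rng.standard_normal((m, t))
        # cov over (individuals x traits): K_b (x) G_traits
        G[idx] = Lk @ z @ Lg.T
    E = rng.standard_normal((n, t)) @ Le.T

    age = frame["age"].to_numpy()
    sex = frame["sex"].to_numpy().astype(float)
    data = {"id": frame["id"], "sex": frame["sex"], "age": frame["age"]}
    for j, tr in enumerate(spec.traits):
        fixed = (
            tr.mean
            + tr.beta_age * age
            + tr.beta_sex * sex
            + tr.beta_age_sex * age * sex
        )
        data[tr.name] = fixed + G[:, j] + E[:, j]
    return pedigree, pd.DataFrame(data)


def simulate_parcel_data(
    spec: CohortSpec, cohort: pd.DataFrame, seed: int,
    relatedness: RelatednessMatrix | None = None,
) -> pd.DataFrame:
    """Parcel matrix = sum of planted rank-one components + iid noise.

    Each component's score is the standardized behavioral mix; when
    ``score_h2`` > 0 and the relatedness matrix is supplied, a heritable
    latent with that heritability is blended in (weights chosen so the
    score keeps unit variance).  Column names are parcel_001..parcel_P.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    P = spec.n_parcels
    M = rng.standard_normal((n, P)) * spec.parcel_noise_sd
    Y = cohort[spec.trait_names].to_numpy(dtype=float)
    Yz = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=0)
    for comp in spec.planted_components:
        if comp.brain_loading.size != P:
            raise ValueError("brain loading length does not match n_parcels")
        if comp.behavior_loading.size != Y.shape[1]:
            raise ValueError("behavior loading length does not match traits")
        score = Yz @ comp.behavior_loading
        sd = score.std(ddof=0)
        if sd > 0:
            score = score / sd
        if comp.score_h2 > 0:
            if relatedness is None:
                relatedness = expected_relatedness(
                    build_pedigree(cohort[["id"]].assign(
                        family_id=cohort["id"], zygosity="NONE", pair_id=""))
                )
            lat = np.empty(n)
            for idx in relatedness.blocks:
                m = idx.size
                Lk = (np.ones((1, 1)) if m == 1
                      else _psd_factor(relatedness.values[np.ix_(idx, idx)]))
                g = Lk @ rng.standard_normal(m)
                lat[idx] = (np.sqrt(comp.score_h2) * g
                            + np.sqrt(1 - comp.score_h2) * rng.standard_normal(m))
            score = (score + lat) / np.sqrt(2.0)
        M += comp.strength * np.outer(score, comp.brain_loading)
    cols = [f"parcel_{k + 1:03d}" for k in range(P)]
    out = pd.DataFrame(M, columns=cols)
    out.insert(0, "id", cohort["id"].to_numpy())
    return out


def default_network_labels(n_parcels: int = 200) -> pd.DataFrame:
    """Cycle the seven canonical functional networks over parcels."""
    networks = ["visual", "sensorimotor", "dorsal-attention",
                "ventral-attention", "limbic", "frontoparietal", "default"]
    labels = [networks[k % 7] for k in range(n_parcels)]
    return pd.DataFrame(
        {"parcel": [f"parcel_{k + 1:03d}" for k in range(n_parcels)],
         "network": labels}
    )
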