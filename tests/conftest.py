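import numpy as np
import pandas as pd
import pytest

from twinpls import (
    CohortSpec,
    TraitSpec,
    build_pedigree,
    covariate_design,
    expected_relatedness,
    simulate_cohort,
)


def make_pedigree_frame(n_mz=2, n_dz=2, n_sing=2, n_sib_fams=0, sib_size=3):
    """Small deterministic pedigree table for structural tests."""
    rows, fam = [], 0
    for z, npairs in (("MZ", n_mz), ("DZ", n_dz)):
        for p in range(npairs):
            fam += 1
            pid = f"{z}{p}"
            for k in (1, 2):
                rows.append({"id": f"{pid}_{k}", "family_id": f"F{fam}",
                             "pair_id": pid, "zygosity": z})
    for f in range(n_sib_fams):
        fam += 1
        for k in range(sib_size):
            rows.append({"id": f"SIB{f}_{k}", "family_id": f"F{fam}",
                         "pair_id": f"sib{f}", "zygosity": "SIB"})
    for s in range(n_sing):
        fam += 1
        rows.append({"id": f"S{s}", "family_id": f"F{fam}",
                     "pair_id": "", "zygosity": "NONE"})
    df = pd.DataFrame(rows)
    df["sex"] = np.arange(len(df)) % 2
    df["age"] = 25.0 + np.arange(len(df)) % 10
    return df


def random_pedigree_frame(rng, max_n=50):
    """Random mix of MZ/DZ pairs, sib families and singletons, <= max_n ids."""
    rows, fam, n = [], 0, 0
    while n < max_n - 3:
        kind = rng.choice(["MZ", "DZ", "SIB", "NONE"])
        fam += 1
        if kind == "NONE":
            rows.append({"id": f"i{n}", "family_id": f"F{fam}",
                         "pair_id": "", "zygosity": "NONE"})
            n += 1
        else:
            size = 2 if kind in ("MZ", "DZ") else int(rng.integers(2, 5))
            for k in range(size):
                rows.append({"id": f"i{n}", "family_id": f"F{fam}",
                             "pair_id": f"p{fam}", "zygosity": kind})
                n += 1
    df = pd.DataFrame(rows)
    df["sex"] = rng.integers(0, 2, len(df))
    df["age"] = rng.uniform(20, 40, len(df))
    return df


def twin_cohort(h2, n_mz=143, n_dz=85, n_sing=650, seed=0, name="t"):
    """Simulated single-trait cohort plus its kinship and covariate design."""
    spec = CohortSpec(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, n_singletons=n_sing,
        traits=(TraitSpec(name, h2=h2),),
    )
    ped, pheno = simulate_cohort(spec, seed=seed)
    K = expected_relatedness(ped)
    design = covariate_design(pheno["id"], pheno["age"], pheno["sex"])
    return K, design, pheno[name].to_numpy()


@pytest.fixture
def small_pedigree():
    return build_pedigree(make_pedigree_frame())
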