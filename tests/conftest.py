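import numpy as np
import pandas as pd
import pytest

import hcngp
from hcngp.snp_qc import impute_and_center


@pytest.fixture(scope="session")
def small_sim():
    """A small family-structured dataset shared across test modules."""
    cfg = hcngp.SimConfig(n_founders=20, n_families=10, family_size=8,
                          n_markers=400, seed=7)
    geno, truth, pheno = hcngp.simulate_dataset(cfg)
    return {"cfg": cfg, "geno": geno, "truth": truth, "pheno": pheno}


@pytest.fixture(scope="session")
def hwe_panel():
    """Unrelated clones in Hardy-Weinberg equilibrium (no families)."""
    rng = np.random.default_rng(42)
    n, m = 200, 3000
    p = rng.uniform(0.1, 0.5, m)
    X = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = [f"u{i}" for i in range(n)]
    return hcngp.GenotypeTable(ids, [f"m{j}" for j in range(m)], X)


@pytest.fixture(scope="session")
def ridge_instance():
    """Moderate genotype/phenotype instance for model-equivalence checks."""
    rng = np.random.default_rng(5)
    n, m = 100, 500
    X = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    ids = [f"c{i}" for i in range(n)]
    geno = hcngp.GenotypeTable(ids, [f"m{j}" for j in range(m)], X)
    cg = impute_and_center(geno)
    b = rng.normal(0, 0.08, m)
    g = cg.Z @ b
    y = pd.Series(g + rng.normal(0, g.std(), n), index=ids)
    G = hcngp.vanraden_grm(cg.Z, cg.p, cg.clone_ids)
    return {"geno": geno, "cg": cg, "y": y, "g": g, "G": G}
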