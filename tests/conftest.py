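import numpy as np
import pandas as pd
import pytest

from florastage import CountMatrix, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small but full simulated study (6 stages, planted truth)."""
    config = SimulationConfig(
        n_genes=600,
        family_catalog={"DUF1216": 15, "F-box": 40, "PPR": 30},
        seed=7,
    )
    annotation, truth, counts, evidence = simulate_all(config)
    return config, annotation, truth, counts, evidence


@pytest.fixture
def tiny_counts():
    """Hand-sized count matrix with explicit library sizes."""
    counts = pd.DataFrame(
        {
            "IM": [10, 0, 9, 100],
            "F1-9": [5, 3, 40, 100],
            "F12": [0, 50, 12, 100],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    libs = pd.Series({"IM": 10**6, "F1-9": 10**6, "F12": 2 * 10**6})
    return CountMatrix(counts=counts, library_sizes=libs)


@pytest.fixture
def tiny_annotation():
    return pd.DataFrame(
        {
            "length_bp": [1000, 2000, 500, 1500],
            "chromosome": ["Chr1"] * 4,
            "start": [1, 3001, 6001, 8001],
            "end": [1000, 5000, 6500, 9500],
            "gene_type": ["coding", "coding", "transposon", "coding"],
            "families": ["FamA", "FamA;FamB", "", "FamB"],
            "tf_family": ["", "MADS", "", ""],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


def hypergeom_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher P: enumerate every table with the observed
    margins, sum the probabilities of those no more likely than observed.

    Probabilities come straight from the hypergeometric mass written with
    binomial coefficients — independent of scipy.
    """
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
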