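import numpy as np
import pandas as pd
import pytest

from sexdim import synthetic_data as sd
from sexdim.data import CountStudy


@pytest.fixture(scope="session")
def small_panel():
    return sd.generate_founder_panel(n_haplotypes=189, n_loci=70, seed=1)


@pytest.fixture(scope="session")
def default_truth():
    return sd.make_truth(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def default_study(default_truth):
    design = sd.standard_design(n_replicates=6)
    return sd.generate_count_study(default_truth, design, seed=12)


@pytest.fixture()
def toy_study():
    """Tiny 3-gene whole-body-only study for I/O round trips."""
    design = pd.DataFrame(
        {
            "sex": ["F", "F", "M", "M"],
            "group": ["ancestral", "evolved", "ancestral", "evolved"],
            "tissue": ["whole"] * 4,
            "replicate": ["r1"] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    counts = pd.DataFrame(
        np.array([[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 2, 3]], dtype=float),
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
        columns=design.index,
    )
    return CountStudy(counts, design)


def make_null_de_study(seed: int, n_genes: int = 2000, reps: int = 6, dispersion: float = 0.05):
    """Four-group study with no group effect and a common NB dispersion."""
    rng = np.random.default_rng(seed)
    rows = []
    for grp in ("ancestral", "evolved"):
        for sex in ("F", "M"):
            for r in range(reps):
                rows.append(
                    {
                        "sample": f"{grp}_{sex}_{r}",
                        "sex": sex,
                        "group": grp,
                        "tissue": "whole",
                        "replicate": f"r{r}",
                    }
                )
    design = pd.DataFrame(rows).set_index("sample")
    base = np.exp(rng.normal(np.log(100.0), 1.0, n_genes))
    mu = np.tile(base[:, None], (1, len(design)))
    r_nb = 1.0 / dispersion
    y = rng.negative_binomial(r_nb, r_nb / (r_nb + mu)).astype(float)
    counts = pd.DataFrame(
        y, index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"), columns=design.index
    )
    return CountStudy(counts, design)
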