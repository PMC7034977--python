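"""Synthetic founder panels and expression studies with known ground truth.

Two generators live here.  :func:`generate_founder_panel` produces a panel of
binary haplotypes over segregating biallelic loci, emulating the founder
lines of an evolve-and-resequence experiment; it seeds the forward simulator.
:func:`generate_count_study` draws negative-binomial RNA-seq counts for
whole-body, gonad and carcass samples whose expectations obey the tissue
mixing model

    mean_wholebody = alpha * mean_gonad + (1 - alpha) * mean_carcass

with group-specific mixing coefficients alpha, sex-biased baselines and
evolved log2 fold changes, so that the allometric-correction and
differential-expression stages can be validated against programmed truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexdim.data import GROUPS, SEXES, CountStudy

_MAX_REDRAWS = 1000


@dataclass
class HaplotypePanel:
    """Founder haplotypes over segregating biallelic loci.

    ``matrix`` is n_haplotypes x n_loci with entries in {0, 1}; every locus
    segregates (0 < column sum < n_haplotypes).
    """

    matrix: np.ndarray
    locus_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0/1")
        counts = self.matrix.sum(axis=0)
        bad = np.flatnonzero((counts == 0) | (counts == self.n_haplotypes))
        if bad.size:
            raise ValueError(f"non-segregating loci at columns {bad.tolist()}")
        if len(self.locus_ids) != self.n_loci:
            raise ValueError("locus_ids length does not match matrix")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[1]

    @property
    def allele_frequencies(self) -> np.ndarray:
        """Derived-allele frequency per locus (column mean of the matrix)."""
        return self.matrix.mean(axis=0)

    def sample_diploids(self, n_individuals: int, rng: np.random.Generator) -> np.ndarray:
        """n_individuals x n_loci dosage matrix from random haplotype pairs."""
        idx = rng.integers(0, self.n_haplotypes, size=(n_individuals, 2))
        return (self.matrix[idx[:, 0]] + self.matrix[idx[:, 1]]).astype(np.int8)


def neutral_sfs_counts(rng: np.random.Generator, n_loci: int, n_haplotypes: int) -> np.ndarray:
    """Panel allele counts in {1, ..., n-1} weighted proportional to 1/count.

    This is the expected neutral site-frequency spectrum shape, which puts
    most mass on rare variants as in natural founder panels.
    """
    counts = np.arange(1, n_haplotypes)
    w = 1.0 / counts
    return rng.choice(counts, size=n_loci, p=w / w.sum())


def generate_founder_panel(
    n_haplotypes: int = 189,
    n_loci: int = 70,
    maf_model="neutral_sfs",
    seed: int = 0,
) -> HaplotypePanel:
    """Generate a panel of segregating haplotypes.

    Parameters
    ----------
    maf_model
        ``"neutral_sfs"`` (default) draws panel allele counts proportional to
        1/count and places exactly that many derived alleles per locus, so
        every locus segregates by construction.  Alternatively a callable
        ``f(rng, n) -> frequencies in (0, 1)`` may be given; per-haplotype
        alleles are then Bernoulli draws and loci fixed by sampling are
        redrawn (bounded attempts).
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if n_loci < 1:
        raise ValueError("need at least 1 locus")
    rng = np.random.default_rng(seed)
    H = np.zeros((n_haplotypes, n_loci), dtype=np.int8)
    if maf_model == "neutral_sfs" or maf_model is None:
        counts = neutral_sfs_counts(rng, n_loci, n_haplotypes)
        for j, c in enumerate(counts):
            H[rng.choice(n_haplotypes, size=c, replace=False), j] = 1
    elif callable(maf_model):
        for j in range(n_loci):
            for attempt in range(_MAX_REDRAWS + 1):
                p = float(np.asarray(maf_model(rng, 1)).ravel()[0])
                if not 0.0 < p < 1.0:
                    raise ValueError(f"maf_model produced frequency {p} outside (0,1)")
                col = (rng.random(n_haplotypes) < p).astype(np.int8)
                if 0 < col.sum() < n_haplotypes:
                    H[:, j] = col
                    break
            else:
                raise RuntimeError(
                    f"locus {j}: could not obtain a segregating locus in "
                    f"{_MAX_REDRAWS} redraws; maf_model may be degenerate"
                )
    else:
        raise ValueError(f"unknown maf_model: {maf_model!r}")
    ids = [f"L{j:05d}" for j in range(n_loci)]
    return HaplotypePanel(H, ids, seed=seed)


# ---------------------------------------------------------------------------
# expression truth + count study generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticExpressionTruth:
    """Programmed ground truth behind a synthetic count study.

    All per-gene tables are DataFrames indexed by gene id.

    baseline
        Ancestral mean expression on the CPM scale, columns ``{sex}_{tissue}``
        for tissue in {gonad, carcass}.
    alpha
        Mixing coefficient in [0, 1], columns ``{sex}_{group}``.
    lfc
        Evolved log2 fold change per sex (applied to both dissected tissues),
        columns ``F``, ``M``.
    dispersion
        Per-gene NB dispersion (var = mu + d * mu^2), > 0.
    """

    baseline: pd.DataFrame
    alpha: pd.DataFrame
    lfc: pd.DataFrame
    dispersion: pd.Series
    library_size: float = 1e6
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_sets = {
            "baseline": set(self.baseline.index),
            "alpha": set(self.alpha.index),
            "lfc": set(self.lfc.index),
            "dispersion": set(self.dispersion.index),
        }
        ref = gene_sets["baseline"]
        for name, genes in gene_sets.items():
            if genes != ref:
                offending = sorted((genes ^ ref))[:10]
                raise ValueError(
                    f"gene sets of 'baseline' and '{name}' differ, e.g. {offending}"
                )
        a = self.alpha.to_numpy(float)
        if ((a < 0) | (a > 1)).any():
            raise ValueError("alpha values must lie in [0, 1]")
        if (self.dispersion.to_numpy(float) <= 0).any():
            raise ValueError("dispersions must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.baseline.index

    def mean_cpm(self, sex: str, group: str, tissue: str) -> pd.Series:
        """Programmed mean expression (CPM scale) for one condition.

        Whole-body means satisfy the mixing identity exactly:
        ``alpha * gonad + (1 - alpha) * carcass``.
        """
        fold = 2.0 ** self.lfc[sex] if group == "evolved" else 1.0
        gonad = self.baseline[f"{sex}_gonad"] * fold
        carcass = self.baseline[f"{sex}_carcass"] * fold
        if tissue == "gonad":
            return gonad
        if tissue == "carcass":
            return carcass
        if tissue == "whole":
            a = self.alpha[f"{sex}_{group}"]
            return a * gonad + (1.0 - a) * carcass
        raise ValueError(f"unknown tissue {tissue!r}")

    def to_json(self, path) -> None:
        payload = {
            "baseline": self.baseline.to_dict(orient="index"),
            "alpha": self.alpha.to_dict(orient="index"),
            "lfc": self.lfc.to_dict(orient="index"),
            "dispersion": self.dispersion.to_dict(),
            "library_size": self.library_size,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticExpressionTruth":
        with open(path) as fh:
            payload = json.load(fh)
        baseline = pd.DataFrame.from_dict(payload["baseline"], orient="index")
        baseline.index.name = "gene"
        order = baseline.index
        alpha = pd.DataFrame.from_dict(payload["alpha"], orient="index").loc[order]
        lfc = pd.DataFrame.from_dict(payload["lfc"], orient="index").loc[order]
        alpha.index.name = lfc.index.name = "gene"
        dispersion = pd.Series(payload["dispersion"], name="dispersion").loc[order]
        dispersion.index.name = "gene"
        return cls(
            baseline=baseline,
            alpha=alpha,
            lfc=lfc,
            dispersion=dispersion,
            library_size=payload.get("library_size", 1e6),
            meta=payload.get("meta", {}),
        )


def make_truth(
    n_genes: int = 500,
    seed: int = 0,
    frac_de: float = 0.1,
    lfc_sd: float = 1.0,
    frac_sex_biased: float = 0.3,
    sex_bias_log2_sd: float = 1.5,
    alpha_shift: float = 0.0,
    dispersion_mean: float = 0.05,
    dispersion_log_sd: float = 0.5,
    library_size: float = 1e6,
) -> SyntheticExpressionTruth:
    """Draw a plausible expression truth.

    Baselines are log-normal around ~50 CPM; a fraction of genes carries a
    sex-biased baseline; evolved log2 fold changes are normal with sd
    ``lfc_sd`` on a random ``frac_de`` subset, independently per sex.
    ``alpha_shift`` moves the evolved-group alpha relative to ancestral
    (clipped to [0, 1]) to emulate an evolved change in gonad/carcass
    allometry.  Dispersions are log-normal around ``dispersion_mean``.
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")

    base = np.exp(rng.normal(np.log(50.0), 1.0, size=n_genes))
    bias = np.zeros(n_genes)
    biased = rng.random(n_genes) < frac_sex_biased
    bias[biased] = rng.normal(0.0, sex_bias_log2_sd, size=biased.sum())
    # gonad expression tends to dominate or lag carcass per gene
    gonad_shift = rng.normal(0.0, 1.0, size=n_genes)
    baseline = pd.DataFrame(
        {
            "F_gonad": base * 2.0 ** (bias / 2 + gonad_shift / 2),
            "F_carcass": base * 2.0 ** (bias / 2 - gonad_shift / 2),
            "M_gonad": base * 2.0 ** (-bias / 2 + gonad_shift / 2),
            "M_carcass": base * 2.0 ** (-bias / 2 - gonad_shift / 2),
        },
        index=genes,
    )
    # keep each tissue condition compositionally coherent on the CPM scale
    # (column totals = 1e6) so per-sample CPM recomputation is consistent
    baseline = baseline / baseline.sum(axis=0) * 1e6

    alpha_anc = rng.beta(2.0, 2.0, size=n_genes)
    alpha = pd.DataFrame(
        {
            "F_ancestral": alpha_anc,
            "F_evolved": np.clip(alpha_anc + alpha_shift, 0.0, 1.0),
            "M_ancestral": alpha_anc,
            "M_evolved": np.clip(alpha_anc + alpha_shift, 0.0, 1.0),
        },
        index=genes,
    )

    lfc = pd.DataFrame(0.0, index=genes, columns=list(SEXES))
    for sex in SEXES:
        de = rng.random(n_genes) < frac_de
        lfc.loc[de, sex] = rng.normal(0.0, lfc_sd, size=de.sum())

    dispersion = pd.Series(
        np.exp(rng.normal(np.log(dispersion_mean), dispersion_log_sd, size=n_genes)),
        index=genes,
        name="dispersion",
    )
    return SyntheticExpressionTruth(
        baseline, alpha, lfc, dispersion, library_size=library_size, meta={"seed": seed}
    )


def standard_design(
    n_replicates: int = 6,
    tissues=("whole", "gonad", "carcass"),
    sexes=SEXES,
    groups=GROUPS,
    library_size: float | None = None,
) -> pd.DataFrame:
    """Fully crossed sample design table (sex x group x tissue x replicate)."""
    rows = []
    for sex in sexes:
        for group in groups:
            for tissue in tissues:
                for rep in range(1, n_replicates + 1):
                    name = f"{sex}_{group}_{tissue}_r{rep}"
                    row = {
                        "sample": name,
                        "sex": sex,
                        "group": group,
                        "tissue": tissue,
                        "replicate": f"r{rep}",
                    }
                    if library_size is not None:
                        row["library_size"] = library_size
                    rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def generate_count_study(
    truth: SyntheticExpressionTruth, design: pd.DataFrame, seed: int = 0
) -> CountStudy:
    """Draw NB counts for every designed sample.

    Counts are NB with mean ``library_size * mean_cpm / 1e6`` and the gene's
    programmed dispersion; dispersions below 1e-8 fall back to Poisson.
    """
    rng = np.random.default_rng(seed)
    disp = truth.dispersion.to_numpy(float)
    cols = {}
    for sample, row in design.iterrows():
        lib = float(row.get("library_size", truth.library_size))
        mu = truth.mean_cpm(row["sex"], row["group"], row["tissue"]).to_numpy(float)
        mu = mu / 1e6 * lib
        y = np.empty_like(mu)
        poisson = disp < 1e-8
        if poisson.any():
            y[poisson] = rng.poisson(mu[poisson])
        nb = ~poisson
        if nb.any():
            r = 1.0 / disp[nb]
            p = r / (r + mu[nb])
            y[nb] = rng.negative_binomial(r, p)
        cols[sample] = y
    counts = pd.DataFrame(cols, index=truth.genes)
    keep = [c for c in design.columns if c != "library_size"]
    return CountStudy(counts, design[keep], meta={"seed": seed})
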