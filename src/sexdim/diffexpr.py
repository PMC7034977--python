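"""Differential expression under the four-level group model.

The analysis models counts for each gene as negative binomial with a log
link and the single factor ``group`` = sex x evolution (ancestral females,
ancestral males, evolved females, evolved males):

    Y = group + error,   Y_gj ~ NB(mean = s_j * exp(eta_g,group(j)), disp d_g)

where ``s_j`` is the effective library size (raw library size times its TMM
normalization factor).  Three 1-df likelihood-ratio contrasts are tested per
gene — female evolution, male evolution and sex bias — followed by
Benjamini-Hochberg FDR control at 0.05, and genes are classified into
sex-specific evolutionary categories from the joint significance/sign
pattern of the two evolution contrasts.

TMM (weighted trimmed mean of M-values) and the NB GLM / LRT machinery are
implemented here from their published definitions.  Corrected ancestral
whole-body counts are non-integer; the NB likelihood is evaluated through
its gamma-function form, which extends smoothly to continuous values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from sexdim.data import CountStudy, cpm

GROUP_LEVELS = ("ancestral:F", "ancestral:M", "evolved:F", "evolved:M")

#: 1-df contrast vectors over GROUP_LEVELS; value = log fold change direction
CONTRASTS = {
    "female_evolution": np.array([-1.0, 0.0, 1.0, 0.0]),
    "male_evolution": np.array([0.0, -1.0, 0.0, 1.0]),
    "sex_bias": np.array([0.5, -0.5, 0.5, -0.5]),
    "sex_bias_ancestral": np.array([1.0, -1.0, 0.0, 0.0]),
    "sex_bias_evolved": np.array([0.0, 0.0, 1.0, -1.0]),
}

_ETA_FLOOR = np.log(1e-10)
_DISP_FLOOR = 1e-12
_POISSON_R = 1e10  # NB size above this is evaluated as Poisson


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def cpm_filter(
    counts: pd.DataFrame,
    threshold: float = 0.1,
    library_sizes: pd.Series | None = None,
) -> pd.Index:
    """Genes whose CPM exceeds ``threshold`` in *every* sample.

    Low-count genes carry almost no information for the NB tests and inflate
    the FDR denominator; the conventional cut requires expression above the
    threshold in all samples of the main dataset.
    """
    mat = cpm(counts, library_sizes)
    keep = (mat > threshold).all(axis=1)
    if not keep.any():
        raise ValueError("CPM filter removed every gene")
    return counts.index[keep]


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values normalization factors.

    For each sample against the reference, gene-wise log-ratios
    ``M = log2((y_s/N_s)/(y_r/N_r))`` and average log-intensities ``A`` are
    computed on genes with positive counts in both samples; the upper and
    lower ``trim_m`` of genes by M and ``trim_a`` by A are discarded; the
    factor is 2 to the inverse-variance-weighted mean of the surviving M
    values (weights from the delta-method binomial variance).  Factors are
    rescaled to have geometric mean one, so they multiply to one.

    The default reference is the sample whose 75th CPM percentile is closest
    to the mean of those percentiles.
    """
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        zero = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero total count in samples: {zero}")
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    p75 = np.percentile(y / lib * 1e6, 75, axis=0)
    if reference is None:
        ref_idx = int(np.argmin(np.abs(p75 - p75.mean())))
    else:
        ref_idx = list(counts.columns).index(reference)

    yr = y[:, ref_idx]
    nr = lib[ref_idx]
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        ys, ns = y[:, j], lib[j]
        ok = (ys > 0) & (yr > 0)
        fs, fr = ys[ok] / ns, yr[ok] / nr
        M = np.log2(fs / fr)
        A = 0.5 * np.log2(fs * fr)
        n = M.size
        if n == 0:
            continue
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        w = 1.0 / ((ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        log_factors[j] = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# NB group model
# ---------------------------------------------------------------------------


def _group_labels(design: pd.DataFrame) -> pd.Series:
    return design["group"].astype(str) + ":" + design["sex"].astype(str)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """NB log-likelihood (gamma-function form, valid for continuous y).

    ``r = 1/dispersion``; terms free of mu are kept so likelihoods are
    comparable across nested fits with identical y and r.  Sizes above
    ``_POISSON_R`` are evaluated with the exact Poisson limit, where the
    gamma-function form loses precision.
    """
    mu = np.maximum(mu, 1e-300)
    r_safe = np.minimum(r, _POISSON_R)
    nb = (
        gammaln(y + r_safe)
        - gammaln(r_safe)
        - gammaln(y + 1.0)
        + r_safe * np.log(r_safe / (r_safe + mu))
        + y * np.log(mu / (r_safe + mu))
    )
    pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    return np.where(np.broadcast_to(r, nb.shape) >= _POISSON_R, pois, nb)


def _fit_common_eta(y: np.ndarray, s: np.ndarray, r: np.ndarray, tol=1e-10, maxit=100):
    """Per-gene MLE of a single log-mean eta shared by columns of y.

    y: genes x samples, s: offsets (samples,), r: per-gene NB size.
    Returns (eta, converged).
    """
    tot = y.sum(axis=1)
    eta = np.log(np.maximum(tot, 1e-10) / s.sum())
    zero = tot <= 0
    eta[zero] = _ETA_FLOOR
    conv = zero.copy()
    active = ~zero
    for _ in range(maxit):
        if not active.any():
            break
        mu = np.exp(eta[active])[:, None] * s[None, :]
        ra = r[active][:, None]
        score = (y[active] - mu * (y[active] + ra) / (mu + ra)).sum(axis=1)
        info = (mu * ra / (mu + ra)).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta[active] += step
        done = np.abs(score) < tol * np.maximum(1.0, info)
        idx = np.flatnonzero(active)
        conv[idx[done]] = True
        active[idx[done]] = False
    return eta, conv | ~active


@dataclass
class NBGroupFit:
    """Per-gene NB fit of the four-level group model."""

    genes: pd.Index
    eta: np.ndarray  # genes x 4 group log-means (relative to offsets)
    dispersion: np.ndarray
    loglik: np.ndarray  # per-gene full-model log-likelihood
    converged: np.ndarray
    counts: np.ndarray
    offsets: np.ndarray
    group_index: np.ndarray  # sample -> group level index

    @property
    def group_means(self) -> pd.DataFrame:
        return pd.DataFrame(np.exp(self.eta), index=self.genes, columns=GROUP_LEVELS)


def estimate_dispersion(
    counts: pd.DataFrame,
    offsets: np.ndarray,
    group_index: np.ndarray,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion: method of moments shrunk toward a trend.

    The raw estimator equates the group-model residual variance with
    ``mu + d mu^2`` (degrees-of-freedom corrected); raw values are then
    shrunk 50% (on the log scale) toward a mean-dispersion trend fitted by
    lowess, which stabilizes the gene-wise estimates at few replicates in
    the spirit of empirical-Bayes moderation.
    """
    y = counts.to_numpy(float)
    n = y.shape[1]
    K = len(np.unique(group_index))
    if n - K <= 0:
        raise ValueError("need more samples than groups to estimate dispersion")
    mu = np.empty_like(y)
    for k in np.unique(group_index):
        cols = group_index == k
        b = y[:, cols].sum(axis=1) / offsets[cols].sum()
        mu[:, cols] = b[:, None] * offsets[None, cols]
    mu = np.maximum(mu, 1e-10)
    ss = ((y - mu) ** 2).sum(axis=1) * n / (n - K)
    raw = (ss - mu.sum(axis=1)) / (mu**2).sum(axis=1)
    raw = np.maximum(raw, _DISP_FLOOR)

    mean_expr = np.log10(np.maximum(mu.mean(axis=1), 1e-8))
    informative = raw > _DISP_FLOOR * 10
    if informative.sum() >= 20:
        fit = lowess(np.log10(raw[informative]), mean_expr[informative], frac=0.5)
        trend = np.interp(mean_expr, fit[:, 0], fit[:, 1])
    else:
        trend = np.full_like(mean_expr, np.log10(np.median(raw)))
    log_d = np.where(
        informative,
        (1.0 - shrink) * np.log10(raw) + shrink * trend,
        trend,
    )
    return pd.Series(10.0**log_d, index=counts.index, name="dispersion")


def fit_group_model(
    study: CountStudy,
    factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
    offsets: np.ndarray | None = None,
) -> NBGroupFit:
    """Fit the per-gene NB group model (log link, offset = effective library).

    ``factors`` default to TMM on the study counts; ``dispersion`` may be a
    per-gene Series, a common float, or None to estimate from the data.
    ``offsets`` overrides the effective library sizes directly (one positive
    value per sample).  Requires at least two replicates in each group.
    """
    labels = _group_labels(study.design)
    missing = [g for g in GROUP_LEVELS if (labels == g).sum() < 2]
    if missing:
        raise ValueError(f"need >=2 replicates per group; too few in {missing}")
    if offsets is None:
        if factors is None:
            factors = tmm_factors(study.counts)
        offsets = (study.library_sizes * factors.reindex(study.samples)).to_numpy(float)
    else:
        offsets = np.asarray(offsets, dtype=float)
    group_index = np.array([GROUP_LEVELS.index(g) for g in labels])
    y = study.counts.to_numpy(float)

    if dispersion is None:
        disp = estimate_dispersion(study.counts, offsets, group_index).to_numpy()
    elif np.isscalar(dispersion):
        disp = np.full(y.shape[0], float(dispersion))
    else:
        disp = dispersion.reindex(study.genes).to_numpy(float)
    disp = np.maximum(disp, _DISP_FLOOR)
    r = 1.0 / disp

    G = y.shape[0]
    eta = np.empty((G, 4))
    conv = np.ones(G, dtype=bool)
    ll = np.zeros(G)
    for k in range(4):
        cols = group_index == k
        ek, ck = _fit_common_eta(y[:, cols], offsets[cols], r)
        eta[:, k] = ek
        conv &= ck
        mu = np.exp(ek)[:, None] * offsets[None, cols]
        ll += _nb_loglik(y[:, cols], mu, r[:, None]).sum(axis=1)
    return NBGroupFit(
        genes=study.genes,
        eta=eta,
        dispersion=disp,
        loglik=ll,
        converged=conv,
        counts=y,
        offsets=offsets,
        group_index=group_index,
    )


def _fit_constrained(fit: NBGroupFit, c: np.ndarray, tol=1e-8, maxit=100):
    """Batched MLE of the group model under the linear constraint c'eta = 0.

    The four group log-means are reparametrized as eta = Z theta with Z an
    orthonormal basis of the null space of c'; Fisher scoring with step
    halving is run simultaneously for all genes.
    """
    c = c / np.linalg.norm(c)
    # orthonormal null-space basis via QR of [c | I]
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(4)]))
    Z = q[:, 1:4]

    y, s, gi = fit.counts, fit.offsets, fit.group_index
    r = 1.0 / fit.dispersion
    G = y.shape[0]
    M = np.zeros((4, len(s)))  # group membership indicator
    M[gi, np.arange(len(s))] = 1.0

    eta_init = np.maximum(fit.eta, _ETA_FLOOR)
    theta = eta_init @ Z  # projection onto the constraint surface

    def loglik(theta):
        eta = theta @ Z.T
        mu = np.exp(eta[:, gi]) * s[None, :]
        return _nb_loglik(y, mu, r[:, None]).sum(axis=1)

    ll = loglik(theta)
    converged = np.zeros(G, dtype=bool)
    for _ in range(maxit):
        eta = theta @ Z.T
        mu = np.exp(eta[:, gi]) * s[None, :]
        resid = y - mu * (y + r[:, None]) / (mu + r[:, None])
        u_eta = resid @ M.T  # genes x 4 group scores
        info = (mu * r[:, None] / (mu + r[:, None])) @ M.T  # genes x 4
        grad = u_eta @ Z
        H = np.einsum("ak,ga,al->gkl", Z, info, Z)
        H += 1e-10 * np.eye(3)[None, :, :]
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        step = np.clip(step, -5.0, 5.0)
        # step halving where the likelihood would decrease
        factor = np.ones((G, 1))
        for _h in range(12):
            cand = theta + factor * step
            ll_new = loglik(cand)
            worse = ll_new < ll - 1e-12
            if not worse.any():
                break
            factor[worse] *= 0.5
        theta = theta + factor * step
        ll_prev, ll = ll, loglik(theta)
        converged = np.abs(ll - ll_prev) < tol * (np.abs(ll) + 1.0)
        if converged.all():
            break
    return ll, converged


def contrast_test(fit: NBGroupFit, contrast: str) -> pd.DataFrame:
    """1-df likelihood-ratio test of a named contrast.

    Returns per-gene ``lfc`` (log2), ``lr`` statistic, ``p`` and BH ``q``.
    Genes whose full or constrained fit failed to converge get ``p = NaN``
    and are excluded from the FDR denominator.
    """
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}; have {sorted(CONTRASTS)}")
    c = CONTRASTS[contrast]
    ll0, conv0 = _fit_constrained(fit, c)
    lr = np.maximum(2.0 * (fit.loglik - ll0), 0.0)
    ok = fit.converged & conv0
    p = np.where(ok, stats.chi2.sf(lr, df=1), np.nan)
    lfc = (fit.eta @ c) / np.log(2.0)
    n_failed = int((~ok).sum())
    if n_failed:
        import logging

        logging.getLogger(__name__).warning(
            "%s: %d gene(s) did not converge; excluded from FDR", contrast, n_failed
        )
    return pd.DataFrame(
        {
            "contrast": contrast,
            "lfc": lfc,
            "lr": lr,
            "p": p,
            "q": bh_fdr(pd.Series(p, index=fit.genes)),
        },
        index=fit.genes,
    )


def bh_fdr(pvals: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values; NaN p-values are passed through."""
    p = pd.Series(pvals, dtype=float)
    if ((p.dropna() < 0) | (p.dropna() > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# classification of evolutionary patterns
# ---------------------------------------------------------------------------

CATEGORIES = (
    "concordant_up",
    "concordant_down",
    "male_specific_up",
    "male_specific_down",
    "female_specific_up",
    "female_specific_down",
    "antagonistic_Mup_Fdown",
    "antagonistic_Mdown_Fup",
    "unchanged",
)


def classify_genes(
    female: pd.DataFrame, male: pd.DataFrame, q_threshold: float = 0.05
) -> pd.Series:
    """Sex-specific evolutionary category from the two evolution contrasts.

    Both significant, same sign -> concordant; exactly one significant ->
    that sex's specific category (direction from its LFC sign); both
    significant with opposite signs -> antagonistic; neither -> unchanged.
    Categories are mutually exclusive and exhaustive.
    """
    if not female.index.equals(male.index):
        missing = female.index.symmetric_difference(male.index).tolist()
        raise ValueError(f"contrasts cover different genes, e.g. {missing[:10]}")
    fsig = (female["q"] < q_threshold).fillna(False).to_numpy()
    msig = (male["q"] < q_threshold).fillna(False).to_numpy()
    fup = female["lfc"].to_numpy() > 0
    mup = male["lfc"].to_numpy() > 0

    cat = np.full(len(female), "unchanged", dtype=object)
    cat[fsig & ~msig & fup] = "female_specific_up"
    cat[fsig & ~msig & ~fup] = "female_specific_down"
    cat[msig & ~fsig & mup] = "male_specific_up"
    cat[msig & ~fsig & ~mup] = "male_specific_down"
    both = fsig & msig
    cat[both & fup & mup] = "concordant_up"
    cat[both & ~fup & ~mup] = "concordant_down"
    cat[both & mup & ~fup] = "antagonistic_Mup_Fdown"
    cat[both & ~mup & fup] = "antagonistic_Mdown_Fup"
    return pd.Series(cat, index=female.index, name="category")


SEX_BIAS_CALLS = ("gained", "lost", "reversed", "strengthened", "weakened", "unchanged")


def sex_bias_evolution(
    ancestral: pd.DataFrame, evolved: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-gene change in sex-biased expression between the two groups.

    The sex-bias contrast (females vs males) is evaluated within each group;
    the call lattice compares significance and sign: neither significant ->
    unchanged; only evolved -> gained; only ancestral -> lost; both with
    opposite signs -> reversed; both same sign -> strengthened/weakened by
    the change in |LFC|.  ``direction`` is the sign of the change in the
    female-vs-male LFC (0 when unchanged).
    """
    if not ancestral.index.equals(evolved.index):
        missing = ancestral.index.symmetric_difference(evolved.index).tolist()
        raise ValueError(f"contrasts cover different genes, e.g. {missing[:10]}")
    asig = (ancestral["q"] < q_threshold).fillna(False).to_numpy()
    esig = (evolved["q"] < q_threshold).fillna(False).to_numpy()
    alfc = ancestral["lfc"].to_numpy()
    elfc = evolved["lfc"].to_numpy()

    call = np.full(len(ancestral), "unchanged", dtype=object)
    call[esig & ~asig] = "gained"
    call[asig & ~esig] = "lost"
    both = asig & esig
    opposite = both & (np.sign(alfc) != np.sign(elfc))
    call[opposite] = "reversed"
    same = both & ~opposite
    call[same & (np.abs(elfc) > np.abs(alfc))] = "strengthened"
    call[same & (np.abs(elfc) < np.abs(alfc))] = "weakened"

    direction = np.where(call != "unchanged", np.sign(elfc - alfc), 0.0)
    return pd.DataFrame(
        {"call": call, "direction": direction, "lfc_ancestral": alfc, "lfc_evolved": elfc},
        index=ancestral.index,
    )


def run_de(
    study: CountStudy,
    cpm_threshold: float = 0.1,
    q_threshold: float = 0.05,
    dispersion=None,
) -> dict:
    """Filter, normalize, test the three headline contrasts and classify.

    Operates on whole-body samples of ``study``.  Returns a dict with the
    retained gene index, TMM factors, per-contrast tables (including the
    within-group sex-bias contrasts), the classification and the sex-bias
    evolution calls.
    """
    wb = study.select(tissue="whole")
    kept = cpm_filter(wb.counts, cpm_threshold)
    wb = CountStudy(wb.counts.loc[kept], wb.design, dict(wb.meta))
    factors = tmm_factors(wb.counts)
    fit = fit_group_model(wb, factors=factors, dispersion=dispersion)
    results = {
        name: contrast_test(fit, name)
        for name in (
            "female_evolution",
            "male_evolution",
            "sex_bias",
            "sex_bias_ancestral",
            "sex_bias_evolved",
        )
    }
    classification = classify_genes(
        results["female_evolution"], results["male_evolution"], q_threshold
    )
    bias_evo = sex_bias_evolution(
        results["sex_bias_ancestral"], results["sex_bias_evolved"], q_threshold
    )
    return {
        "genes": kept,
        "factors": factors,
        "fit": fit,
        "contrasts": results,
        "classification": classification,
        "sex_bias_evolution": bias_evo,
    }
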