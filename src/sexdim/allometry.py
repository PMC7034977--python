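"""Gonad/carcass allometric correction of whole-body expression.

Whole-body RNA-seq of an organism whose gonad-to-carcass size ratio evolves
confounds regulatory change with tissue composition.  For gene *i* the mean
whole-body expression is modeled as a linear mixture of its dissected-tissue
means,

    wb_i = alpha_i * gonad_i + (1 - alpha_i) * carcass_i,   alpha_i in [0, 1],

where alpha_i measures the relative gonadal contribution.  Estimating alpha
separately in ancestral and evolved populations exposes evolved allometric
shifts; reconstructing *pseudo* whole-body samples from ancestral dissected
tissues with the evolved alpha, and taking the per-gene ratio to the observed
ancestral whole-body mean, yields multiplicative correction factors gamma
that put ancestral whole-body samples on the evolved tissue scale.

All arithmetic here is on the linear CPM scale: the mixture model is linear,
not logarithmic.  Genes expressed at similar levels in gonad and carcass are
insensitive to tissue scaling and ill-conditioned for estimation; they are
flagged non-correctable and left untouched (gamma = 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from sexdim.data import CountStudy, cpm

logger = logging.getLogger(__name__)

#: default non-correctability rule: |log2 gonad/carcass| below this (with a
#: 0.5-CPM pseudo-count) marks a gene as similarly expressed in both tissues.
SIMILARITY_LOG2 = 0.5
PSEUDO_CPM = 0.5


def estimate_alpha(
    wb_mean,
    gonad_mean,
    carcass_mean,
    similarity_log2: float = SIMILARITY_LOG2,
    pseudo_cpm: float = PSEUDO_CPM,
) -> pd.DataFrame:
    """Per-gene mixing coefficient from condition means.

    Parameters are aligned Series (or scalars) of non-negative means on a
    common linear CPM scale.  Returns a DataFrame with columns ``alpha``
    (NaN where non-correctable), ``correctable``, ``boundary`` (alpha was
    clipped to 0 or 1), and the three input means as diagnostics.
    """
    df = pd.DataFrame(
        {"wb_mean": wb_mean, "gonad_mean": gonad_mean, "carcass_mean": carcass_mean},
        dtype=float,
    )
    if (df.to_numpy() < 0).any():
        raise ValueError("expression means must be non-negative")
    g = df["gonad_mean"].to_numpy()
    c = df["carcass_mean"].to_numpy()
    w = df["wb_mean"].to_numpy()

    ratio = np.log2((g + pseudo_cpm) / (c + pseudo_cpm))
    correctable = (np.abs(ratio) >= similarity_log2) & (g != c)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - c) / (g - c)
    alpha = np.clip(raw, 0.0, 1.0)
    boundary = correctable & ((raw < 0.0) | (raw > 1.0))
    alpha = np.where(correctable, alpha, np.nan)

    return pd.DataFrame(
        {
            "alpha": alpha,
            "correctable": correctable,
            "boundary": boundary,
            "wb_mean": df["wb_mean"],
            "gonad_mean": df["gonad_mean"],
            "carcass_mean": df["carcass_mean"],
        },
        index=df.index,
    )


def _tissue_means(study: CountStudy, sex: str, group: str) -> dict[str, pd.DataFrame]:
    """Per-tissue CPM matrices (genes x replicates) for one sex/group."""
    out = {}
    for tissue in ("whole", "gonad", "carcass"):
        sub = study.select(sex=sex, group=group, tissue=tissue)
        mat = cpm(sub.counts)
        mat.columns = sub.design["replicate"].tolist()
        out[tissue] = mat
    return out


def fit_alpha(
    study: CountStudy,
    sex: str,
    group: str,
    similarity_log2: float = SIMILARITY_LOG2,
) -> pd.DataFrame:
    """Estimate alpha for one sex within one group from replicate-mean CPM."""
    mats = _tissue_means(study, sex, group)
    fit = estimate_alpha(
        mats["whole"].mean(axis=1),
        mats["gonad"].mean(axis=1),
        mats["carcass"].mean(axis=1),
        similarity_log2=similarity_log2,
    )
    fit.insert(0, "group", group)
    fit.insert(0, "sex", sex)
    return fit


def loo_cv(study: CountStudy, sex: str, group: str) -> tuple[pd.DataFrame, float]:
    """Leave-one-replicate-out cross-validation of the mixture model.

    For each replicate label, alpha is estimated from the remaining
    replicates and used with the held-out gonad/carcass values to predict the
    held-out whole-body value.  Returns the per-gene, per-fold table of
    predictions (correctable genes only) and the overall Pearson correlation
    between predicted and observed whole-body expression on the log10 scale
    (0.5-CPM pseudo-count), which weighs genes evenly across the orders of
    magnitude that expression spans.
    """
    mats = _tissue_means(study, sex, group)
    reps = [r for r in mats["whole"].columns]
    common = [r for r in reps if r in mats["gonad"].columns and r in mats["carcass"].columns]
    if len(common) < 3:
        raise ValueError(
            f"leave-one-out needs >=3 shared replicates for sex={sex} group={group}, "
            f"found {len(common)}"
        )
    rows = []
    for held in common:
        rest = [r for r in common if r != held]
        fit = estimate_alpha(
            mats["whole"][rest].mean(axis=1),
            mats["gonad"][rest].mean(axis=1),
            mats["carcass"][rest].mean(axis=1),
        )
        a = fit["alpha"]
        pred = a * mats["gonad"][held] + (1 - a) * mats["carcass"][held]
        obs = mats["whole"][held]
        keep = fit["correctable"]
        rows.append(
            pd.DataFrame(
                {"fold": held, "predicted": pred[keep], "observed": obs[keep]}
            ).rename_axis("gene")
        )
    table = pd.concat(rows).reset_index()
    r = float(
        np.corrcoef(
            np.log10(table["predicted"] + PSEUDO_CPM),
            np.log10(table["observed"] + PSEUDO_CPM),
        )[0, 1]
    )
    return table, r


def compare_alpha_distributions(fit_a: pd.DataFrame, fit_b: pd.DataFrame):
    """Two-sample Kolmogorov-Smirnov comparison of correctable-gene alphas.

    Returns ``(D, p)`` with the exact ECDF-supremum statistic and asymptotic
    p-value.
    """
    a = fit_a.loc[fit_a["correctable"], "alpha"].dropna().to_numpy()
    b = fit_b.loc[fit_b["correctable"], "alpha"].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 correctable genes per group (got {len(a)} and {len(b)})"
        )
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def reconstruct_pseudo_wholebody(
    anc_gonad: pd.DataFrame, anc_carcass: pd.DataFrame, alpha_evo: pd.Series
) -> pd.DataFrame:
    """Pseudo whole-body expression from ancestral dissected samples.

    Columns of the two matrices are replicate labels and must match;
    ``alpha_evo`` is the per-gene alpha estimated from the evolved group.
    Result: ``alpha_evo * gonad + (1 - alpha_evo) * carcass`` per replicate.
    """
    unmatched = set(anc_gonad.columns) ^ set(anc_carcass.columns)
    if unmatched:
        raise ValueError(f"unmatched replicate labels: {sorted(unmatched)}")
    cols = list(anc_gonad.columns)
    a = alpha_evo.reindex(anc_gonad.index)
    return anc_gonad[cols].mul(a, axis=0) + anc_carcass[cols].mul(1.0 - a, axis=0)


def correction_factors(
    pseudo_mean: pd.Series, observed_wb_mean: pd.Series, correctable: pd.Series
) -> pd.DataFrame:
    """Per-gene multiplicative correction factors gamma.

    gamma = pseudo / observed for correctable genes; 1 otherwise.  A
    correctable gene with zero observed whole-body mean has no defined ratio
    and is demoted to non-correctable (gamma = 1) with a logged warning.
    """
    idx = pseudo_mean.index
    observed = observed_wb_mean.reindex(idx)
    correctable = correctable.reindex(idx).fillna(False).astype(bool)
    zero_obs = correctable & ~(observed > 0)
    if zero_obs.any():
        logger.warning(
            "demoting %d correctable gene(s) with zero observed whole-body mean "
            "to gamma=1: %s",
            int(zero_obs.sum()),
            idx[zero_obs][:10].tolist(),
        )
        correctable = correctable & ~zero_obs
    gamma = pd.Series(1.0, index=idx, name="gamma")
    gamma[correctable] = pseudo_mean[correctable] / observed[correctable]
    bad = correctable & ~(gamma > 0)
    if bad.any():  # pseudo mean 0 for a correctable gene
        gamma[bad] = 1.0
        correctable[bad] = False
    return pd.DataFrame({"gamma": gamma, "correctable": correctable})


def apply_correction(
    expression: pd.DataFrame, factors: pd.DataFrame, target_samples=None
) -> pd.DataFrame:
    """Multiply target columns (default: all) by each gene's gamma."""
    corrected = expression.copy()
    cols = list(expression.columns) if target_samples is None else list(target_samples)
    gamma = factors["gamma"].reindex(expression.index).fillna(1.0)
    corrected[cols] = corrected[cols].mul(gamma, axis=0)
    return corrected


def allometric_correction(
    study_main: CountStudy,
    study_dissected: CountStudy,
    similarity_log2: float = SIMILARITY_LOG2,
) -> tuple[CountStudy, dict]:
    """End-to-end correction of ancestral whole-body samples in the main study.

    Alphas are estimated per sex in each group of the dissected study; gamma
    is computed per sex from the evolved alpha plus ancestral dissected and
    whole-body means, and applied to the main study's ancestral whole-body
    counts.  Returns the corrected study and a summary dict (per-sex KS
    comparison of ancestral vs evolved alpha distributions, gamma tables).
    """
    corrected = study_main.counts.copy()
    summary: dict = {}
    for sex in ("F", "M"):
        fit_anc = fit_alpha(study_dissected, sex, "ancestral", similarity_log2)
        fit_evo = fit_alpha(study_dissected, sex, "evolved", similarity_log2)
        D, p = compare_alpha_distributions(fit_anc, fit_evo)
        mats = _tissue_means(study_dissected, sex, "ancestral")
        pseudo = reconstruct_pseudo_wholebody(
            mats["gonad"], mats["carcass"], fit_evo["alpha"]
        )
        both = fit_anc["correctable"] & fit_evo["correctable"]
        factors = correction_factors(
            pseudo.mean(axis=1), mats["whole"].mean(axis=1), both
        )
        target = study_main.design.query(
            "sex == @sex and group == 'ancestral' and tissue == 'whole'"
        ).index
        corrected[list(target)] = apply_correction(
            corrected[list(target)], factors.reindex(corrected.index)
        )
        summary[sex] = {
            "ks_D": D,
            "ks_p": p,
            "n_correctable": int(both.sum()),
            "factors": factors,
            "alpha_ancestral": fit_anc,
            "alpha_evolved": fit_evo,
        }
    return CountStudy(corrected, study_main.design, dict(study_main.meta)), summary
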