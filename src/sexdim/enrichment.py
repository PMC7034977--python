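"""Tissue-signature enrichment and the transcription-factor candidate screen.

Tissue signatures follow the conventional atlas rule: a gene belongs to a
tissue's signature when its expression there is more than ``fold_threshold``
times its whole-body expression (strict inequality).  Enrichment of a query
gene set in each signature (or in TF target sets) uses the two-sided
Fisher's exact test on the 2x2 membership table, with BH FDR across sets.

The TF screen asks three questions of every transcription factor with a
target annotation: (1) are its targets enriched among sex-biased genes,
(2) are they enriched among genes whose sex bias evolved, and (3) did the
TF's own sex bias evolve in a direction compatible with the dominant
direction of its evolving targets?  Candidates pass all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sexdim.diffexpr import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSets:
    """A gene universe plus uniquely labelled subsets of it."""

    universe: set
    sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        for label, genes in self.sets.items():
            genes = set(genes)
            outside = genes - self.universe
            if outside:
                raise ValueError(
                    f"set {label!r} contains genes outside the universe, "
                    f"e.g. {sorted(outside)[:5]}"
                )
            self.sets[label] = genes

    def __len__(self) -> int:
        return len(self.sets)


def tissue_signatures(
    tissue_table: pd.DataFrame,
    fold_threshold: float = 2.0,
    whole_body_column: str = "whole_body",
) -> AnnotationSets:
    """Per-tissue signature sets from a gene x tissue expression table.

    ``gene in signature(t) iff expression(t) > fold_threshold * whole_body``.
    """
    if whole_body_column not in tissue_table.columns:
        raise ValueError(f"tissue table lacks a {whole_body_column!r} column")
    if (tissue_table.to_numpy(float) < 0).any():
        raise ValueError("tissue expression values must be non-negative")
    wb = tissue_table[whole_body_column]
    sets = {}
    for tissue in tissue_table.columns:
        if tissue == whole_body_column:
            continue
        mask = tissue_table[tissue] > fold_threshold * wb
        sets[tissue] = set(tissue_table.index[mask])
    return AnnotationSets(universe=set(tissue_table.index), sets=sets)


def fisher_enrichment(query, sets: AnnotationSets, q_threshold: float = 0.05) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of ``query`` in every set.

    Returns one row per set: the 2x2 table counts (``a`` = in query and set,
    ``b`` = query only, ``c`` = set only, ``d`` = neither), the sample odds
    ratio (Haldane +0.5 correction when any cell is zero, flagged), the
    exact two-sided p (point-probability method) and BH q across sets.
    Degenerate tables (empty query or empty set) are reported with odds
    ratio NaN and p = 1.
    """
    query = set(query)
    outside = query - sets.universe
    if outside:
        raise ValueError(f"query genes outside universe, e.g. {sorted(outside)[:5]}")
    n_universe = len(sets.universe)
    rows = []
    for label, members in sets.sets.items():
        a = len(query & members)
        b = len(query) - a
        c = len(members) - a
        d = n_universe - a - b - c
        if len(query) == 0 or len(members) == 0:
            rows.append(
                {"set": label, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": np.nan, "p": 1.0, "haldane": False}
            )
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = min(a, b, c, d) == 0
        if haldane:
            odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            odds = a * d / (b * c)
        rows.append(
            {"set": label, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "p": p, "haldane": haldane}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"])
    out["significant"] = out["q"] < q_threshold
    return out


def tf_candidate_screen(
    tf_bias_change: pd.Series,
    tf_targets: AnnotationSets,
    sex_biased_genes,
    bias_evolving_direction: pd.Series,
    q_threshold: float = 0.05,
    mode: str = "enrichment",
) -> pd.DataFrame:
    """Three-criteria screen for transcription factors driving sex-bias change.

    Parameters
    ----------
    tf_bias_change
        Per-TF sign of its own sex-bias change (+1 / -1 / 0); every TF in
        ``tf_targets`` must have a call.
    tf_targets
        Target sets per TF over the study's gene universe.
    sex_biased_genes
        Genes with significant sex-biased expression.
    bias_evolving_direction
        Per-gene sign of a significant sex-bias evolution (only genes whose
        bias evolved appear; values +1 / -1).
    mode
        ``"enrichment"`` (default) judges criteria 1-2 by Fisher q <
        ``q_threshold``; ``"overlap"`` by non-empty intersection.

    Returns one row per TF with boolean ``criterion1/2/3`` flags, diagnostics
    and the overall ``candidate`` flag.
    """
    if mode not in ("enrichment", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [tf for tf in tf_targets.sets if tf not in tf_bias_change.index]
    if missing:
        raise ValueError(f"TFs without a sex-bias-evolution call: {missing[:10]}")
    sex_biased = set(sex_biased_genes)
    evolving = set(bias_evolving_direction.index)

    usable = {tf: tg for tf, tg in tf_targets.sets.items() if tg}
    empty = sorted(set(tf_targets.sets) - set(usable))
    if empty:
        logger.info("excluding %d TF(s) with empty target sets: %s", len(empty), empty[:10])
    if not usable:
        return pd.DataFrame(
            columns=["criterion1", "criterion2", "criterion3", "candidate"]
        )
    targets = AnnotationSets(tf_targets.universe, usable)

    if mode == "enrichment":
        enr1 = fisher_enrichment(sex_biased, targets, q_threshold)
        enr2 = fisher_enrichment(evolving, targets, q_threshold)
        crit1 = enr1["significant"]
        crit2 = enr2["significant"]
    else:
        crit1 = pd.Series(
            {tf: len(tg & sex_biased) > 0 for tf, tg in usable.items()}
        )
        crit2 = pd.Series(
            {tf: len(tg & evolving) > 0 for tf, tg in usable.items()}
        )

    rows = []
    for tf, tg in usable.items():
        signs = bias_evolving_direction.reindex(sorted(tg & evolving)).dropna()
        n_up = int((signs > 0).sum())
        n_down = int((signs < 0).sum())
        dominant = np.sign(n_up - n_down)  # 0 on ties: no strict majority
        own = np.sign(tf_bias_change[tf])
        crit3 = bool(dominant != 0 and own == dominant)
        rows.append(
            {
                "tf": tf,
                "n_targets": len(tg),
                "criterion1": bool(crit1[tf]),
                "criterion2": bool(crit2[tf]),
                "criterion3": crit3,
                "own_direction": own,
                "target_direction": dominant,
                "targets_up": n_up,
                "targets_down": n_down,
            }
        )
    out = pd.DataFrame(rows).set_index("tf")
    out["candidate"] = out["criterion1"] & out["criterion2"] & out["criterion3"]
    return out
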