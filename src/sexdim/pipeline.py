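"""End-to-end pipeline orchestration and run configuration.

The pipeline mirrors the study's analysis order: synthetic data (or loaded
counts) -> allometric correction of ancestral whole-body samples -> TMM/NB
differential expression on the corrected counts -> classification ->
optional tissue enrichment.  Every output table carries the config hash and
global seed in its metadata header, so a rerun with the same config
reproduces outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from sexdim import allometry, diffexpr, enrichment, synthetic_data
from sexdim.data import CountStudy, read_count_study, read_table, substream, write_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; see ``RunConfig.from_file`` for file loading."""

    out_dir: str = "sexdim_out"
    seed: int = 0
    # input paths; None -> generate synthetic data
    counts: str | None = None
    design: str | None = None
    dissected_counts: str | None = None
    dissected_design: str | None = None
    tissue_table: str | None = None
    # thresholds
    cpm_threshold: float = 0.1
    fdr_threshold: float = 0.05
    tissue_fold_threshold: float = 2.0
    similarity_log2: float = allometry.SIMILARITY_LOG2
    apply_correction: bool = True
    # synthetic-data block (used when counts is None)
    synth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cpm_threshold", "fdr_threshold", "tissue_fold_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls(**payload)

    @property
    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _meta(config: RunConfig, stage: str) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed, "stage": stage}


def _load_or_generate(config: RunConfig):
    """Return (main_study, dissected_study, truth-or-None)."""
    if config.counts is not None:
        main = read_count_study(config.counts, config.design)
        dissected = None
        if config.dissected_counts is not None:
            dissected = read_count_study(config.dissected_counts, config.dissected_design)
        return main, dissected, None
    synth = dict(config.synth)
    n_replicates = int(synth.pop("n_replicates", 6))
    truth = synthetic_data.make_truth(
        seed=int(substream(config.seed, "truth").integers(2**31)), **synth
    )
    design = synthetic_data.standard_design(n_replicates=n_replicates)
    study = synthetic_data.generate_count_study(
        truth, design, seed=int(substream(config.seed, "counts").integers(2**31))
    )
    main = study.select(tissue="whole")
    dissected = study
    return main, dissected, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write TSV outputs and a run log under ``out_dir``.

    Returns a result bundle with the corrected study, per-contrast tables,
    classification, sex-bias evolution calls and (if a tissue table was
    supplied) enrichment results.  Any stage failure aborts with the stage
    name; partial outputs written so far are listed in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    written: list[str] = []

    def log(msg: str) -> None:
        line = f"{time.strftime('%Y-%m-%d %H:%M:%S')} {msg}"
        log_lines.append(line)
        logger.info(msg)

    def emit(df: pd.DataFrame, name: str, stage: str, index=True) -> None:
        path = out / name
        write_table(df, path, _meta(config, stage), index=index)
        written.append(str(path))

    stage = "load"
    try:
        main, dissected, truth = _load_or_generate(config)
        log(
            f"load: {main.counts.shape[0]} genes, {main.counts.shape[1]} main samples"
            + (f", {dissected.counts.shape[1]} dissected samples" if dissected is not None else "")
        )
        if truth is not None:
            truth.to_json(out / "truth.json")
            written.append(str(out / "truth.json"))

        stage = "allometry"
        summary: dict = {}
        if config.apply_correction and dissected is not None and not dissected.select(
            tissue="gonad"
        ).design.empty:
            corrected, allo = allometry.allometric_correction(
                main, dissected, similarity_log2=config.similarity_log2
            )
            for sex, block in allo.items():
                emit(block["factors"], f"correction_factors_{sex}.tsv", stage)
                emit(block["alpha_ancestral"], f"alpha_ancestral_{sex}.tsv", stage)
                emit(block["alpha_evolved"], f"alpha_evolved_{sex}.tsv", stage)
                summary[f"ks_D_{sex}"] = block["ks_D"]
                summary[f"ks_p_{sex}"] = block["ks_p"]
                summary[f"n_correctable_{sex}"] = block["n_correctable"]
                log(
                    f"allometry[{sex}]: {block['n_correctable']} correctable genes, "
                    f"KS D={block['ks_D']:.4f} p={block['ks_p']:.3g}"
                )
        else:
            corrected = main
            log("allometry: skipped (no dissected data or correction disabled)")

        stage = "diffexpr"
        de = diffexpr.run_de(
            corrected,
            cpm_threshold=config.cpm_threshold,
            q_threshold=config.fdr_threshold,
        )
        log(f"diffexpr: {len(de['genes'])} genes retained by the {config.cpm_threshold}-CPM filter")
        for name, table in de["contrasts"].items():
            emit(table, f"contrast_{name}.tsv", stage)
        emit(de["classification"].to_frame(), "classification.tsv", stage)
        emit(de["sex_bias_evolution"], "sex_bias_evolution.tsv", stage)
        counts_by_cat = de["classification"].value_counts()
        log("diffexpr: classification counts " + json.dumps(counts_by_cat.to_dict()))

        stage = "enrichment"
        enrich_results = None
        if config.tissue_table is not None:
            tissue = read_table(config.tissue_table)
            sigs = enrichment.tissue_signatures(
                tissue.reindex(de["genes"]).dropna(),
                fold_threshold=config.tissue_fold_threshold,
            )
            cls = de["classification"]
            enrich_results = {}
            for category in cls.unique():
                if category == "unchanged":
                    continue
                query = set(cls.index[cls == category]) & sigs.universe
                res = enrichment.fisher_enrichment(query, sigs, config.fdr_threshold)
                enrich_results[category] = res
                emit(res, f"enrichment_{category}.tsv", stage)
            log(f"enrichment: tested {len(enrich_results)} categories x {len(sigs)} tissues")

        stage = "finish"
        with open(out / "run_log.txt", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config.config_hash,
                    "seed": config.seed,
                    "n_genes_retained": int(len(de["genes"])),
                    "classification_counts": counts_by_cat.to_dict(),
                    **summary,
                },
                fh,
                indent=1,
            )
        return {
            "study": corrected,
            "de": de,
            "allometry": summary,
            "enrichment": enrich_results,
            "truth": truth,
            "outputs": written,
        }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{stage}'; partial outputs: {written}"
        ) from exc
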