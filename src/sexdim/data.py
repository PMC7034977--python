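"""Core containers and tabular I/O for count studies.

A :class:`CountStudy` couples a gene x sample count matrix with its sample
design table (sex, evolution group, tissue, replicate).  All tabular I/O is
TSV (optionally gzipped, inferred from the ``.gz`` suffix); tables written by
this package carry a commented ``# key=value`` metadata header.
"""

from __future__ import annotations

import io as _io
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("F", "M")
GROUPS = ("ancestral", "evolved")
TISSUES = ("whole", "gonad", "carcass")

DESIGN_COLUMNS = ("sex", "group", "tissue", "replicate")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one global seed.

    Every module draws randomness through one of these so that a single
    config seed determines the whole pipeline without hidden global state.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


@dataclass
class CountStudy:
    """Gene x sample counts plus the sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample.  Values may be
        non-integer after multiplicative correction.
    design
        DataFrame indexed by sample name with columns ``sex`` (F/M),
        ``group`` (ancestral/evolved), ``tissue`` (whole/gonad/carcass) and
        ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.design.index.duplicated().any():
            dups = self.design.index[self.design.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample names: {dups}")
        missing = [s for s in self.design.index if s not in self.counts.columns]
        if missing:
            raise ValueError(f"design samples absent from counts: {missing}")
        extra = [s for s in self.counts.columns if s not in self.design.index]
        if extra:
            raise ValueError(f"count columns absent from design: {extra}")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise ValueError(f"design table lacks required column '{col}'")
        bad_sex = set(self.design["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
        bad_group = set(self.design["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group levels: {sorted(bad_group)}")
        bad_tissue = set(self.design["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue levels: {sorted(bad_tissue)}")
        # canonical column order = design row order
        self.counts = self.counts.loc[:, list(self.design.index)]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.design.index

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset(self, mask: pd.Series) -> "CountStudy":
        """Sub-study restricted to design rows where ``mask`` is True."""
        samples = self.design.index[mask.loc[self.design.index]]
        return CountStudy(
            self.counts.loc[:, list(samples)], self.design.loc[samples], dict(self.meta)
        )

    def select(self, **levels) -> "CountStudy":
        """Sub-study matching design levels, e.g. ``select(sex="F", tissue="whole")``."""
        mask = pd.Series(True, index=self.design.index)
        for col, val in levels.items():
            vals = (val,) if np.isscalar(val) else tuple(val)
            mask &= self.design[col].isin(vals)
        return self.subset(mask)


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; library size defaults to the column sum."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (np.asarray(library_sizes) <= 0).any():
        zero = library_sizes.index[np.asarray(library_sizes) <= 0].tolist()
        raise ValueError(f"non-positive library sizes for samples: {zero}")
    return counts.div(library_sizes, axis=1) * 1e6


def _metadata_header(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = True) -> None:
    """Write a TSV with a commented ``# key=value`` metadata header."""
    path = str(path)
    buf = _io.StringIO()
    if meta:
        buf.write(_metadata_header(meta))
    df.to_csv(buf, sep="\t", index=index)
    data = buf.getvalue().encode()
    if path.endswith(".gz"):
        import gzip

        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        with open(path, "wb") as fh:
            fh.write(data)


def read_table(path, index_col=0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_count_study(study: CountStudy, counts_path, design_path, meta: dict | None = None) -> None:
    meta = {**study.meta, **(meta or {})}
    write_table(study.counts, counts_path, meta)
    write_table(study.design, design_path, meta)


def read_count_study(counts_path, design_path) -> CountStudy:
    """Load and validate a study from counts and design TSVs.

    The first column of the counts TSV is the gene id; design rows must match
    count columns one-to-one (validated by :class:`CountStudy`).
    """
    counts = read_table(counts_path)
    design = read_table(design_path)
    counts.columns.name = design.index.name
    return CountStudy(counts, design)
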