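"""Reading, validation and normalization of count-based expression data.

The analysis starts from a matrix of deduplicated, uniquely aligned read
counts (genes as rows, samples as columns) plus a sample metadata table
mapping each sample to an experimental group.  Counts are normalized to
reads per million (RPM); a small positive shift can later be applied so
that log- and reciprocal-scale transforms stay finite for zero counts.

Per-sample totals default to the column sums of the supplied matrix.  The
sequencer's true total read output (pre-alignment) is not recoverable from
a count matrix; users who have it can supply a ``library_size`` column in
the metadata and those totals are used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_counts",
    "read_annotation",
    "rpm_normalize",
    "apply_shift",
    "consolidate_by_symbol",
    "write_table",
]

#: RefSeq accession prefixes conventionally treated as non-(protein-)coding
#: and dropped before symbol-level consolidation.
NONCODING_PREFIXES = ("XR_", "XM_", "NR_")


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with group metadata."""

    counts: pd.DataFrame
    sample_groups: pd.Series
    baseline_group: str | None = None
    strata: pd.Series | None = None
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in count matrix")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(vals).any():
            raise ValueError("counts contain missing values")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count for gene {c.index[g]!r} in sample {c.columns[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise ValueError(
                f"non-integral count for gene {c.index[g]!r} in sample {c.columns[s]!r}"
            )
        missing = c.columns.difference(self.sample_groups.index)
        if len(missing):
            raise ValueError(f"samples absent from metadata: {list(missing)}")
        self.sample_groups = self.sample_groups.reindex(c.columns)
        if self.baseline_group is not None:
            if self.baseline_group not in set(self.sample_groups):
                raise ValueError(
                    f"baseline group {self.baseline_group!r} has no samples"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_groups:
            seen.setdefault(g, None)
        return list(seen)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        """Restrict to a subset of samples (order preserved as given)."""
        return CountMatrix(
            counts=self.counts[samples],
            sample_groups=self.sample_groups.loc[samples],
            baseline_group=self.baseline_group,
            strata=None if self.strata is None else self.strata.loc[samples],
            library_size=(
                None if self.library_size is None else self.library_size.loc[samples]
            ),
        )


@dataclass
class ExpressionMatrix:
    """RPM values on the same axes as the source counts.

    ``shift`` records the threshold offset gamma (RPM units) added to every
    entry; 0 means unshifted.  Group metadata is carried along so downstream
    stages never need the raw counts again.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    baseline_group: str | None = None
    shift: float = 0.0

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def gene_means(self) -> pd.Series:
        """Gene-wise mean RPM across all samples (on the unshifted scale)."""
        return self.values.mean(axis=1) - self.shift

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[genes])


def _read_delim(path: str | Path, **kw) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, **kw)


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample count matrix and its sample metadata.

    The matrix is TSV or CSV (by extension) with gene IDs in the first
    column and sample IDs in the header.  Metadata needs ``sample`` and
    ``group`` columns; ``stratum``, ``library_size`` and ``baseline``
    (boolean marker of the reference group) are optional.
    """
    counts = _read_delim(path, index_col=0)
    meta = _read_delim(metadata_path)
    for col in ("sample", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    meta = meta.set_index("sample")
    groups = meta["group"].astype(str)
    baseline = None
    if "baseline" in meta.columns:
        flagged = groups[meta["baseline"].astype(bool)].unique()
        if len(flagged) == 1:
            baseline = flagged[0]
        elif len(flagged) > 1:
            raise ValueError(f"multiple groups flagged as baseline: {list(flagged)}")
    return CountMatrix(
        counts=counts,
        sample_groups=groups,
        baseline_group=baseline,
        strata=meta["stratum"].astype(str) if "stratum" in meta.columns else None,
        library_size=(
            meta["library_size"].astype(float) if "library_size" in meta.columns else None
        ),
    )


def read_annotation(path: str | Path) -> pd.Series:
    """Read a two-column transcript-ID -> gene-symbol table."""
    ann = _read_delim(path)
    if ann.shape[1] < 2:
        raise ValueError("annotation needs two columns: transcript_id, symbol")
    ann = ann.iloc[:, :2]
    ann.columns = ["transcript_id", "symbol"]
    if ann["transcript_id"].duplicated().any():
        raise ValueError("duplicate transcript IDs in annotation")
    if (ann["symbol"].astype(str).str.len() == 0).any() or ann["symbol"].isna().any():
        raise ValueError("empty gene symbols in annotation")
    return ann.set_index("transcript_id")["symbol"].astype(str)


def rpm_normalize(cm: CountMatrix) -> ExpressionMatrix:
    """Normalize counts to reads per million of total reads per sample.

    Totals are the per-sample column sums unless the metadata supplied
    explicit ``library_size`` values.
    """
    totals = (
        cm.counts.sum(axis=0).astype(float)
        if cm.library_size is None
        else cm.library_size.reindex(cm.sample_ids)
    )
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    rpm = cm.counts.div(totals, axis=1) * 1e6
    return ExpressionMatrix(
        values=rpm,
        sample_groups=cm.sample_groups,
        baseline_group=cm.baseline_group,
        shift=0.0,
    )


def apply_shift(em: ExpressionMatrix, gamma: float) -> ExpressionMatrix:
    """Add the fitted threshold gamma (RPM) to every value.

    The shift keeps zero-valued RPM entries strictly positive so that the
    log and reciprocal transformants, and fold-change ratios, stay finite.
    """
    if gamma < 0:
        raise ValueError(f"shift gamma must be >= 0, got {gamma}")
    if em.shift != 0.0:
        raise ValueError(f"matrix already shifted by {em.shift}; refusing to re-shift")
    return replace(em, values=em.values + gamma, shift=float(gamma))


def consolidate_by_symbol(
    values: pd.DataFrame,
    annotation: pd.Series,
    drop_prefixes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Collapse a per-transcript table to official gene symbols.

    Rows whose transcript ID starts with one of ``drop_prefixes`` (e.g. the
    RefSeq non-coding prefixes) are removed first; the remaining rows are
    averaged (arithmetic mean, column-wise) within each symbol.  Output has
    one row per distinct symbol, in first-appearance order.
    """
    keep = values.index
    if drop_prefixes:
        keep = keep[~keep.str.startswith(tuple(drop_prefixes))]
    vals = values.loc[keep]
    unannotated = vals.index.difference(annotation.index)
    if len(unannotated):
        raise ValueError(f"unannotated transcripts: {list(unannotated[:5])}")
    symbols = annotation.reindex(vals.index)
    out = vals.groupby(symbols, sort=False).mean()
    out.index.name = "symbol"
    return out


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a TSV plus a small JSON sidecar of run provenance."""
    import json

    path = Path(path)
    df.to_csv(path, sep="\t")
    if provenance is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(provenance, indent=2, default=str) + "\n")
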