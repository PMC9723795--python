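"""Abundance tables: I/O, filtering, zero replacement, CLR, rare/abundant labels.

Count tables are features x samples (OTUs/proteins/KOs in rows, sampling dates
in columns), the layout used throughout marine time-series metagenomics.  All
transforms here are compositional: only within-sample relative information is
interpreted, which is why zeros must be replaced before taking log-ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FeatureKind = Literal["otu", "protein", "ko"]
FractionLabel = Literal["assembled", "unassembled"]

#: Rare/abundant split for relative abundances (0.01 % within a sample).
RARE_THRESHOLD = 1e-4


@dataclass
class AbundanceTable:
    """Integer count matrix, features in rows, samples in columns.

    Parameters
    ----------
    counts:
        DataFrame with feature ids as index and sample ids as columns,
        non-negative integer cells.
    feature_kind:
        What the rows are: ``otu`` (16S), ``protein`` (gene catalog entries)
        or ``ko`` (KEGG orthologs).
    fraction_label:
        Optional read-fraction provenance of the table.
    """

    counts: pd.DataFrame
    feature_kind: Optional[FeatureKind] = None
    fraction_label: Optional[FractionLabel] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        self.counts = self.counts.astype(np.int64)
        # axis labels live in the file format, not in the in-memory frame
        self.counts.index.name = None
        self.counts.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (columns sum to 1; all-zero samples stay 0)."""
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.replace(0, 1), axis=1)


@dataclass
class ClrTable:
    """Centered log-ratio values, features x samples; columns sum to ~0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        colsums = self.values.sum(axis=0).to_numpy()
        if np.abs(colsums).max(initial=0.0) > 1e-9:
            raise ValueError("CLR columns must sum to 0 within 1e-9")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleMetadata:
    """Per-sample collection dates and environmental covariates.

    ``table`` is indexed by sample id with a ``date`` column (datetime) and one
    column per environmental parameter (temperature, oxygen, nitrite...).
    """

    table: pd.DataFrame

    ENV_COLUMNS = ("temperature", "oxygen", "nitrite")

    def __post_init__(self) -> None:
        if "date" not in self.table.columns:
            raise ValueError("metadata needs a 'date' column")
        self.table = self.table.assign(date=pd.to_datetime(self.table["date"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def dates(self) -> pd.Series:
        return self.table["date"]

    def env(self) -> pd.DataFrame:
        """Environmental covariates as parameters x samples (network layout)."""
        cols = [c for c in self.table.columns if c != "date"]
        return self.table[cols].T


# ---------------------------------------------------------------------------
# I/O


def read_abundance_table(
    path: str | Path,
    feature_kind: Optional[FeatureKind] = None,
    fraction_label: Optional[FractionLabel] = None,
) -> AbundanceTable:
    """Read a tab-separated count table (first column ``feature_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "feature_id":
        raise ValueError(
            f"{path.name}: first column must be 'feature_id', got {df.columns[0]!r}"
        )
    df = df.set_index("feature_id")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac, _ = np.modf(arr.astype(float))
        if np.abs(frac).max(initial=0.0) > 0:
            rows, cols = np.nonzero(np.abs(frac) > 0)
            raise ValueError(
                f"{path.name}: non-integer cell at feature "
                f"{df.index[rows[0]]!r}, sample {df.columns[cols[0]]!r}"
            )
        df = df.astype(np.int64)
    return AbundanceTable(df, feature_kind=feature_kind, fraction_label=fraction_label)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as tab-separated text; round-trips through the reader."""
    df = table.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.table.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_clr_table(path: str | Path) -> ClrTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("feature_id")
    return ClrTable(df.astype(float))


def write_clr_table(table: ClrTable, path: str | Path) -> None:
    df = table.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Filtering and transforms


def filter_low_prevalence(
    table: AbundanceTable,
    min_samples: int = 20,
    drop_total_singletons: bool = True,
) -> AbundanceTable:
    """Drop singleton features and features detected in too few samples.

    A feature is removed when its total count over all samples equals 1
    (``drop_total_singletons``), or when it has a nonzero count in fewer than
    ``min_samples`` samples ("detected" means count >= 1).  The default of 20
    samples is half of a 40-sample monthly series.  Idempotent; the sample set
    is never changed.
    """
    if min_samples > table.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {table.shape[1]}"
        )
    counts = table.counts
    prevalence = (counts > 0).sum(axis=1)
    keep = prevalence >= min_samples
    if drop_total_singletons:
        keep &= counts.sum(axis=1) != 1
    return AbundanceTable(
        counts.loc[keep],
        feature_kind=table.feature_kind,
        fraction_label=table.fraction_label,
    )


def replace_zeros(table: AbundanceTable) -> pd.DataFrame:
    """Bayesian-multiplicative (czm) count-zero replacement.

    Per sample with total n, each zero is imputed as the proportion 0.5/n and
    the nonzero proportions are multiplicatively shrunk by (1 - z*0.5/n) with z
    the number of zeros, so the sample still sums to exactly 1.  Samples with
    no zeros are returned as plain proportions.

    Returns a strictly positive features x samples DataFrame of proportions.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.counts.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} has no counts; cannot replace zeros")
    props = counts / totals
    zeros = counts == 0
    delta = 0.5 / totals  # imputed proportion per zero cell, per sample
    shrink = 1.0 - zeros.sum(axis=0) * delta
    if (shrink <= 0).any():
        bad = table.counts.columns[shrink <= 0][0]
        raise ValueError(f"sample {bad!r}: too many zeros for czm replacement")
    out = props * shrink
    out[zeros] = np.broadcast_to(delta, counts.shape)[zeros]
    return pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)


def clr_transform(composition: pd.DataFrame) -> ClrTable:
    """Centered log-ratio transform: ln(x_i) minus the sample's mean log.

    Requires strictly positive input (run :func:`replace_zeros` first on count
    data).  Within every sample the output sums to 0.
    """
    arr = composition.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("CLR requires strictly positive input")
    logs = np.log(arr)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return ClrTable(pd.DataFrame(clr, index=composition.index, columns=composition.columns))


def clr_from_counts(table: AbundanceTable) -> ClrTable:
    """Convenience: czm zero replacement followed by CLR."""
    return clr_transform(replace_zeros(table))


def classify_rare_abundant(
    table: AbundanceTable, threshold: float = RARE_THRESHOLD
) -> pd.DataFrame:
    """Label every cell rare or abundant by within-sample relative abundance.

    Abundant means strictly above ``threshold`` (default 0.01 %), rare strictly
    below; exact equality is classed rare (the conservative side of an
    otherwise unassigned boundary) with a logged warning.
    """
    if table.counts.size == 0:
        raise ValueError("cannot classify an empty table")
    rel = table.relative_abundance().to_numpy()
    if (rel == threshold).any():
        n = int((rel == threshold).sum())
        logger.warning(
            "%d cells sit exactly at the %.4g threshold; classed as rare", n, threshold
        )
    labels = np.where(rel > threshold, "abundant", "rare")
    return pd.DataFrame(labels, index=table.counts.index, columns=table.counts.columns)
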