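"""Synthetic seasonal metagenomic time series with planted co-abundance groups.

The generator emulates the statistical structure of a monthly marine
metagenomic series: ~3 years of samples, OTU abundances oscillating on a
log-scale annual sinusoid, planted co-abundance gene groups (CAGs) whose
member genes track an anchor OTU up to a fixed per-gene factor and lognormal
noise, a long tail of background genes, and environmental covariates
(temperature, oxygen, nitrite) phase-locked to the season.  Rare OTUs are
planted below the 0.01 % relative-abundance cutoff so rare/abundant recovery
is testable, and get the full seasonal amplitude while abundant OTUs get a
damped one — mirroring the observation that the rare gene pool carries the
clear seasonal signal.

Counts are drawn multinomially per sample at a fixed library size, which
produces the compositional, zero-inflated tables the downstream statistics
assume.  The noise-free latent (expected-abundance) matrices are kept on the
dataset for exact oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    SampleMetadata,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
    write_metadata,
)

#: Expected relative abundance planted for rare OTUs (seasonal peak included);
#: half the 0.01 % rare cutoff so rare OTUs stay rare all year.
_RARE_LEVEL = 5e-5


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic time series.

    Defaults describe the emulated study design: 40 monthly samples, a
    12-month season, multiplicative lognormal gene noise, and a quarter of
    OTUs planted in the rare biosphere (below 0.01 % relative abundance).
    """

    n_samples: int = 40
    n_otus: int = 40
    n_cags: int = 8
    genes_per_cag: tuple[int, int] = (10, 30)
    n_background_genes: int = 100
    seasonal_amplitude: float = 1.0
    seasonal_period: float = 12.0
    noise_sd: float = 0.2
    library_size: int = 50_000
    rare_fraction: float = 0.25
    coverage_threshold: float = 0.01
    abundant_amplitude_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_otus", "n_cags", "library_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        lo, hi = self.genes_per_cag
        if lo < 1 or hi < lo:
            raise ValueError("genes_per_cag must be a (min, max) range with min >= 1")
        if not 0 <= self.rare_fraction <= 1:
            raise ValueError("rare_fraction must lie in [0, 1]")
        if self.seasonal_period <= 0:
            raise ValueError("seasonal_period must be positive")
        if self.seasonal_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("seasonal_amplitude and noise_sd must be >= 0")
        if not 0 <= self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must lie in [0, 1]")
        if self.n_cags > self.n_otus:
            raise ValueError("n_cags cannot exceed n_otus")


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted ground truth.

    ``otu_expected`` / ``gene_expected`` hold the latent expected-abundance
    matrices (gene noise included; exactly proportional to the anchor when
    noise_sd = 0) so tests can bypass multinomial sampling.
    """

    otu_table: AbundanceTable
    gene_table: AbundanceTable
    metadata: SampleMetadata
    truth_gene_to_cag: dict[str, Optional[str]]
    truth_cag_anchor: dict[str, str]
    truth_rare_labels: dict[str, str]
    otu_expected: pd.DataFrame = field(repr=False, default=None)
    gene_expected: pd.DataFrame = field(repr=False, default=None)
    config: GeneratorConfig = None

    def __post_init__(self) -> None:
        otus = set(self.otu_table.feature_ids)
        for cag, anchor in self.truth_cag_anchor.items():
            if anchor not in otus:
                raise ValueError(f"anchor {anchor!r} of {cag} is not an OTU")
        if self.otu_table.sample_ids != self.gene_table.sample_ids:
            raise ValueError("OTU and gene tables must share sample ids in order")


def _seasonal_log_profile(
    months: np.ndarray, mu: float, amplitude: float, phase: float, period: float
) -> np.ndarray:
    return mu + amplitude * np.sin(2 * np.pi * (months - phase) / period)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a reproducible synthetic dataset from ``config.seed``.

    OTU i has expected abundance exp(mu_i + A_i sin(2*pi*(t - phase_i)/P)) at
    month t; every CAG gene is its anchor's expected profile times a fixed
    per-gene factor times exp(N(0, noise_sd)) multiplicative noise.  Counts
    are multinomial per sample at ``library_size`` (columns sum exactly to
    it), separately for the OTU and gene tables.
    """
    rng = np.random.default_rng(config.seed)
    months = np.arange(config.n_samples, dtype=float)
    dates = pd.date_range("2012-01-01", periods=config.n_samples, freq="MS")
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]

    otu_ids = [f"OTU{i + 1:04d}" for i in range(config.n_otus)]
    n_rare = int(round(config.rare_fraction * config.n_otus))
    rare_idx = rng.choice(config.n_otus, size=n_rare, replace=False)
    is_rare = np.zeros(config.n_otus, dtype=bool)
    is_rare[rare_idx] = True

    A = config.seasonal_amplitude
    # Phases stratified evenly over the seasonal cycle (annual succession:
    # different OTUs peak in different months).  With a shared-period sinusoid
    # latent model the phase is the only dynamic fingerprint of an OTU, so an
    # even spread keeps distinct OTUs distinguishable.
    offset = rng.uniform(0, 1)
    phases = (
        config.seasonal_period
        * (rng.permutation(config.n_otus) + offset)
        / config.n_otus
    )
    mu = rng.normal(0.0, 1.0, size=config.n_otus)
    amps = np.where(is_rare, A, A * config.abundant_amplitude_factor)

    otu_log = np.empty((config.n_otus, config.n_samples))
    for i in range(config.n_otus):
        otu_log[i] = _seasonal_log_profile(
            months, mu[i], amps[i], phases[i], config.seasonal_period
        )
    # Pin rare OTUs below the rare cutoff: their seasonal *peak* expected
    # abundance is _RARE_LEVEL of the abundant total at that month.
    otu_exp = np.exp(otu_log)
    if is_rare.any() and (~is_rare).any():
        abundant_total = otu_exp[~is_rare].sum(axis=0).min()
        for i in np.flatnonzero(is_rare):
            peak = otu_exp[i].max()
            otu_exp[i] *= _RARE_LEVEL * abundant_total / peak
    otu_expected = pd.DataFrame(otu_exp, index=otu_ids, columns=sample_ids)

    # Anchors prefer abundant OTUs (their dynamics must be observable); spill
    # into rare ones only when there are not enough abundant OTUs.
    abundant_pool = [i for i in range(config.n_otus) if not is_rare[i]]
    rare_pool = [i for i in range(config.n_otus) if is_rare[i]]
    anchor_idx = [int(i) for i in rng.permutation(abundant_pool)][: config.n_cags]
    if len(anchor_idx) < config.n_cags:
        extra = config.n_cags - len(anchor_idx)
        anchor_idx += [int(i) for i in rng.permutation(rare_pool)][:extra]

    cag_ids = [f"CAG{i + 1:03d}" for i in range(config.n_cags)]
    truth_cag_anchor = {c: otu_ids[a] for c, a in zip(cag_ids, anchor_idx)}

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth_gene_to_cag: dict[str, Optional[str]] = {}
    lo, hi = config.genes_per_cag
    for cag, a in zip(cag_ids, anchor_idx):
        n_genes = int(rng.integers(lo, hi + 1))
        anchor_profile = otu_exp[a]
        base = anchor_profile / anchor_profile.mean()  # comparable gene scales
        for g in range(n_genes):
            gid = f"{cag}_g{g + 1:03d}"
            factor = rng.lognormal(0.0, 0.5)
            noise = (
                np.exp(rng.normal(0.0, config.noise_sd, size=config.n_samples))
                if config.noise_sd > 0
                else 1.0
            )
            gene_rows.append(base * factor * noise)
            gene_ids.append(gid)
            truth_gene_to_cag[gid] = cag

    # Background genes: the long tail.  Independent seasonal profiles at the
    # full amplitude (the tail is the strongly seasonal pool), small scale.
    bg_phases = rng.uniform(0, config.seasonal_period, size=config.n_background_genes)
    bg_mu = rng.normal(-2.0, 1.0, size=config.n_background_genes)
    for b in range(config.n_background_genes):
        gid = f"BG_g{b + 1:04d}"
        profile = np.exp(
            _seasonal_log_profile(
                months, bg_mu[b], A, bg_phases[b], config.seasonal_period
            )
        )
        if config.noise_sd > 0:
            profile = profile * np.exp(
                rng.normal(0.0, config.noise_sd, size=config.n_samples)
            )
        gene_rows.append(profile)
        gene_ids.append(gid)
        truth_gene_to_cag[gid] = None

    gene_expected = pd.DataFrame(
        np.asarray(gene_rows), index=gene_ids, columns=sample_ids
    )

    otu_counts = _multinomial_counts(rng, otu_expected.to_numpy(), config.library_size)
    gene_counts = _multinomial_counts(rng, gene_expected.to_numpy(), config.library_size)

    otu_table = AbundanceTable(
        pd.DataFrame(otu_counts, index=otu_ids, columns=sample_ids), feature_kind="otu"
    )
    gene_table = AbundanceTable(
        pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids),
        feature_kind="protein",
    )

    # Season-locked environment: temperature peaks mid-summer, oxygen is in
    # antiphase (cold water holds more O2), nitrite peaks in early winter.
    w = 2 * np.pi * months / config.seasonal_period
    meta = pd.DataFrame(
        {
            "date": dates,
            "temperature": 15.0 + 7.0 * np.sin(w - np.pi / 2),
            "oxygen": 250.0 - 40.0 * np.sin(w - np.pi / 2),
            "nitrite": 0.2 + 0.15 * np.sin(w + np.pi / 3),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    return SyntheticDataset(
        otu_table=otu_table,
        gene_table=gene_table,
        metadata=SampleMetadata(meta),
        truth_gene_to_cag=truth_gene_to_cag,
        truth_cag_anchor=truth_cag_anchor,
        truth_rare_labels={
            otu_ids[i]: ("rare" if is_rare[i] else "abundant")
            for i in range(config.n_otus)
        },
        otu_expected=otu_expected,
        gene_expected=gene_expected,
        config=config,
    )


def _multinomial_counts(
    rng: np.random.Generator, expected: np.ndarray, library_size: int
) -> np.ndarray:
    """Draw one multinomial per sample (column) at the given library size."""
    n_features, n_samples = expected.shape
    out = np.empty((n_features, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = expected[:, j] / expected[:, j].sum()
        out[:, j] = rng.multinomial(library_size, p)
    return out


def assign_fractions(
    dataset: SyntheticDataset, coverage_threshold: Optional[float] = None
) -> tuple[AbundanceTable, AbundanceTable]:
    """Split the gene table into (assembled, unassembled) by anchor coverage.

    A gene's counts in a sample go to the unassembled table when its anchor
    OTU's relative abundance in that sample (from the OTU count table) is
    strictly below ``coverage_threshold`` — a desk-scale proxy for "too low
    coverage to assemble".  Background genes, which have no anchor, are routed
    by their own relative abundance in the gene table.  The two outputs sum
    cell-wise to the original gene table.
    """
    if coverage_threshold is None:
        coverage_threshold = dataset.config.coverage_threshold
    if not 0 <= coverage_threshold <= 1:
        raise ValueError("coverage_threshold must lie in [0, 1]")

    otu_rel = dataset.otu_table.relative_abundance()
    gene_rel = dataset.gene_table.relative_abundance()
    counts = dataset.gene_table.counts

    unassembled_mask = np.empty(counts.shape, dtype=bool)
    for r, gid in enumerate(counts.index):
        cag = dataset.truth_gene_to_cag.get(gid)
        if cag is not None:
            anchor = dataset.truth_cag_anchor[cag]
            cov = otu_rel.loc[anchor].to_numpy()
        else:
            cov = gene_rel.loc[gid].to_numpy()
        unassembled_mask[r] = cov < coverage_threshold

    arr = counts.to_numpy()
    unassembled = np.where(unassembled_mask, arr, 0)
    assembled = arr - unassembled
    mk = dataset.gene_table.feature_kind
    return (
        AbundanceTable(
            pd.DataFrame(assembled, index=counts.index, columns=counts.columns),
            feature_kind=mk,
            fraction_label="assembled",
        ),
        AbundanceTable(
            pd.DataFrame(unassembled, index=counts.index, columns=counts.columns),
            feature_kind=mk,
            fraction_label="unassembled",
        ),
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write tables, metadata and truth maps as tab-separated files.

    Returns a name -> path map.  Round-trips losslessly through
    :func:`read_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": directory / "otu_table.tsv",
        "gene_table": directory / "gene_table.tsv",
        "metadata": directory / "metadata.tsv",
        "truth_gene_to_cag": directory / "truth_gene_to_cag.tsv",
        "truth_cag_anchor": directory / "truth_cag_anchor.tsv",
        "truth_rare_labels": directory / "truth_rare_labels.tsv",
    }
    try:
        write_abundance_table(dataset.otu_table, paths["otu_table"])
        write_abundance_table(dataset.gene_table, paths["gene_table"])
        write_metadata(dataset.metadata, paths["metadata"])
        _write_map(
            paths["truth_gene_to_cag"],
            ("gene_id", "cag_id"),
            {g: (c if c is not None else "none") for g, c in dataset.truth_gene_to_cag.items()},
        )
        _write_map(paths["truth_cag_anchor"], ("cag_id", "otu_id"), dataset.truth_cag_anchor)
        _write_map(paths["truth_rare_labels"], ("otu_id", "label"), dataset.truth_rare_labels)
    except OSError as exc:
        raise OSError(f"failed writing {exc.filename}: {exc}") from exc
    return paths


def _write_map(path: Path, header: tuple[str, str], mapping: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def _read_map(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset` (no latent matrices)."""
    directory = Path(directory)
    g2c = {
        g: (None if c == "none" else c)
        for g, c in _read_map(directory / "truth_gene_to_cag.tsv").items()
    }
    return SyntheticDataset(
        otu_table=read_abundance_table(directory / "otu_table.tsv", feature_kind="otu"),
        gene_table=read_abundance_table(
            directory / "gene_table.tsv", feature_kind="protein"
        ),
        metadata=read_metadata(directory / "metadata.tsv"),
        truth_gene_to_cag=g2c,
        truth_cag_anchor=_read_map(directory / "truth_cag_anchor.tsv"),
        truth_rare_labels=_read_map(directory / "truth_rare_labels.tsv"),
    )
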