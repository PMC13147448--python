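"""Abundance tables, taxonomy maps and sample metadata.

The central container is :class:`AbundanceTable`, a validated samples x taxa
matrix of counts or relative abundances at a stated taxonomic rank
(ASV, genus, order or phylum).  TSV readers/writers, rank aggregation and
per-species profile collapsing live here; every downstream analysis consumes
these objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: taxonomic ranks from finest to coarsest
RANKS = ("ASV", "genus", "order", "phylum")

UNCLASSIFIED = "unclassified"


def _check_rank(rank: str) -> str:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    return rank


@dataclass
class AbundanceTable:
    """A samples x taxa abundance matrix at a single taxonomic rank.

    Parameters
    ----------
    data :
        DataFrame with sample ids as index and taxon ids as columns.
        Values must be finite and non-negative; no sample row may sum to zero.
    rank :
        Taxonomic level of the columns, one of ``ASV, genus, order, phylum``.
    is_relative :
        True if each row is a composition summing to one.
    """

    data: pd.DataFrame
    rank: str
    is_relative: bool = False

    def __post_init__(self) -> None:
        _check_rank(self.rank)
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance matrix contains NaN/inf")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        row_sums = values.sum(axis=1)
        if (row_sums == 0).any():
            bad = df.index[row_sums == 0].tolist()
            raise ValueError(f"zero-total sample(s): {bad}")
        if self.is_relative and not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("is_relative=True but row sums deviate from 1")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "AbundanceTable":
        """Subset (and reorder) to the given sample ids."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(), self.rank, self.is_relative)


@dataclass
class TaxonomyMap:
    """taxon_id -> (phylum, order, genus) labels; unknowns are 'unclassified'."""

    data: pd.DataFrame  # index taxon_id; columns phylum, order, genus

    def __post_init__(self) -> None:
        required = {"phylum", "order", "genus"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"taxonomy map needs columns {sorted(required)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate taxon ids in taxonomy map")
        self.data = self.data.fillna(UNCLASSIFIED)

    def label(self, taxon_id: str, rank: str) -> str:
        _check_rank(rank)
        if rank == "ASV":
            return taxon_id
        if taxon_id not in self.data.index:
            return UNCLASSIFIED
        return str(self.data.loc[taxon_id, rank])


@dataclass
class SampleMetadata:
    """Per-sample host species and body site assignments."""

    data: pd.DataFrame  # index sample_id; columns host_species, body_site

    def __post_init__(self) -> None:
        required = {"host_species", "body_site"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"metadata needs columns {sorted(required)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")

    def covers(self, table: AbundanceTable) -> bool:
        return set(table.sample_ids) <= set(self.data.index)

    def species_of(self, sample_ids) -> pd.Series:
        return self.data.loc[list(sample_ids), "host_species"]

    def sites_of(self, sample_ids) -> pd.Series:
        return self.data.loc[list(sample_ids), "body_site"]


# ---------------------------------------------------------------------------
# TSV IO
# ---------------------------------------------------------------------------

def read_abundance_table(path, rank: str, samples_as_rows: bool = True,
                         is_relative: bool = False) -> AbundanceTable:
    """Read an abundance TSV (header = taxon ids, first column = sample ids).

    Set ``samples_as_rows=False`` for the transposed dialect
    (taxa as rows, samples as columns).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, rank=rank, is_relative=is_relative)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyMap(df)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (idempotent)."""
    if table.is_relative:
        return table
    values = table.matrix
    rel = values / values.sum(axis=1, keepdims=True)
    df = pd.DataFrame(rel, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(df, rank=table.rank, is_relative=True)


def aggregate_rank(table: AbundanceTable, taxonomy: TaxonomyMap,
                   target: str) -> AbundanceTable:
    """Sum columns into a coarser rank using the taxonomy map.

    Taxa absent from the map are pooled into 'unclassified' with a warning.
    Row totals are preserved exactly.
    """
    _check_rank(target)
    if RANKS.index(target) <= RANKS.index(table.rank):
        raise ValueError(
            f"target rank {target!r} is not coarser than table rank {table.rank!r}"
        )
    missing = [t for t in table.taxon_ids if t not in taxonomy.data.index]
    if missing:
        warnings.warn(
            f"{len(missing)} taxa missing from taxonomy map mapped to "
            f"'{UNCLASSIFIED}' (e.g. {missing[:3]})"
        )
    labels = [taxonomy.label(t, target) for t in table.taxon_ids]
    grouped = table.data.T.groupby(pd.Index(labels, name=target)).sum().T
    # keep a stable, readable column order: alphabetical with unclassified last
    cols = sorted(c for c in grouped.columns if c != UNCLASSIFIED)
    if UNCLASSIFIED in grouped.columns:
        cols.append(UNCLASSIFIED)
    grouped = grouped[cols]
    return AbundanceTable(grouped, rank=target, is_relative=table.is_relative)


def mean_species_profile(table: AbundanceTable, metadata: SampleMetadata,
                         body_site: str, pooled: bool = False) -> AbundanceTable:
    """Collapse replicate samples to one relative-abundance profile per host species.

    For each species with samples at ``body_site``, either average the samples'
    relative-abundance rows (default) or pool raw rows before renormalizing
    (``pooled=True``).  Returns a table whose "sample" ids are species names.
    """
    if not metadata.covers(table):
        missing = sorted(set(table.sample_ids) - set(metadata.data.index))
        raise ValueError(f"samples without metadata: {missing}")
    sites = metadata.sites_of(table.sample_ids)
    keep = [s for s, site in zip(table.sample_ids, sites) if site == body_site]
    if not keep:
        raise ValueError(f"no samples at body site {body_site!r}")
    sub = table.select_samples(keep)
    species = metadata.species_of(keep).to_numpy()
    if pooled:
        pooled_df = sub.data.groupby(species).sum()
        rel = pooled_df.div(pooled_df.sum(axis=1), axis=0)
    else:
        rel = to_relative(sub).data.groupby(species).mean()
    rel.index = rel.index.astype(str)
    rel = rel.sort_index()
    return AbundanceTable(rel, rank=table.rank, is_relative=True)
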