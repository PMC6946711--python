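"""Core data containers and tab-separated I/O.

The package revolves around three aligned tables — an OTU abundance table
(samples x taxa), per-sample design metadata, and per-taxon annotation
(ranked lineage plus functional guild) — and a rank-based cladogram built
from the annotation.  Everything is label-addressed: rows are samples,
columns are taxa, and matrices carry their ids.

All tables are read and written as plain TSV so that fixtures stay
diff-able.  Trees use newick via scikit-bio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "TableMode",
    "CommunityTable",
    "SampleMetadata",
    "TaxonAnnotation",
    "RANKS",
    "COMPARTMENTS",
    "TREATMENTS",
    "CULTIVARS",
    "GUILDS",
    "UNKNOWN_RANK",
    "load_dataset",
    "taxonomy_to_cladogram",
    "patristic_distances",
    "write_distance_matrix",
    "read_distance_matrix",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
COMPARTMENTS = ("leaf", "root", "rhizosphere", "soil")
TREATMENTS = ("control", "pre_flowering_drought", "post_flowering_drought")
CULTIVARS = ("RTx430", "BTx642")
GUILDS = ("saprotroph", "plant_pathogen", "amf", "endophyte", "yeast", "unknown")

#: sentinel for an unresolved rank; never an empty string
UNKNOWN_RANK = "unknown"


class TableMode(str, enum.Enum):
    """How the abundance values of a :class:`CommunityTable` are scaled."""

    counts = "counts"
    relative = "relative"
    clr = "clr"


class ValidationError(ValueError):
    """A table or metadata object violates one of its invariants."""


@dataclass
class CommunityTable:
    """Samples x taxa abundance matrix with an explicit value mode.

    Parameters
    ----------
    data:
        DataFrame with sample ids on the index and taxon ids on the
        columns.  Values are raw counts, relative abundances, or centred
        log-ratios depending on ``mode``.
    mode:
        One of ``counts``, ``relative`` or ``clr``.
    """

    data: pd.DataFrame
    mode: TableMode = TableMode.counts

    def __post_init__(self) -> None:
        self.mode = TableMode(self.mode)
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite abundance values")
        if self.mode in (TableMode.counts, TableMode.relative) and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance for sample {idx[r]!r}, taxon {cols[c]!r}"
            )
        if self.mode is TableMode.relative:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("relative-mode rows must sum to 1")
        if self.mode is TableMode.clr:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 0.0, atol=1e-9):
                raise ValidationError("clr-mode rows must sum to 0")

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "CommunityTable":
        return CommunityTable(self.data.copy(), self.mode)

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: TableMode | str = TableMode.counts) -> "CommunityTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, TableMode(mode))


@dataclass
class SampleMetadata:
    """Per-sample design factors for the compartment x week x treatment grid.

    Required columns: ``compartment``, ``week``, ``treatment``; optional:
    ``cultivar``, ``plot``, ``x``, ``y``, ``community_size``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df = df.copy()
                df.index.name = "sample_id"
        df.index = df.index.astype(str)
        self.data = df
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
        for col in ("compartment", "week", "treatment"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad = set(df["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(f"unknown compartment values: {sorted(bad)}")
        weeks = df["week"].astype(int)
        if ((weeks < 0) | (weeks > 17)).any():
            raise ValidationError("week must lie in 0..17")
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment values: {sorted(bad)}")
        if "cultivar" in df.columns:
            bad = set(df["cultivar"].dropna()) - set(CULTIVARS)
            if bad:
                raise ValidationError(f"unknown cultivar values: {sorted(bad)}")
        if "community_size" in df.columns:
            cs = df["community_size"].dropna()
            if (cs <= 0).any():
                raise ValidationError("community_size must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, table: CommunityTable) -> "SampleMetadata":
        """Return a copy whose rows follow the sample order of *table*."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"metadata missing sample id {missing[0]!r}")
        return SampleMetadata(self.data.loc[table.sample_ids].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class TaxonAnnotation:
    """Ranked lineage (kingdom..genus) plus functional guild per taxon.

    Unresolved ranks are stored as the explicit string ``"unknown"``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "taxon_id":
            if "taxon_id" in df.columns:
                df = df.set_index("taxon_id")
            else:
                df = df.copy()
                df.index.name = "taxon_id"
        df.index = df.index.astype(str)
        df = df.copy()
        for rank in RANKS:
            if rank not in df.columns:
                raise ValidationError(f"annotation missing rank column {rank!r}")
            df[rank] = df[rank].fillna(UNKNOWN_RANK).replace("", UNKNOWN_RANK).astype(str)
        if "guild" not in df.columns:
            df["guild"] = "unknown"
        self.data = df
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids in annotation: {dupes}")
        bad = set(df["guild"]) - set(GUILDS)
        if bad:
            raise ValidationError(f"unknown guild labels: {sorted(bad)}")
        # a resolved rank below an unknown one would make the lineage ambiguous
        ranks = df[list(RANKS)].to_numpy()
        known = ranks != UNKNOWN_RANK
        for i, row in enumerate(known):
            if row.any() and not row.all():
                first_unknown = int(np.argmin(row)) if not row[0] else int(np.argmax(~row))
                if row[first_unknown:].any():
                    raise ValidationError(
                        f"taxon {df.index[i]!r}: resolved rank below an unknown rank"
                    )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, taxon_id: str) -> list[str]:
        """Resolved rank path for a taxon, truncated at the first unknown."""
        row = self.data.loc[taxon_id, list(RANKS)]
        path = []
        for rank_name, value in zip(RANKS, row):
            if value == UNKNOWN_RANK:
                break
            path.append(str(value))
        return path

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------

def load_dataset(
    table_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
    mode: TableMode | str = TableMode.counts,
) -> tuple[CommunityTable, SampleMetadata, TaxonAnnotation]:
    """Load and cross-validate the three canonical TSVs.

    Metadata rows are re-ordered to follow the table's sample order.  Any
    table sample missing from the metadata, or table taxon missing from
    the annotation, raises a :class:`ValidationError` naming the id.
    """
    table = CommunityTable.from_tsv(table_path, mode)
    meta = SampleMetadata.from_tsv(metadata_path).aligned_to(table)
    annot = TaxonAnnotation.from_tsv(taxonomy_path)
    extra = [s for s in meta.sample_ids if s not in set(table.sample_ids)]
    if extra:
        raise ValidationError(f"metadata sample id {extra[0]!r} not present in table")
    missing_taxa = [t for t in table.taxon_ids if t not in set(annot.taxon_ids)]
    if missing_taxa:
        raise ValidationError(f"taxon {missing_taxa[0]!r} missing from annotation")
    return table, meta, annot


# ---------------------------------------------------------------------------
# rank-based cladogram
# ---------------------------------------------------------------------------

def taxonomy_to_cladogram(
    annotation: TaxonAnnotation,
    branch_length_per_rank: float = 1.0,
) -> TreeNode:
    """Build a cladogram from ranked lineages.

    One internal node is created per distinct rank path; every edge
    (including the terminal tip edge) gets ``branch_length_per_rank``.
    Taxa with unresolved deep ranks attach directly below their deepest
    resolved rank, so unknown ranks never create one-child chains.  Two
    taxa sharing a genus are therefore two unit-length tip edges apart,
    and two fully resolved taxa sharing only a kingdom are twelve.
    """
    if branch_length_per_rank <= 0:
        raise ValueError("branch_length_per_rank must be positive")
    if len(annotation.data) == 0:
        raise ValidationError("empty annotation")

    root = TreeNode(name="root", length=None)
    nodes: dict[tuple[str, ...], TreeNode] = {(): root}
    for taxon_id in annotation.taxon_ids:
        path = annotation.lineage(taxon_id)
        parent = root
        for depth in range(1, len(path) + 1):
            key = tuple(path[:depth])
            node = nodes.get(key)
            if node is None:
                node = TreeNode(
                    name="|".join(key), length=float(branch_length_per_rank)
                )
                parent.append(node)
                nodes[key] = node
            parent = node
        tip = TreeNode(name=str(taxon_id), length=float(branch_length_per_rank))
        parent.append(tip)
    return root


def patristic_distances(tree: TreeNode, taxon_ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Tip-to-tip path-length distances, optionally restricted and reordered."""
    dm = tree.tip_tip_distances()
    if taxon_ids is not None:
        missing = [t for t in taxon_ids if t not in set(dm.ids)]
        if missing:
            raise ValidationError(f"taxon {missing[0]!r} is not a tip of the tree")
        dm = dm.filter(list(taxon_ids))
    return dm


# ---------------------------------------------------------------------------
# distance-matrix TSV round-trip
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
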