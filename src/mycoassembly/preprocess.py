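"""The two dataset preparations: rarefied counts and zero-imputed CLR.

High-throughput amplicon tables can be treated either as counts — in
which case samples are rarefied to a common depth so richness and
dissimilarity are comparable — or as compositions, in which case zeros
are imputed and rows are mapped to centred log-ratios.  Both routes are
provided, along with the Hellinger / relative transforms and functional-
guild subsetting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import CommunityTable, TableMode, TaxonAnnotation, GUILDS

__all__ = ["rarefy", "clr_transform", "transform", "subset_by_guild"]

logger = logging.getLogger(__name__)


def _require_counts(table: CommunityTable, op: str) -> None:
    if table.mode is not TableMode.counts:
        raise ValueError(f"{op} requires a counts-mode table, got {table.mode.value}")


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int | np.random.Generator = 0,
    on_short: str = "error",
) -> CommunityTable:
    """Subsample every sample without replacement to a fixed depth.

    Equivalent to drawing ``depth`` individuals from each sample's count
    vector hypergeometrically, so a taxon's expected rarefied count is
    depth times its relative abundance.  Samples whose total is below
    ``depth`` either raise (default) or are dropped (``on_short="drop"``).
    """
    _require_counts(table, "rarefy")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if on_short not in ("error", "drop"):
        raise ValueError("on_short must be 'error' or 'drop'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = np.rint(table.values).astype(np.int64)
    if not np.allclose(counts, table.values):
        raise ValueError("rarefy requires integer counts")
    totals = counts.sum(axis=1)
    short = totals < depth
    if short.any():
        names = [table.sample_ids[i] for i in np.flatnonzero(short)]
        if on_short == "error":
            raise ValueError(
                f"sample {names[0]!r} has only {int(totals[short][0])} reads, "
                f"fewer than depth {depth}"
            )
        logger.warning("rarefy: dropping %d short samples: %s", len(names), names)
    keep = ~short
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(counts[keep]):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(
        out.astype(float),
        index=table.data.index[keep],
        columns=table.data.columns,
    )
    return CommunityTable(df, TableMode.counts)


def clr_transform(
    table: CommunityTable,
    zero_method: str = "czm_multiplicative",
    pseudo_count: float = 0.5,
) -> CommunityTable:
    """Zero-imputed centred log-ratio transform.

    Zeros are replaced by the count-zero multiplicative method: each zero
    becomes the pseudo-proportion ``pseudo_count / row_total`` (strictly
    below the smallest observed proportion since observed counts are at
    least 1), and the nonzero proportions are rescaled so the row stays
    on the simplex.  Then clr(x)_i = ln x_i - mean_j ln x_j, so every
    output row sums to zero.
    """
    _require_counts(table, "clr_transform")
    if zero_method != "czm_multiplicative":
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if not (0 < pseudo_count < 1):
        raise ValueError("pseudo_count must lie in (0, 1)")
    counts = table.values
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has no nonzero taxon")
    props = counts / totals[:, None]
    zero = counts == 0
    delta = pseudo_count / totals  # pseudo-proportion per sample
    imputed = props.copy()
    for i in range(props.shape[0]):
        z = zero[i]
        if z.any():
            shrink = 1.0 - delta[i] * z.sum()
            imputed[i, ~z] = props[i, ~z] * shrink
            imputed[i, z] = delta[i]
    logim = np.log(imputed)
    clr = logim - logim.mean(axis=1, keepdims=True)
    df = pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)
    return CommunityTable(df, TableMode.clr)


def transform(table: CommunityTable, kind: str) -> CommunityTable:
    """Row-normalize (``relative``) or Hellinger-transform (``hellinger``)."""
    _require_counts(table, "transform")
    totals = table.values.sum(axis=1)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    rel = table.values / totals[:, None]
    if kind == "relative":
        out, mode = rel, TableMode.relative
    elif kind == "hellinger":
        # rows of sqrt(relative); squared values of each row sum to 1.
        # Not a simplex, so kept in the unconstrained counts mode.
        out, mode = np.sqrt(rel), TableMode.counts
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return CommunityTable(df, mode)


def subset_by_guild(
    table: CommunityTable,
    annotation: TaxonAnnotation,
    guild: str,
) -> CommunityTable:
    """Restrict columns to taxa of one functional guild.

    Samples left with zero total abundance are dropped; the number
    dropped is logged.
    """
    if guild not in GUILDS:
        raise ValueError(f"unknown guild {guild!r}; valid guilds: {list(GUILDS)}")
    members = [
        t for t in table.taxon_ids
        if t in annotation.data.index and annotation.data.loc[t, "guild"] == guild
    ]
    if not members:
        raise ValueError(
            f"guild {guild!r} has no member taxa in this table; "
            f"valid guilds: {list(GUILDS)}"
        )
    sub = table.data[members]
    if table.mode in (TableMode.counts, TableMode.relative):
        totals = sub.to_numpy().sum(axis=1)
        empty = totals <= 0
        if empty.any():
            logger.warning(
                "subset_by_guild(%s): dropping %d samples with zero total",
                guild,
                int(empty.sum()),
            )
            sub = sub.loc[~empty]
        if table.mode is TableMode.relative:
            sub = sub.div(sub.sum(axis=1), axis=0)
    return CommunityTable(sub.copy(), table.mode)
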