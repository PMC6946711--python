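"""Pairwise community dissimilarities and the richness-free turnover split.

Bray–Curtis and binary Jaccard act on (rarefied) counts, Aitchison
distance is Euclidean distance between CLR rows, and the Sørensen
dissimilarity is partitioned into its Simpson (pure turnover) and
nestedness components.  The Simpson metric is the piece that is
insensitive to richness differences between the two samples, which is
what makes it suitable for comparing compositional variance across
communities of very different sizes.  A Gst-type "community Fst" based
on the probability that two random individuals differ in species
identity is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .datamodel import CommunityTable, TableMode

__all__ = [
    "pairwise_dissimilarity",
    "BetaPartition",
    "sorensen_partition",
    "community_fst",
]

_METRIC_MODES = {
    "bray_curtis": (TableMode.counts, TableMode.relative),
    "jaccard_binary": (TableMode.counts, TableMode.relative),
    "aitchison": (TableMode.clr,),
    "euclidean": (TableMode.counts, TableMode.relative, TableMode.clr),
}


def pairwise_dissimilarity(table: CommunityTable, metric: str) -> DistanceMatrix:
    """All-pairs dissimilarity under one of the supported metrics.

    ``aitchison`` requires a CLR-mode table (it is the Euclidean distance
    between CLR rows); ``bray_curtis`` and ``jaccard_binary`` require
    counts or relative mode.
    """
    if metric not in _METRIC_MODES:
        raise ValueError(f"unknown metric {metric!r}")
    if table.mode not in _METRIC_MODES[metric]:
        raise ValueError(
            f"metric {metric!r} is incompatible with table mode {table.mode.value!r}"
        )
    X = table.values
    if metric == "bray_curtis":
        cond = pdist(X, metric="braycurtis")
    elif metric == "jaccard_binary":
        cond = pdist(X > 0, metric="jaccard")
    else:  # aitchison, euclidean
        cond = pdist(X, metric="euclidean")
    return DistanceMatrix(squareform(np.nan_to_num(cond)), ids=table.sample_ids)


@dataclass
class BetaPartition:
    """Per-pair Sørensen dissimilarity split into turnover + nestedness.

    ``sor = sim + sne`` holds exactly; each field is a square labelled
    DataFrame over the sample set.
    """

    sim: pd.DataFrame
    sne: pd.DataFrame
    sor: pd.DataFrame


def sorensen_partition(table: CommunityTable) -> BetaPartition:
    """Baselga's partition of Sørensen dissimilarity from presence data.

    With a shared taxa and b, c unique to each sample:
    beta_sim = min(b,c) / (a + min(b,c));
    beta_sor = (b + c) / (2a + b + c); beta_sne = beta_sor - beta_sim.
    Presence is strictly positive abundance.
    """
    pres = (table.values > 0)
    if (~pres.any(axis=1)).any():
        bad = table.sample_ids[int(np.argmax(~pres.any(axis=1)))]
        raise ValueError(f"sample {bad!r} is empty; partition undefined")
    P = pres.astype(np.int64)
    A = P @ P.T  # shared counts
    rich = P.sum(axis=1)
    B = rich[:, None] - A
    C = rich[None, :] - A
    mn = np.minimum(B, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = mn / (A + mn)
        sor = (B + C) / (2 * A + B + C)
    sim = np.nan_to_num(sim)  # identical empty-intersection handled above
    sor = np.nan_to_num(sor)
    np.fill_diagonal(sim, 0.0)
    np.fill_diagonal(sor, 0.0)
    sne = sor - sim
    ids = table.sample_ids
    return BetaPartition(
        sim=pd.DataFrame(sim, index=ids, columns=ids),
        sne=pd.DataFrame(sne, index=ids, columns=ids),
        sor=pd.DataFrame(sor, index=ids, columns=ids),
    )


def community_fst(table: CommunityTable, pooled: bool = False) -> DistanceMatrix:
    """Gst-type differentiation between pairs of communities.

    For a pair with relative-abundance vectors p1, p2 and mean p̄:
    H_T = 1 - sum(p̄^2); H_S = mean of the two within-sample
    heterozygosities 1 - sum(p^2); Fst = (H_T - H_S) / H_T.  Two
    monocultures of different taxa give Fst = 1; identical communities
    give 0 (including the degenerate shared-monoculture case H_T = 0).

    ``pooled=True`` replaces the pairwise mean p̄ with the grand mean
    over all samples in the table.
    """
    if table.mode not in (TableMode.counts, TableMode.relative):
        raise ValueError("community_fst requires counts or relative mode")
    X = table.values.astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    P = X / totals[:, None]
    n = P.shape[0]
    hs_each = 1.0 - (P**2).sum(axis=1)
    out = np.zeros((n, n))
    grand = P.mean(axis=0)
    for i in range(n):
        for j in range(i + 1, n):
            pbar = grand if pooled else 0.5 * (P[i] + P[j])
            ht = 1.0 - (pbar**2).sum()
            hs = 0.5 * (hs_each[i] + hs_each[j])
            fst = 0.0 if ht <= 1e-15 else (ht - hs) / ht
            out[i, j] = out[j, i] = min(max(fst, 0.0), 1.0)
    return DistanceMatrix(out, ids=table.sample_ids)
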