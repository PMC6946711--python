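"""Phylogenetic and taxonomic null models for community-assembly inference.

Two standardized pairwise indices drive the inference:

* beta-NTI — the z-score of the observed beta mean nearest taxon
  distance (betaMNTD) against a null in which tip labels are shuffled
  across the whole phylogeny.  |betaNTI| >= 2 indicates that selection
  structures the pair (negative: phylogenetically clustered, homogeneous
  selection; positive: overdispersed, variable selection).

* Raup–Crick index (RCI) — a quantile score in [-1, 1] comparing the
  observed compositional similarity of a pair with richness-preserving
  null assemblages.  RCI <= -0.95: the pair shares more species than
  chance (homogenizing processes); RCI >= 0.95: fewer than chance
  (dispersal limitation); |RCI| < 0.95: indistinguishable from chance.

Pairs with |betaNTI| < 2 and |RCI| < 0.95 are not dominated by either
dimension of selection or dispersal; their compositional variance is
attributed to stochasticity (drift and/or stochastic colonization).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .datamodel import CommunityTable, SampleMetadata, TableMode, patristic_distances

__all__ = [
    "NullModelResult",
    "ProcessSummary",
    "PROCESS_CLASSES",
    "beta_mntd",
    "bnti",
    "raup_crick",
    "classify_processes",
    "stochastic_fraction",
    "within_group_pairs",
]


def within_group_pairs(
    metadata: SampleMetadata, group_by: list[str]
) -> list[tuple[str, str]]:
    """All unordered sample pairs sharing every ``group_by`` value."""
    md = metadata.data
    pairs: list[tuple[str, str]] = []
    for _, members in md.groupby(group_by, sort=True).groups.items():
        mm = list(members)
        pairs.extend((mm[i], mm[j]) for i in range(len(mm)) for j in range(i + 1, len(mm)))
    return pairs

logger = logging.getLogger(__name__)

PROCESS_CLASSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "stochastic_undominated",
    "selection_or_dispersal_ambiguous",
)

#: degenerate-null guard: below this null sd the z-score is undefined
_SD_EPS = 1e-12


@dataclass
class NullModelResult:
    """Per-pair observed statistic, null moments, and standardized score.

    ``score`` is betaNTI (z-score) or RCI (scaled quantile) depending on
    ``kind``; entries whose null distribution collapsed (sd < 1e-12) are
    flagged ``degenerate`` and carry NaN scores.
    """

    pairs: list[tuple[str, str]]
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    reps: int
    score: np.ndarray
    degenerate: np.ndarray
    kind: str

    def to_frame(self) -> pd.DataFrame:
        a, b = zip(*self.pairs) if self.pairs else ((), ())
        return pd.DataFrame(
            {
                "sample_a": a,
                "sample_b": b,
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                self.kind: self.score,
                "degenerate": self.degenerate,
            }
        )


@dataclass
class ProcessSummary:
    """Fractions of pairs per assembly-process class within one group."""

    group_key: tuple
    fractions: dict[str, float]
    pair_count: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.pair_count > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("process fractions must sum to 1")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _sample_profiles(table: CommunityTable) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-sample present-taxon indices and normalized abundance weights."""
    X = table.values
    idxs, weights = [], []
    for row in X:
        idx = np.flatnonzero(row > 0)
        if idx.size == 0:
            raise ValueError("betaMNTD undefined for an empty sample")
        w = row[idx].astype(float)
        idxs.append(idx)
        weights.append(w / w.sum())
    return idxs, weights


def _pair_bmntd(
    D: np.ndarray,
    ia: np.ndarray,
    wa: np.ndarray,
    ib: np.ndarray,
    wb: np.ndarray,
    weighted: bool,
) -> float:
    sub = D[np.ix_(ia, ib)]
    da = sub.min(axis=1)
    db = sub.min(axis=0)
    if weighted:
        return 0.5 * (float(wa @ da) + float(wb @ db))
    return 0.5 * (float(da.mean()) + float(db.mean()))


def _resolve_pairs(
    table: CommunityTable, pairs: list[tuple[str, str]] | None
) -> list[tuple[int, int]]:
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    if pairs is None:
        return list(itertools.combinations(range(len(pos)), 2))
    out = []
    for a, b in pairs:
        if a not in pos or b not in pos:
            missing = a if a not in pos else b
            raise ValueError(f"unknown sample id {missing!r} in pair list")
        out.append((pos[a], pos[b]))
    return out


def beta_mntd(
    table: CommunityTable,
    tree: TreeNode,
    weighted: bool = True,
) -> DistanceMatrix:
    """Beta mean nearest taxon distance between all sample pairs.

    For each taxon present in sample A the patristic distance to its
    nearest taxon in sample B is taken; these are averaged (abundance-
    weighted when ``weighted``) and symmetrized over both directions.
    """
    D = patristic_distances(tree, table.taxon_ids).data
    idxs, weights = _sample_profiles(table)
    n = len(idxs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _pair_bmntd(D, idxs[i], weights[i], idxs[j], weights[j], weighted)
            out[i, j] = out[j, i] = v
    return DistanceMatrix(out, ids=table.sample_ids)


def bnti(
    table: CommunityTable,
    tree: TreeNode,
    reps: int = 999,
    weighted: bool = True,
    seed: int | np.random.SeedSequence = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> NullModelResult:
    """betaNTI: z-score of betaMNTD against a tip-shuffling null.

    The null randomly re-places taxa on the phylogeny (a single label
    permutation applied to the patristic matrix per replicate, shared by
    all pairs of that replicate).  Pairs whose null sd collapses — for
    example on a star phylogeny, where the statistic is invariant to
    relabeling — are flagged degenerate with an undefined score.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(table.sample_ids) < 2:
        raise ValueError("betaNTI requires at least two samples")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    D = patristic_distances(tree, table.taxon_ids).data
    idxs, weights = _sample_profiles(table)
    pair_idx = _resolve_pairs(table, pairs)
    npairs = len(pair_idx)
    S = D.shape[0]

    observed = np.array(
        [_pair_bmntd(D, idxs[i], weights[i], idxs[j], weights[j], weighted) for i, j in pair_idx]
    )
    acc = np.zeros(npairs)
    acc2 = np.zeros(npairs)
    for _ in range(reps):
        perm = rng.permutation(S)
        for k, (i, j) in enumerate(pair_idx):
            v = _pair_bmntd(D, perm[idxs[i]], weights[i], perm[idxs[j]], weights[j], weighted)
            acc[k] += v
            acc2[k] += v * v
    mean = acc / reps
    var = acc2 / reps - mean**2
    if reps > 1:
        var = var * reps / (reps - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    degenerate = sd < _SD_EPS
    score = np.full(npairs, np.nan)
    ok = ~degenerate
    score[ok] = (observed[ok] - mean[ok]) / sd[ok]
    labels = [(table.sample_ids[i], table.sample_ids[j]) for i, j in pair_idx]
    return NullModelResult(labels, observed, mean, sd, reps, score, degenerate, "bnti")


# ---------------------------------------------------------------------------
# Raup–Crick
# ---------------------------------------------------------------------------

def _null_presence_draws(
    rng: np.random.Generator, logw: np.ndarray, k: int, reps: int
) -> np.ndarray:
    """reps x S boolean matrix of k-taxon draws without replacement,
    probability proportional to exp(logw), via the Gumbel-top-k trick."""
    S = logw.size
    keys = rng.gumbel(size=(reps, S)) + logw
    top = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    out = np.zeros((reps, S), dtype=bool)
    rows = np.repeat(np.arange(reps), k)
    out[rows, top.ravel()] = True
    return out


def raup_crick(
    table: CommunityTable,
    reps: int = 999,
    variant: str = "presence_occupancy",
    seed: int | np.random.SeedSequence = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> NullModelResult:
    """Raup–Crick index against richness-preserving null assemblages.

    ``presence_occupancy`` (default): null communities preserve each
    sample's richness and draw taxa with probability proportional to
    their occupancy frequency across all samples; the observed number of
    shared taxa is ranked within the null distribution of shared taxa.

    ``abundance_bray``: nulls preserve richness and total abundance;
    after seeding each chosen taxon with one individual the remaining
    individuals are drawn proportional to pool-wide relative abundance,
    and the observed Bray–Curtis dissimilarity is ranked within the null.

    Both are scaled to RCI = 2 * ((n_null_more_similar + 0.5 * ties) /
    reps) - 1, so RCI = -1 means the observed pair is more similar than
    every null realization.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if variant not in ("presence_occupancy", "abundance_bray"):
        raise ValueError(f"unknown variant {variant!r}")
    if table.mode not in (TableMode.counts, TableMode.relative):
        raise ValueError("raup_crick requires counts or relative mode")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    X = table.values
    pres = X > 0
    rich = pres.sum(axis=1)
    if (rich == 0).any():
        bad = table.sample_ids[int(np.argmax(rich == 0))]
        raise ValueError(f"sample {bad!r} has zero richness")
    occupancy = pres.sum(axis=0).astype(float)
    with np.errstate(divide="ignore"):
        logw = np.log(occupancy)  # -inf excludes never-observed taxa
    pool_rel = X.sum(axis=0)
    pool_rel = pool_rel / pool_rel.sum()
    pair_idx = _resolve_pairs(table, pairs)

    npairs = len(pair_idx)
    observed = np.empty(npairs)
    mean = np.empty(npairs)
    sd = np.empty(npairs)
    score = np.empty(npairs)

    totals = np.rint(X.sum(axis=1)).astype(int)
    for k, (i, j) in enumerate(pair_idx):
        child = np.random.default_rng(rng.integers(0, 2**63))
        if variant == "presence_occupancy":
            obs = float(np.count_nonzero(pres[i] & pres[j]))
            na = _null_presence_draws(child, logw, int(rich[i]), reps)
            nb = _null_presence_draws(child, logw, int(rich[j]), reps)
            null = (na & nb).sum(axis=1).astype(float)
            more_similar = null > obs
            ties = null == obs
        else:
            ab = X[i] + X[j]
            obs = float(np.abs(X[i] - X[j]).sum() / ab.sum()) if ab.sum() else 0.0
            null = np.empty(reps)
            for r in range(reps):
                va = _null_abundance_vector(child, logw, pool_rel, int(rich[i]), int(totals[i]))
                vb = _null_abundance_vector(child, logw, pool_rel, int(rich[j]), int(totals[j]))
                s = va + vb
                null[r] = np.abs(va - vb).sum() / s.sum() if s.sum() else 0.0
            more_similar = null < obs
            ties = np.isclose(null, obs)
            more_similar &= ~ties
        observed[k] = obs
        mean[k] = null.mean()
        sd[k] = null.std(ddof=1) if reps > 1 else 0.0
        score[k] = 2.0 * ((more_similar.sum() + 0.5 * ties.sum()) / reps) - 1.0

    degenerate = sd < _SD_EPS
    labels = [(table.sample_ids[i], table.sample_ids[j]) for i, j in pair_idx]
    return NullModelResult(labels, observed, mean, sd, reps, score, degenerate, "rci")


def _null_abundance_vector(
    rng: np.random.Generator,
    logw: np.ndarray,
    pool_rel: np.ndarray,
    k: int,
    total: int,
) -> np.ndarray:
    """Null community of ``k`` taxa and ``total`` individuals."""
    S = logw.size
    keys = rng.gumbel(size=S) + logw
    chosen = np.argpartition(-keys, k - 1)[:k]
    vec = np.zeros(S)
    vec[chosen] = 1.0
    remaining = max(total - k, 0)
    if remaining:
        p = pool_rel[chosen]
        p = p / p.sum() if p.sum() > 0 else np.full(k, 1.0 / k)
        vec[chosen] += rng.multinomial(remaining, p)
    return vec


# ---------------------------------------------------------------------------
# process classification
# ---------------------------------------------------------------------------

def classify_processes(
    bnti_result: NullModelResult,
    rci_result: NullModelResult,
    bnti_threshold: float = 2.0,
    rci_threshold: float = 0.95,
) -> tuple[pd.DataFrame, ProcessSummary]:
    """Assign each pair to an assembly-process class.

    betaNTI >= 2: variable selection; betaNTI <= -2: homogeneous
    selection.  Otherwise the taxonomic null decides: RCI >= 0.95 is
    dispersal limitation, RCI <= -0.95 is the ambiguous homogenizing
    class (homogeneous selection or homogenizing dispersal — phylogeny
    gives no signal to separate them), and |RCI| < 0.95 leaves the pair
    stochastic/undominated.  Degenerate betaNTI pairs are classified on
    RCI alone (logged).
    """
    if bnti_result.pairs != rci_result.pairs:
        raise ValueError("betaNTI and RCI results cover different pair sets")
    rows = []
    n_degenerate = 0
    for (a, b), bn, rc, bobs, deg in zip(
        bnti_result.pairs,
        bnti_result.score,
        rci_result.score,
        bnti_result.observed,
        bnti_result.degenerate,
    ):
        if deg or np.isnan(bn):
            n_degenerate += 1
            if rc >= rci_threshold:
                cls = "dispersal_limitation"
            elif rc <= -rci_threshold:
                cls = "selection_or_dispersal_ambiguous"
            else:
                cls = "stochastic_undominated"
        elif bn >= bnti_threshold:
            cls = "variable_selection"
        elif bn <= -bnti_threshold:
            cls = "homogeneous_selection"
        elif rc >= rci_threshold:
            cls = "dispersal_limitation"
        elif rc <= -rci_threshold:
            cls = "selection_or_dispersal_ambiguous"
        else:
            cls = "stochastic_undominated"
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "bmntd": bobs,
                "bnti": bn,
                "rci": rc,
                "process": cls,
            }
        )
    if n_degenerate:
        logger.info(
            "classify_processes: %d pairs with degenerate betaNTI null "
            "classified on RCI alone",
            n_degenerate,
        )
    pair_table = pd.DataFrame(rows)
    counts = pair_table["process"].value_counts()
    n = len(pair_table)
    fractions = {c: float(counts.get(c, 0)) / n if n else 0.0 for c in PROCESS_CLASSES}
    return pair_table, ProcessSummary(("all",), fractions, n)


def stochastic_fraction(
    pair_table: pd.DataFrame,
    metadata: SampleMetadata,
    group_by: list[str],
) -> pd.DataFrame:
    """Per-group fractions of pairs in each process class.

    Only within-group pairs (both samples sharing every ``group_by``
    value) contribute.  Groups with fewer than two samples are skipped
    with a warning.  Returns one row per group with the class-fraction
    columns, the stochastic fraction, and the pair count.
    """
    md = metadata.data
    for col in group_by:
        if col not in md.columns:
            raise ValueError(f"metadata has no column {col!r}")
    rows = []
    for key, group_samples in md.groupby(group_by, sort=True).groups.items():
        key_t = key if isinstance(key, tuple) else (key,)
        if len(group_samples) < 2:
            logger.warning("group %s has < 2 samples; skipped", key_t)
            continue
        members = set(group_samples)
        sel = pair_table[
            pair_table["sample_a"].isin(members) & pair_table["sample_b"].isin(members)
        ]
        n = len(sel)
        if n == 0:
            continue
        counts = sel["process"].value_counts()
        row = {col: val for col, val in zip(group_by, key_t)}
        for c in PROCESS_CLASSES:
            row[c] = float(counts.get(c, 0)) / n
        row["stochastic_fraction"] = row["stochastic_undominated"]
        row["n_pairs"] = n
        rows.append(row)
    return pd.DataFrame(rows)
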