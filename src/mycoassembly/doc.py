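"""Dissimilarity–overlap curve (DOC) analysis.

For every pair of communities the overlap — the mean total relative
abundance of the taxa the two samples share — is plotted against the
root Jensen–Shannon divergence of the pair restricted (and renormalized)
to those shared taxa.  If all communities obey the same underlying
ecological dynamics, pairs that share most of their taxa should also
agree on the shared taxa's relative abundances, so the smoothed curve
bends downwards at high overlap.  The fraction of pairs lying beyond the
point where the negative slope begins (Fns) quantifies the support for
such universal dynamics; the change point itself is the median over
bootstrap replicates that resample whole samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datamodel import CommunityTable, TableMode

__all__ = ["overlap_dissimilarity_pairs", "fit_doc", "DOCResult", "bonferroni"]

#: upper bound of the root Jensen–Shannon divergence with natural log
RJSD_MAX = float(np.sqrt(np.log(2.0)))


@dataclass
class DOCResult:
    """Smoothed curve, change point, Fns and bootstrap significance."""

    points: pd.DataFrame
    curve: pd.DataFrame
    x_min: float
    fns: float
    p_value: float
    significant: bool
    bootstrap_reps: int
    excluded_pairs: int


def overlap_dissimilarity_pairs(
    table: CommunityTable,
) -> tuple[pd.DataFrame, int]:
    """Per-pair overlap and shared-taxon root Jensen–Shannon divergence.

    Overlap of samples a, b with shared taxon set S is
    ``sum_{i in S} (a_i + b_i) / 2``; the dissimilarity is the root JSD
    (natural log) of the two abundance vectors renormalized over S.
    Pairs with zero overlap carry no shared information and are
    excluded; the count of exclusions is returned alongside the points.
    """
    if table.mode is not TableMode.relative:
        raise ValueError("overlap_dissimilarity_pairs requires a relative-mode table")
    X = table.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    ids = table.sample_ids
    rows = []
    excluded = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = X[i], X[j]
        shared = (a > 0) & (b > 0)
        if not shared.any():
            excluded += 1
            continue
        overlap = 0.5 * float(a[shared].sum() + b[shared].sum())
        if overlap <= 0:
            excluded += 1
            continue
        pa = a[shared] / a[shared].sum()
        pb = b[shared] / b[shared].sum()
        rjsd = float(jensenshannon(pa, pb))
        if np.isnan(rjsd):  # identical one-taxon vectors
            rjsd = 0.0
        rows.append((ids[i], ids[j], overlap, rjsd))
    points = pd.DataFrame(rows, columns=["sample_a", "sample_b", "overlap", "rjsd"])
    return points, excluded


def _fit_curve(points: pd.DataFrame, span: float) -> pd.DataFrame:
    """LOWESS fit of rjsd on overlap, evaluated at the observed overlaps."""
    x = points["overlap"].to_numpy()
    y = points["rjsd"].to_numpy()
    fitted = lowess(y, x, frac=span, it=2, return_sorted=True)
    # collapse duplicate x to their mean fit
    df = pd.DataFrame(fitted, columns=["overlap", "fitted"])
    return df.groupby("overlap", as_index=False)["fitted"].mean()


def _negative_slope_onset(curve: pd.DataFrame) -> float | None:
    """Smallest overlap from which the fitted slope stays negative to the
    end of the curve; None when the terminal slope is not negative."""
    x = curve["overlap"].to_numpy()
    y = curve["fitted"].to_numpy()
    if x.size < 2:
        return None
    slopes = np.diff(y)
    if slopes[-1] >= 0:
        return None
    k = slopes.size - 1
    while k >= 0 and slopes[k] < 0:
        k -= 1
    return float(x[k + 1])


def fit_doc(
    points: pd.DataFrame,
    smoothing_span: float = 0.2,
    bootstrap_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    excluded_pairs: int = 0,
) -> DOCResult:
    """Fit the DOC, locate the change point, and bootstrap significance.

    The curve is a locally weighted (LOWESS) regression of rJSD on
    overlap.  Each bootstrap resamples *samples* (not pairs, which are
    not independent), rebuilds the pair set among the resampled samples,
    refits, and records the overlap at which the terminal negative slope
    begins; the reported change point ``x_min`` is the bootstrap median
    (bootstraps without a negative terminal slope contribute the maximum
    observed overlap).  Fns is the fraction of real pairs with overlap
    beyond ``x_min``, and the analysis is significant when at least 95%
    of bootstrap curves end in a negative slope (p = the complementary
    fraction).
    """
    if not (0 < smoothing_span <= 1):
        raise ValueError("smoothing_span must lie in (0, 1]")
    if bootstrap_reps < 1:
        raise ValueError("bootstrap_reps must be >= 1")
    if len(points) < 10:
        raise ValueError("need at least 10 pairs to fit a DOC")
    if points["overlap"].nunique() < 2:
        raise ValueError("all pairs share one overlap value; no slope estimable")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    curve = _fit_curve(points, smoothing_span)
    x_max = float(points["overlap"].max())

    samples = sorted(set(points["sample_a"]) | set(points["sample_b"]))

    x_mins = np.empty(bootstrap_reps)
    negative_terminal = 0
    for b in range(bootstrap_reps):
        chosen = rng.choice(samples, size=len(samples), replace=True)
        uniq = sorted(set(chosen))
        mask = points["sample_a"].isin(uniq) & points["sample_b"].isin(uniq)
        sub = points[mask]
        if len(sub) < 3 or sub["overlap"].nunique() < 2:
            x_mins[b] = x_max
            continue
        bcurve = _fit_curve(sub, smoothing_span)
        onset = _negative_slope_onset(bcurve)
        if onset is None:
            x_mins[b] = x_max
        else:
            negative_terminal += 1
            x_mins[b] = onset

    x_min = float(np.median(x_mins))
    fns = float((points["overlap"] > x_min).mean())
    p_value = 1.0 - negative_terminal / bootstrap_reps
    return DOCResult(
        points=points,
        curve=curve,
        x_min=x_min,
        fns=fns,
        p_value=p_value,
        significant=p_value <= 0.05,
        bootstrap_reps=bootstrap_reps,
        excluded_pairs=excluded_pairs,
    )


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni adjustment across a family of DOC analyses."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
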