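"""Supporting multivariate and model-based statistics.

Sequential (Type-I) PERMANOVA on arbitrary distance matrices, Mantel
tests, multivariate dispersion (betadisper with the imaginary-axis
correction), principal coordinates, the stochasticity-versus-community-
size mixed model, CLR co-abundance network clustering, and the random-
forest community-age delay protocol used to quantify how far drought
sets community development back in time.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .datamodel import CommunityTable, SampleMetadata, TableMode

__all__ = [
    "permanova",
    "mantel",
    "beta_dispersion",
    "pcoa",
    "mixed_stochasticity_model",
    "cooccurrence_clusters",
    "age_delay_protocol",
    "OTU_WISE_P_CUTOFF",
]

logger = logging.getLogger(__name__)

#: default OTU-wise significance cutoff (0.05 Bonferroni-divided across
#: ~1000 OTU tests)
OTU_WISE_P_CUTOFF = 5e-5


# ---------------------------------------------------------------------------
# PERMANOVA (sequential, adonis-style)
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(X: np.ndarray) -> np.ndarray:
    # pseudo-inverse guards against rank deficiency among dummy columns
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _design_columns(values: pd.Series) -> np.ndarray:
    """Dummy-code a factor (numeric columns enter as a single covariate)."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)[:, None]
    return pd.get_dummies(values.astype(str), drop_first=True).to_numpy(dtype=float)


def _sequential_stats(
    G: np.ndarray, term_cols: list[np.ndarray], dfs: list[int]
) -> tuple[np.ndarray, float, np.ndarray]:
    """Sequential term SS, residual SS and per-term pseudo-F from the
    Gower-centered matrix (McArdle & Anderson trace decomposition)."""
    n = G.shape[0]
    ss_total = float(np.trace(G))
    ones = np.ones((n, 1))
    X = ones
    prev_ss = 0.0
    ss_terms = np.empty(len(term_cols))
    for k, cols in enumerate(term_cols):
        X = np.hstack([X, cols])
        ss_model = float(np.trace(_hat(X) @ G))
        ss_terms[k] = ss_model - prev_ss
        prev_ss = ss_model
    ss_resid = ss_total - prev_ss
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_terms / np.asarray(dfs)) / ms_resid if ms_resid > 0 else np.full(
            len(dfs), np.inf
        )
    return ss_terms, ss_resid, f


def permanova(
    dist: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    terms: list[str],
    permutations: int | str = 999,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Sequential (Type-I) permutational multivariate ANOVA.

    Terms are fitted in the order given; each term's SS is the increase
    in explained trace of the Gower-centered squared-distance matrix, so
    R-squared values (terms + residual) sum to one.  p-values come from
    free permutation of sample labels, reported as (b + 1) / (m + 1);
    ``permutations="all"`` enumerates every relabeling (small n only)
    and reports the exact proportion of permuted pseudo-F >= observed.
    """
    md = metadata.data if isinstance(metadata, SampleMetadata) else metadata
    ids = list(dist.ids)
    missing = [s for s in ids if s not in md.index]
    if missing:
        raise ValueError(f"metadata missing sample {missing[0]!r}")
    md = md.loc[ids]
    term_cols = []
    dfs = []
    for t in terms:
        if t not in md.columns:
            raise ValueError(f"metadata has no column {t!r}")
        if md[t].nunique() < 2:
            raise ValueError(f"term {t!r} has a single level")
        cols = _design_columns(md[t])
        term_cols.append(cols)
        dfs.append(cols.shape[1])

    G = _gower_center(dist.data)
    n = G.shape[0]
    ss_terms, ss_resid, f_obs = _sequential_stats(G, term_cols, dfs)
    ss_total = float(np.trace(G))

    def f_for(perm: np.ndarray) -> np.ndarray:
        Gp = G[np.ix_(perm, perm)]
        return _sequential_stats(Gp, term_cols, dfs)[2]

    if permutations == "all":
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            fp = f_for(np.array(perm))
            count += fp >= f_obs - 1e-12
            total += 1
        pvals = count / total
    else:
        m = int(permutations)
        if m < 1:
            raise ValueError("permutations must be >= 1")
        rng = np.random.default_rng(
            seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        )
        count = np.zeros(len(terms))
        for _ in range(m):
            fp = f_for(rng.permutation(n))
            count += fp >= f_obs - 1e-12
        pvals = (count + 1) / (m + 1)

    rows = []
    for t, df_t, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append(
            {"term": t, "df": df_t, "ss": ss, "r2": ss / ss_total, "pseudo_f": f, "p": p}
        )
    rows.append(
        {
            "term": "residual",
            "df": n - 1 - sum(dfs),
            "ss": ss_resid,
            "r2": ss_resid / ss_total,
            "pseudo_f": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    permutations: int | str = 999,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Correlates lower-triangle entries (Pearson or Spearman); the null
    permutes rows and columns of the second matrix jointly.  p is
    (b + 1)/(m + 1), or the exact enumeration proportion with
    ``permutations="all"``.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share the same label set")
    d2 = d2.filter(list(d1.ids))
    A = d1.data
    B = d2.data
    n = A.shape[0]
    tri = np.tril_indices(n, k=-1)

    def corr(b: np.ndarray) -> float:
        if method == "pearson":
            return float(sps.pearsonr(A[tri], b[tri])[0])
        if method == "spearman":
            return float(sps.spearmanr(A[tri], b[tri])[0])
        raise ValueError(f"unknown method {method!r}")

    r_obs = corr(B)
    if permutations == "all":
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            count += corr(B[np.ix_(p, p)]) >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    m = int(permutations)
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    count = 0
    for _ in range(m):
        p = rng.permutation(n)
        count += corr(B[np.ix_(p, p)]) >= r_obs - 1e-12
    return r_obs, (count + 1) / (m + 1)


# ---------------------------------------------------------------------------
# PCoA and beta dispersion
# ---------------------------------------------------------------------------

def pcoa(
    dist: DistanceMatrix | np.ndarray,
    correction: str = "none",
    ids: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates: eigendecomposition of the Gower matrix.

    Returns coordinates on the positive-eigenvalue axes (sorted
    descending) and the full eigenvalue spectrum.  ``lingoes`` adds the
    constant that makes all eigenvalues non-negative before re-embedding
    (correcting a non-Euclidean input).
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.data
        labels = list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        labels = ids if ids is not None else [str(i) for i in range(d.shape[0])]
    if correction not in ("none", "lingoes"):
        raise ValueError(f"unknown correction {correction!r}")
    G = _gower_center(d)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if correction == "lingoes" and evals[-1] < -1e-12:
        c = -evals[-1]
        d2 = d**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        G = _gower_center(np.sqrt(d2))
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=labels, columns=cols), evals


def beta_dispersion(
    dist: DistanceMatrix,
    groups: pd.Series | dict,
    permutations: int = 999,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Multivariate dispersion: distance to group centroid in PCoA space.

    Samples are embedded with all (positive and negative) eigenvalue
    axes; squared distances on imaginary axes are subtracted from those
    on real axes (Anderson's correction), so dispersions reproduce the
    original distances faithfully for non-Euclidean inputs.  The group
    effect is the one-way ANOVA F on the per-sample distances, with a
    permutation p-value.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = list(dist.ids)
    g = groups.loc[labels]
    levels = g.unique()
    if len(levels) < 2:
        raise ValueError("beta_dispersion requires at least two groups")

    G = _gower_center(dist.data)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.abs(evals) > 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(np.abs(evals))
    is_pos = evals > 0

    z = np.empty(len(labels))
    for lev in levels:
        members = np.array([i for i, s in enumerate(labels) if g.iloc[i] == lev])
        if members.size == 1:
            logger.warning("group %r has a single sample; dispersion 0", lev)
            z[members] = 0.0
            continue
        centroid = coords[members].mean(axis=0)
        diff2 = (coords[members] - centroid) ** 2
        z2 = diff2[:, is_pos].sum(axis=1) - diff2[:, ~is_pos].sum(axis=1)
        z[members] = np.sqrt(np.maximum(z2, 0.0))

    codes = pd.Categorical(g).codes
    f_obs = _anova_f(z, codes)
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    count = 0
    for _ in range(permutations):
        count += _anova_f(z, codes[rng.permutation(len(codes))]) >= f_obs - 1e-12
    p = (count + 1) / (permutations + 1)
    per_sample = pd.Series(z, index=labels, name="dist_to_centroid")
    group_means = per_sample.groupby(g.values).mean()
    return {
        "distances": per_sample,
        "group_means": group_means,
        "f": f_obs,
        "p": p,
    }


def _anova_f(y: np.ndarray, codes: np.ndarray) -> float:
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    k = 0
    for c in np.unique(codes):
        yy = y[codes == c]
        ss_between += yy.size * (yy.mean() - grand) ** 2
        ss_within += ((yy - yy.mean()) ** 2).sum()
        k += 1
    df_b = k - 1
    df_w = y.size - k
    if df_w <= 0 or ss_within <= 1e-300:
        return math.inf if ss_between > 1e-300 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


# ---------------------------------------------------------------------------
# stochasticity ~ community size mixed model
# ---------------------------------------------------------------------------

def mixed_stochasticity_model(
    data: pd.DataFrame,
    y: str = "stochastic_fraction",
    x: str = "community_size",
    random_group: str = "compartment",
    log_x: bool = True,
) -> dict:
    """Linear mixed model of stochastic fraction on community size.

    Fits y ~ x with a random intercept per compartment, the natural way
    to ask whether stochasticity declines with community size while
    letting each compartment sit at its own baseline.  Community size is
    log10-transformed by default (sizes span orders of magnitude).
    Returns the slope, its Wald p-value, and Nakagawa marginal /
    conditional R-squared.  With a single compartment the model
    degenerates to OLS (warned).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[y, x, random_group]].dropna().copy()
    df["_x"] = np.log10(df[x]) if log_x else df[x]
    n_groups = df[random_group].nunique()
    if n_groups < 2:
        logger.warning("single %s level; falling back to ordinary regression", random_group)
        ols = sm.OLS(df[y], sm.add_constant(df["_x"])).fit()
        r2 = float(ols.rsquared)
        return {
            "slope": float(ols.params["_x"]),
            "p": float(ols.pvalues["_x"]),
            "marginal_r2": r2,
            "conditional_r2": r2,
            "model": ols,
        }
    counts = df.groupby(random_group).size()
    if (counts < 3).any():
        raise ValueError("each compartment needs at least 3 groups of observations")
    md = smf.mixedlm(f"{y} ~ _x", df, groups=df[random_group])
    fit = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with np.errstate(all="ignore"):
                fit = md.fit(reml=True, method=method)
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if fit is None:
        # random-intercept variance collapsed; the model is an OLS limit
        logger.warning("mixed model failed to converge; using OLS limit")
        ols = sm.OLS(df[y], sm.add_constant(df["_x"])).fit()
        r2 = float(ols.rsquared)
        return {
            "slope": float(ols.params["_x"]),
            "p": float(ols.pvalues["_x"]),
            "marginal_r2": r2,
            "conditional_r2": r2,
            "model": ols,
        }
    slope = float(fit.fe_params["_x"])
    p = float(fit.pvalues["_x"])
    fixed = fit.fe_params["Intercept"] + fit.fe_params["_x"] * df["_x"]
    var_f = float(np.var(fixed, ddof=0))
    var_r = float(fit.cov_re.iloc[0, 0])
    var_e = float(fit.scale)
    denom = var_f + var_r + var_e
    return {
        "slope": slope,
        "p": p,
        "marginal_r2": var_f / denom,
        "conditional_r2": (var_f + var_r) / denom,
        "model": fit,
    }


# ---------------------------------------------------------------------------
# co-abundance network
# ---------------------------------------------------------------------------

def cooccurrence_clusters(
    table: CommunityTable,
    r_threshold: float = 0.8,
    phi_threshold: float = 0.1,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Co-abundance network from CLR profiles.

    Taxa i, j are connected when their CLR profiles satisfy Pearson
    r > ``r_threshold``, proportionality phi = var(clr_i - clr_j) /
    var(clr_i) < ``phi_threshold`` in at least one direction, and the
    correlation p-value survives Bonferroni correction over all taxon
    pairs.  Clusters are the connected components, numbered by
    decreasing size.  Constant CLR columns are excluded with a warning.
    """
    if table.mode is not TableMode.clr:
        raise ValueError("cooccurrence_clusters requires a clr-mode table")
    if table.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    X = table.values
    var = X.var(axis=0, ddof=1)
    keep = var > 1e-12
    if (~keep).any():
        dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
        logger.warning("excluding %d constant clr columns: %s", len(dropped), dropped[:5])
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    X = X[:, keep]
    var = var[keep]
    n, S = X.shape
    R = np.corrcoef(X, rowvar=False)
    # var(x_i - x_j) = var_i + var_j - 2 cov_ij
    cov = np.cov(X, rowvar=False, ddof=1)
    diff_var = var[:, None] + var[None, :] - 2 * cov
    phi = diff_var / var[:, None]
    phi_sym = np.minimum(phi, phi.T)

    m_tests = S * (S - 1) / 2
    edges = []
    graph = nx.Graph()
    # constant columns stay as isolated nodes; they just cannot form edges
    graph.add_nodes_from(table.taxon_ids)
    for i in range(S):
        for j in range(i + 1, S):
            r = R[i, j]
            if r <= r_threshold or phi_sym[i, j] >= phi_threshold:
                continue
            # two-sided t-test on r, Bonferroni over all pairs
            t = r * np.sqrt((n - 2) / max(1e-300, 1 - r**2))
            p = 2 * sps.t.sf(abs(t), df=n - 2)
            p_adj = min(1.0, p * m_tests)
            if p_adj < alpha:
                edges.append((taxa[i], taxa[j], r, phi_sym[i, j], p_adj))
                graph.add_edge(taxa[i], taxa[j])
    edge_df = pd.DataFrame(edges, columns=["taxon_a", "taxon_b", "r", "phi", "p_adj"])
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    rows = []
    for cid, comp in enumerate(comps, start=1):
        for t in sorted(comp):
            rows.append({"taxon_id": t, "cluster": cid, "cluster_size": len(comp)})
    cluster_df = pd.DataFrame(rows)
    return edge_df, cluster_df


# ---------------------------------------------------------------------------
# community-age delay protocol
# ---------------------------------------------------------------------------

def age_delay_protocol(
    table: CommunityTable,
    metadata: SampleMetadata,
    n_estimators: int = 500,
    top_k: int | str = "cv_select",
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Quantify the developmental delay of treated communities in weeks.

    Half of the control samples (seeded 50/50 split stratified by week)
    train a full random-forest regression of sampling week on all taxa;
    features are ranked by importance and a sparse forest is refit on
    the top-k features (k chosen by cross-validated error when
    ``top_k="cv_select"``).  The sparse model predicts the ages of the
    held-out controls and of every non-control sample; the delay at a
    given week is the mean predicted age of held-out controls minus the
    mean predicted age of treatment samples for that week.

    Returns a tidy frame (treatment, week, n, mean predicted ages,
    discrepancy).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    md = metadata.aligned_to(table).data
    weeks = md["week"].astype(int)
    is_control = md["treatment"] == "control"
    control_weeks = sorted(weeks[is_control].unique())
    if len(control_weeks) < 3:
        raise ValueError("control samples must span at least 3 weeks")
    for w in control_weeks:
        if ((weeks == w) & is_control).sum() < 4:
            raise ValueError(f"fewer than 4 control samples in week {w}")

    X = table.values
    y = weeks.to_numpy()

    # stratified 50/50 split of controls by week
    train_idx, hold_idx = [], []
    for w in control_weeks:
        members = np.flatnonzero((weeks == w) & is_control)
        members = rng.permutation(members)
        half = members.size // 2
        train_idx.extend(members[:half])
        hold_idx.extend(members[half:])
    train_idx = np.array(sorted(train_idx))
    hold_idx = np.array(sorted(hold_idx))

    rf_seed = int(rng.integers(0, 2**31))
    full = RandomForestRegressor(
        n_estimators=n_estimators, max_features="sqrt", random_state=rf_seed, n_jobs=1
    )
    full.fit(X[train_idx], y[train_idx])
    ranking = np.argsort(full.feature_importances_)[::-1]

    if top_k == "cv_select":
        candidates = [k for k in (5, 10, 20, 50, 100, X.shape[1]) if k <= X.shape[1]]
        best_k, best_err = candidates[0], np.inf
        kf = KFold(n_splits=5, shuffle=True, random_state=rf_seed)
        for k in candidates:
            feats = ranking[:k]
            errs = []
            for tr, te in kf.split(train_idx):
                a, b = train_idx[tr], train_idx[te]
                model = RandomForestRegressor(
                    n_estimators=max(100, n_estimators // 5),
                    max_features="sqrt",
                    random_state=rf_seed,
                    n_jobs=1,
                )
                model.fit(X[np.ix_(a, feats)], y[a])
                errs.append(np.mean((model.predict(X[np.ix_(b, feats)]) - y[b]) ** 2))
            err = float(np.mean(errs))
            if err < best_err:
                best_err, best_k = err, k
        k = best_k
    else:
        k = int(top_k)
        if k < 1 or k > X.shape[1]:
            raise ValueError("top_k out of range")
    feats = ranking[:k]

    sparse = RandomForestRegressor(
        n_estimators=n_estimators, max_features="sqrt", random_state=rf_seed, n_jobs=1
    )
    sparse.fit(X[np.ix_(train_idx, feats)], y[train_idx])

    pred = np.full(len(y), np.nan)
    eval_idx = np.concatenate([hold_idx, np.flatnonzero(~is_control)])
    pred[eval_idx] = sparse.predict(X[np.ix_(eval_idx, feats)])

    rows = []
    hold_mask = np.zeros(len(y), dtype=bool)
    hold_mask[hold_idx] = True
    for treatment in sorted(md.loc[~is_control, "treatment"].unique()):
        t_mask = (md["treatment"] == treatment).to_numpy()
        for w in sorted(weeks[t_mask].unique()):
            wk = weeks.to_numpy() == w
            ctrl_pred = pred[hold_mask & wk]
            trt_pred = pred[t_mask & wk]
            if ctrl_pred.size == 0 or trt_pred.size == 0:
                continue
            rows.append(
                {
                    "treatment": treatment,
                    "week": int(w),
                    "n_control": int(ctrl_pred.size),
                    "n_treatment": int(trt_pred.size),
                    "control_pred_age": float(ctrl_pred.mean()),
                    "treatment_pred_age": float(trt_pred.mean()),
                    "discrepancy": float(ctrl_pred.mean() - trt_pred.mean()),
                    "top_k": k,
                }
            )
    return pd.DataFrame(rows)
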