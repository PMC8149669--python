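"""Environmental vs spatial driver attribution for plot-level beta metrics.

Three stages, mirroring the standard community-ecology workflow:

* **PCNM** (principal coordinates of neighbour matrices) builds orthogonal
  spatial eigenfunctions from plot coordinates: truncate the Euclidean
  distance matrix at the longest minimum-spanning-tree edge, replace larger
  distances by four times the truncation distance, and take the positive-
  eigenvalue axes of a principal-coordinate analysis.
* **Forward selection** with the double stopping rule picks predictors
  (climate PCA axes, or PCNM axes) one at a time, requiring both a
  permutation p-value <= alpha for each added term and that the cumulative
  adjusted R^2 not exceed the global model's adjusted R^2.
* **Variation partitioning** splits the adjusted R^2 of the joint linear
  model into pure-environment, pure-space, shared and residual fractions,
  with permutation tests for the testable fractions (the shared fraction
  cannot be tested).

Variable-level attribution uses a regression random forest: importance is
the increase in node purity (total decrease in residual sum of squares from
splits on the variable, averaged over trees) with significance from
refitting the forest on permuted responses, plus partial-dependence curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCNM spatial eigenfunctions

@dataclass
class SpatialEigenfunctions:
    """Positive-eigenvalue PCNM axes (columns centred and orthogonal).

    ``vectors`` holds principal coordinates (eigenvector * sqrt(eigenvalue),
    the classical PCoA scaling), one column per positive eigenvalue in
    decreasing order.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    truncation: float


def _haversine_pdist(lonlat: np.ndarray) -> np.ndarray:
    """Condensed great-circle distances (km) for (longitude, latitude) rows."""
    rad = np.radians(lonlat)
    lon, lat = rad[:, 0], rad[:, 1]
    n = len(lonlat)
    out = []
    for i in range(n - 1):
        dlat = lat[i + 1 :] - lat[i]
        dlon = lon[i + 1 :] - lon[i]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat[i + 1 :]) * np.sin(dlon / 2) ** 2
        out.append(2 * 6371.0 * np.arcsin(np.sqrt(h)))
    return np.concatenate(out)


def pcnm(coords, great_circle: bool = False) -> SpatialEigenfunctions:
    """PCNM spatial eigenfunctions from site coordinate pairs.

    By default coordinates are taken as planar (longitude/latitude treated
    as Euclidean axes, the convention of the reference implementation when
    fed raw coordinates); ``great_circle=True`` uses haversine distances in
    km instead. Duplicate coordinates make the truncation degenerate and
    raise with advice to jitter.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need >= 3 coordinate pairs")
    d = _haversine_pdist(coords) if great_circle else pdist(coords)
    if (d == 0).any():
        raise ValueError("duplicate coordinates collapse the MST; jitter the sites")
    dm = squareform(d)
    mst = minimum_spanning_tree(dm)
    t = float(mst.data.max())
    dmod = np.where(dm > t, 4 * t, dm)
    np.fill_diagonal(dmod, 0.0)

    # principal-coordinate analysis (Gower double-centring)
    n = dmod.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmod**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > vals.max() * 1e-10
    vals, vecs = vals[pos], vecs[:, pos]
    return SpatialEigenfunctions(vecs * np.sqrt(vals), vals, t)


# --------------------------------------------------------------------------
# linear-model helpers

def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of OLS of centred y on column-centred X (with intercept)."""
    yc = y - y.mean()
    ss_tot = yc @ yc
    if ss_tot == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return float(1 - (resid @ resid) / ss_tot)


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return float("nan")
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


def _perm_r2(y: np.ndarray, X: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """R^2 of X against ``n_perm`` row-permuted copies of y, vectorized."""
    Xc = X - X.mean(axis=0)
    q, _ = np.linalg.qr(Xc)
    # drop numerically null columns of the basis
    keep = (np.abs(q).max(axis=0) > 1e-12)
    q = q[:, keep]
    perms = np.argsort(rng.random((n_perm, len(y))), axis=1)
    Y = y[perms].T                       # n x n_perm
    Yc = Y - Y.mean(axis=0)
    ss_tot = (Yc**2).sum(axis=0)
    proj = q.T @ Yc
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ss_tot > 0, (proj**2).sum(axis=0) / ss_tot, 0.0)


def forward_select(
    response,
    candidates: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: np.random.Generator | int | None = 0,
) -> list:
    """Forward selection of predictors with the double stopping rule.

    A permutation test on the global model (all candidates) gates entry: if
    it is non-significant the selection is empty. Candidates are then added
    greedily by R^2 gain while (a) the added term's permutation p-value is
    <= alpha (response permutation against the current model's residual
    signal) and (b) the cumulative adjusted R^2 stays at or below the global
    model's adjusted R^2. Never selects more than n - 2 predictors.

    Returns the list of selected column labels (or indices for arrays).
    """
    rng = np.random.default_rng(seed)
    if isinstance(candidates, pd.DataFrame):
        labels = list(candidates.columns)
        Xall = candidates.to_numpy(dtype=float)
    else:
        Xall = np.asarray(candidates, dtype=float)
        labels = list(range(Xall.shape[1]))
    y = np.asarray(response, dtype=float)
    n, p = Xall.shape

    r2_glob = _r2(y, Xall)
    p_glob = float(
        ((_perm_r2(y, Xall, n_perm, rng) >= r2_glob).sum() + 1) / (n_perm + 1)
    )
    if p_glob > alpha:
        logger.info("global test non-significant (p = %.3f); empty selection", p_glob)
        return []
    adj_glob = _adj_r2(r2_glob, n, p) if n - p - 1 > 0 else r2_glob

    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        return []
    Xc = Xall - Xall.mean(axis=0)

    selected: list[int] = []
    remaining = list(range(p))
    r2_cur = 0.0
    resid = yc.copy()
    while remaining and len(selected) < n - 2:
        # residualize remaining candidates on the selected set and normalize;
        # the R^2 gain of adding candidate k is then (c_k . resid)^2 / ss_tot
        C = Xc[:, remaining]
        if selected:
            Xs = Xc[:, selected]
            beta, *_ = np.linalg.lstsq(Xs, C, rcond=None)
            C = C - Xs @ beta
        norms = np.linalg.norm(C, axis=0)
        live = norms > 1e-10 * np.sqrt(n)
        if not live.any():
            break
        C = C[:, live] / norms[live]
        cand = [remaining[i] for i in np.flatnonzero(live)]
        gains = (C.T @ resid) ** 2 / ss_tot
        best = int(np.argmax(gains))

        # max-statistic permutation test (Freedman-Lane residual shuffle):
        # the best gain is compared against the null distribution of the
        # maximum gain over all remaining candidates, so the probability of
        # admitting a spurious variable at each step stays ~ alpha instead
        # of ~ 1 - (1 - alpha)^p_remaining
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        R = resid[perms].T                     # n x n_perm
        null_max = ((C.T @ R) ** 2).max(axis=0) / ss_tot
        p_k = float((np.sum(null_max >= gains[best] - 1e-12) + 1) / (n_perm + 1))

        r2_new = r2_cur + float(gains[best])
        adj_new = _adj_r2(r2_new, n, len(selected) + 1)
        # the adjusted-R^2 ceiling gates additions beyond the first selected
        # candidate: a lone strong predictor's adjusted R^2 fluctuates above
        # the global model's (irrelevant candidates depress the latter), so
        # applying the ceiling to the first pick would reject real signal
        if p_k > alpha or (selected and adj_new > adj_glob + 1e-12):
            break
        k = cand[best]
        resid = resid - C[:, best] * (C[:, best] @ resid)
        selected.append(k)
        remaining.remove(k)
        r2_cur = r2_new
    return [labels[k] for k in selected]


# --------------------------------------------------------------------------
# variation partitioning

@dataclass
class VarpartResult:
    """Adjusted-R^2 variation fractions and permutation tests.

    ``pure_env + shared + pure_space + residual = 1`` on the adjusted scale.
    The shared fraction has no permutation test (it is not expressible as a
    single model's fit). Unadjusted fractions are carried alongside for
    transparency.
    """

    pure_env: float
    shared: float
    pure_space: float
    residual: float
    p_env: float
    p_space: float
    p_joint: float
    r2_env: float          # unadjusted R^2, env-only model
    r2_space: float
    r2_joint: float
    n: int


def variation_partition(
    response,
    env,
    space,
    n_perm: int = 999,
    seed: np.random.Generator | int | None = 0,
) -> VarpartResult:
    """Partition response variance into environment and space fractions.

    Fits env-only, space-only and joint linear models; pure fractions by
    subtraction of adjusted R^2 values. Permutation p-values (response row
    permutation) are attached to the env-only, space-only and joint
    fractions; the shared fraction is reported untested.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(response, dtype=float)
    E = np.atleast_2d(np.asarray(env, dtype=float))
    S = np.atleast_2d(np.asarray(space, dtype=float))
    if E.shape[0] == 1 and len(y) > 1:
        E = E.T
    if S.shape[0] == 1 and len(y) > 1:
        S = S.T
    n = len(y)
    p_e, p_s = E.shape[1], S.shape[1]
    if n <= p_e + p_s + 2:
        raise ValueError(
            f"n = {n} plots insufficient for {p_e} + {p_s} predictors"
        )
    for name, M in (("env", E), ("space", S)):
        rank = np.linalg.matrix_rank(M - M.mean(axis=0))
        if rank < M.shape[1]:
            raise ValueError(f"rank-deficient {name} predictor set (collinear columns)")

    if np.ptp(y) == 0:
        logger.warning("constant response; all fractions 0")
        return VarpartResult(0, 0, 0, 1.0, 1.0, 1.0, 1.0, 0, 0, 0, n)

    J = np.hstack([E, S])
    r2_e, r2_s, r2_j = _r2(y, E), _r2(y, S), _r2(y, J)
    a_e, a_s, a_j = (
        _adj_r2(r2_e, n, p_e), _adj_r2(r2_s, n, p_s), _adj_r2(r2_j, n, p_e + p_s)
    )
    pure_env = a_j - a_s
    pure_space = a_j - a_e
    shared = a_e + a_s - a_j
    residual = 1 - a_j

    def ptest(M, r2_obs):
        null = _perm_r2(y, M, n_perm, rng)
        return float((np.sum(null >= r2_obs - 1e-12) + 1) / (n_perm + 1))

    return VarpartResult(
        pure_env=pure_env, shared=shared, pure_space=pure_space, residual=residual,
        p_env=ptest(E, r2_e), p_space=ptest(S, r2_s), p_joint=ptest(J, r2_j),
        r2_env=r2_e, r2_space=r2_s, r2_joint=r2_j, n=n,
    )


# --------------------------------------------------------------------------
# random-forest importance

@dataclass
class ImportanceResult:
    """Node-purity importances with permutation p-values and PD curves."""

    table: pd.DataFrame            # importance, p, rank per predictor
    partial_dependence: dict       # predictor -> (grid, mean prediction)
    n_trees: int
    n_perm: int

    def top(self, k: int = 5) -> pd.DataFrame:
        return self.table.sort_values("rank").head(k)


def _node_purity_importance(forest: RandomForestRegressor, p: int) -> np.ndarray:
    """Increase-in-node-purity importance (RSS decrease, averaged over trees).

    scikit-learn exposes only normalized mean-decrease-in-impurity, so the
    unnormalized decrease is accumulated from each tree's node records:
    for every split, weighted parent impurity minus weighted child
    impurities, attributed to the split variable. Impurity is MSE, weights
    are node sample counts, so the units are response-variance * samples
    (residual sum of squares).
    """
    imp = np.zeros(p)
    for est in forest.estimators_:
        t = est.tree_
        w = t.weighted_n_node_samples
        internal = t.children_left != -1
        left, right = t.children_left[internal], t.children_right[internal]
        dec = (
            w[internal] * t.impurity[internal]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        )
        np.add.at(imp, t.feature[internal], dec)
    return imp / len(forest.estimators_)


def rf_importance(
    response,
    predictors: pd.DataFrame | np.ndarray,
    n_trees: int = 500,
    n_perm: int = 999,
    seed: int = 0,
    mtry: int | None = None,
    pd_points: int = 25,
    compute_pd: bool = True,
) -> ImportanceResult:
    """Regression-forest variable importance with permutation significance.

    The forest uses bootstrap sampling of plots and ``mtry = floor(p/3)``
    candidate variables per split (regression default). The permutation
    p-value of each predictor is the proportion of ``n_perm`` forests fitted
    to row-permuted responses whose importance for that predictor meets or
    exceeds the observed one. Partial dependence is evaluated on a
    ``pd_points``-point grid per predictor.
    """
    if isinstance(predictors, pd.DataFrame):
        labels = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        labels = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need >= 10 plots, have {n}")
    if mtry is None:
        mtry = max(p // 3, 1)
    rng = np.random.default_rng(seed)
    constant = np.ptp(y) == 0
    if constant:
        logger.warning("constant response; importances ~ 0, p ~ 1")

    def fit(yy, rs):
        f = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, bootstrap=True,
            random_state=rs, n_jobs=1,
        )
        f.fit(X, yy)
        return f

    forest = fit(y, int(rng.integers(2**31 - 1)))
    obs = _node_purity_importance(forest, p)

    exceed = np.zeros(p)
    for _ in range(n_perm):
        yp = rng.permutation(y)
        null_imp = _node_purity_importance(fit(yp, int(rng.integers(2**31 - 1))), p)
        exceed += null_imp >= obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)

    order = np.argsort(-obs, kind="stable")
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    table = pd.DataFrame({"importance": obs, "p": pvals, "rank": ranks}, index=labels)

    pd_curves = {}
    if compute_pd:
        for j, lab in enumerate(labels):
            grid = np.linspace(X[:, j].min(), X[:, j].max(), pd_points)
            preds = np.empty(pd_points)
            Xg = X.copy()
            for g, val in enumerate(grid):
                Xg[:, j] = val
                preds[g] = forest.predict(Xg).mean()
            pd_curves[lab] = (grid, preds)
    return ImportanceResult(table, pd_curves, n_trees, n_perm)
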