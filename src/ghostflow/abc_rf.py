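"""Random-forest ABC: model choice, validation battery, parameter estimation.

Model choice follows the classification-forest scheme of Pudlo et al.
(2016): a forest is trained on the simulated summary statistics
augmented with linear-discriminant axes; the scenario receiving the
most tree votes at the observed point wins, and its posterior
probability is estimated by a second regression forest fitted to the
out-of-bag misclassification indicator.  The out-of-bag
misclassification rate is the prior error rate.

Parameter estimation follows the quantile-regression-forest scheme of
Raynal et al. (2019): one regression forest per parameter; posterior
mean, median and quantiles come from the training responses weighted
by leaf co-membership with the observed point, and the normalized mean
absolute error (NMAE) of out-of-bag predictions summarizes estimation
accuracy.

Supporting checks: PCA overlap of observed and simulated statistics,
a k-nearest-neighbour goodness-of-fit test, and out-of-bag
hyperparameter tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .simulate import PARAM_COLUMNS, ReferenceTable
from .sumstats import STAT_NAMES

__all__ = [
    "ModelChoiceResult",
    "PosteriorEstimate",
    "select_model",
    "prior_error_and_confusion",
    "pca_overlap_check",
    "goodness_of_fit",
    "estimate_parameters",
    "tune_forest",
    "TUNED_NODE_SIZE",
    "TUNED_MTRY",
]

#: forest hyperparameters selected by out-of-bag tuning on this system's
#: reference tables (see tune_forest); usable as presets
TUNED_NODE_SIZE = 50
TUNED_MTRY = 7

_DEF_TREES = 500


def _observed_vector(observed) -> np.ndarray:
    """Accept a Series (validated by name) or a bare 22-vector."""
    if isinstance(observed, pd.Series):
        missing = [c for c in STAT_NAMES if c not in observed.index]
        if missing:
            raise ValueError(f"observed statistics lack columns: {missing}")
        return observed[list(STAT_NAMES)].to_numpy(dtype=float)
    arr = np.asarray(observed, dtype=float)
    if arr.shape != (len(STAT_NAMES),):
        raise ValueError(
            f"observed vector must have length {len(STAT_NAMES)}")
    return arr


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _canonical_sort(data: pd.DataFrame) -> pd.DataFrame:
    """Row order must not matter: sort rows canonically before fitting."""
    cols = ["scenario", *PARAM_COLUMNS, *STAT_NAMES]
    return data.sort_values(cols, kind="mergesort").reset_index(drop=True)


@dataclass
class ModelChoiceResult:
    """Votes, winner, posterior probability and validation numbers."""

    votes: dict[str, float]
    best: str
    posterior_probability: float
    prior_error_rate: float
    confusion: pd.DataFrame
    n_trees: int

    def __post_init__(self):
        total = sum(self.votes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"votes sum to {total}, not 1")
        if self.best != max(self.votes, key=self.votes.get):
            raise ValueError("best scenario is not the vote argmax")


def _model_choice_features(X: np.ndarray, labels: np.ndarray):
    """Standardized statistics + (k-1) linear-discriminant axes."""
    Xs, mu, sd = _standardize(X)
    k = len(np.unique(labels))
    lda = LinearDiscriminantAnalysis(n_components=k - 1)
    lda.fit(Xs, labels)
    proj = lda.transform(Xs)

    def transform(obs_row: np.ndarray) -> np.ndarray:
        z = (obs_row - mu) / sd
        return np.concatenate([z, lda.transform(z[None, :])[0]])

    return np.hstack([Xs, proj]), transform


def select_model(ref: ReferenceTable, observed, n_trees: int = _DEF_TREES,
                 seed: int = 0) -> ModelChoiceResult:
    """Scenario choice by classification-forest votes at the observed point.

    Votes are the fraction of trees voting each scenario; the posterior
    probability of the winner is one minus the local misclassification
    rate predicted by a regression forest trained on out-of-bag error
    indicators.  Deterministic under ``seed``.
    """
    obs = _observed_vector(observed)
    data = _canonical_sort(ref.data)
    if data["scenario"].nunique() < 2:
        raise ValueError("model choice needs at least 2 scenarios")
    X = data[list(STAT_NAMES)].to_numpy(dtype=float)
    y = data["scenario"].to_numpy()
    feats, transform = _model_choice_features(X, y)
    obs_feat = transform(obs)

    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, bootstrap=True,
        random_state=seed, n_jobs=1)
    clf.fit(feats, y)

    # sub-estimators predict encoded class indices
    tree_votes = np.array([int(est.predict(obs_feat[None, :])[0])
                           for est in clf.estimators_])
    classes = clf.classes_
    votes = {c: float(np.mean(tree_votes == i))
             for i, c in enumerate(classes)}
    # normalise away any float crumbs
    total = sum(votes.values())
    votes = {c: v / total for c, v in votes.items()}
    best = max(votes, key=votes.get)

    oob_pred = classes[np.argmax(clf.oob_decision_function_, axis=1)]
    misclassified = (oob_pred != y).astype(float)
    prior_error = float(misclassified.mean())
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(oob_pred, name="oob_predicted"))
    confusion = confusion.reindex(index=classes, columns=classes,
                                  fill_value=0)

    err_rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed + 1, n_jobs=1)
    err_rf.fit(feats, misclassified)
    local_err = float(err_rf.predict(obs_feat[None, :])[0])
    posterior = float(np.clip(1.0 - local_err, 0.0, 1.0))

    return ModelChoiceResult(votes=votes, best=best,
                             posterior_probability=posterior,
                             prior_error_rate=prior_error,
                             confusion=confusion, n_trees=n_trees)


def prior_error_and_confusion(ref: ReferenceTable, n_trees: int = _DEF_TREES,
                              seed: int = 0):
    """Out-of-bag misclassification rate, confusion matrix, stability check.

    Returns ``(prior_error_rate, confusion, stability)`` where
    ``stability`` holds the error rates of two disjoint half-tables; a
    large gap between them flags an undersized reference table.
    """
    data = _canonical_sort(ref.data)
    if data["scenario"].nunique() < 2:
        raise ValueError("need at least 2 scenarios")
    X = data[list(STAT_NAMES)].to_numpy(dtype=float)
    y = data["scenario"].to_numpy()

    def oob_error(Xp, yp, rs):
        feats, _ = _model_choice_features(Xp, yp)
        clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                     bootstrap=True, random_state=rs,
                                     n_jobs=1)
        clf.fit(feats, yp)
        pred = clf.classes_[np.argmax(clf.oob_decision_function_, axis=1)]
        return pred, float(np.mean(pred != yp))

    pred, err = oob_error(X, y, seed)
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(pred, name="oob_predicted"))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    half = len(y) // 2
    _, err_a = oob_error(X[idx[:half]], y[idx[:half]], seed + 1)
    _, err_b = oob_error(X[idx[half:]], y[idx[half:]], seed + 2)
    per_scenario = {
        s: float(np.mean(pred[y == s] != s)) for s in np.unique(y)}
    return err, confusion, {"half_a": err_a, "half_b": err_b,
                            "per_scenario": per_scenario}


def pca_overlap_check(ref: ReferenceTable, observed):
    """Project the observed point onto the simulations' first two PCs.

    Returns ``(outside_flag, obs_xy, sims_xy)``; the flag is raised when
    the observed point falls outside the convex hull of the simulated
    cloud on those two axes.
    """
    from scipy.spatial import Delaunay

    obs = _observed_vector(observed)
    X = ref.stats_matrix()
    Xs, mu, sd = _standardize(X)
    # principal axes via SVD of the standardized simulated statistics
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    sims_xy = Xs @ Vt[:2].T
    obs_xy = ((obs - mu) / sd) @ Vt[:2].T
    hull = Delaunay(sims_xy)
    outside = bool(hull.find_simplex(obs_xy) < 0)
    return outside, obs_xy, sims_xy


def goodness_of_fit(ref_best: ReferenceTable, observed, n_rep: int = 1000,
                    seed: int = 0, k: int = 10) -> float:
    """k-nearest-neighbour goodness-of-fit p-value.

    The statistic is the mean Euclidean distance (standardized
    statistics) from a point to its ``k`` nearest neighbours in a
    reference cloud.  ``n_rep`` simulated rows are held out of the
    cloud and treated as pseudo-observed, so under the null they are
    exchangeable with the observed point and the test is calibrated by
    construction.  ``p = (1 + #{null >= observed}) / (n_rep + 1)``.
    """
    from sklearn.neighbors import NearestNeighbors

    if n_rep < 20:
        raise ValueError("n_rep must be >= 20")
    if len(ref_best.scenarios) != 1:
        raise ValueError("goodness_of_fit expects a single-scenario table")
    obs = _observed_vector(observed)
    X = ref_best.stats_matrix()
    Xs, mu, sd = _standardize(X)
    obs_s = (obs - mu) / sd
    rng = np.random.default_rng(seed)
    # hold the null points out of the cloud (at most half the table)
    n_rep_eff = min(n_rep, len(Xs) // 2)
    if n_rep_eff < 20:
        raise ValueError("reference table too small for the null sample")
    perm = rng.permutation(len(Xs))
    held, cloud = perm[:n_rep_eff], perm[n_rep_eff:]
    nn = NearestNeighbors(n_neighbors=k).fit(Xs[cloud])
    d_obs = float(nn.kneighbors(obs_s[None, :])[0][0].mean())
    null = nn.kneighbors(Xs[held])[0].mean(axis=1)
    return float((1 + np.sum(null >= d_obs)) / (n_rep_eff + 1))


@dataclass
class PosteriorEstimate:
    """Per-parameter posterior summaries from quantile regression forests."""

    table: pd.DataFrame  # index: parameter; columns: mean, median, q2.5, q97.5, nmae
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        if ((t["q2.5"] > t["median"]) | (t["median"] > t["q97.5"])).any():
            raise ValueError("posterior quantiles are not monotone")
        if (t["nmae"] < 0).any():
            raise ValueError("NMAE must be nonnegative")

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.table.loc[parameter]


def _qrf_weights(rf: RandomForestRegressor, X: np.ndarray,
                 obs: np.ndarray) -> np.ndarray:
    """Leaf co-membership weights of training rows w.r.t. the observed point."""
    leaves = rf.apply(X)              # (n, trees)
    obs_leaves = rf.apply(obs[None, :])[0]
    w = np.zeros(len(X))
    for t in range(leaves.shape[1]):
        mask = leaves[:, t] == obs_leaves[t]
        cnt = mask.sum()
        if cnt:
            w[mask] += 1.0 / cnt
    return w / leaves.shape[1]


def _weighted_quantile(y: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(y)
    y, w = y[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(qs, cw, y)


def estimate_parameters(ref_best: ReferenceTable, observed,
                        n_trees: int = _DEF_TREES,
                        node_size: int = TUNED_NODE_SIZE,
                        mtry: int = TUNED_MTRY,
                        seed: int = 0,
                        parameters=None) -> PosteriorEstimate:
    """Posterior parameter estimates for a single-scenario reference table.

    One regression forest per parameter (min leaf size ``node_size``,
    ``mtry`` candidate splits); posterior mean/median/95% interval from
    the weighted out-of-bag-style distribution of training responses,
    NMAE from out-of-bag predictions.  Parameters constant across rows
    are reported in ``fixed`` rather than estimated.  ``parameters``
    restricts estimation to a subset of parameter names.
    """
    if len(ref_best.scenarios) != 1:
        raise ValueError("estimate_parameters expects a single-scenario table")
    obs = _observed_vector(observed)
    data = _canonical_sort(ref_best.data)
    X = data[list(STAT_NAMES)].to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)
    obs_s = (obs - mu) / sd

    wanted = list(PARAM_COLUMNS) if parameters is None else list(parameters)
    unknown = [p for p in wanted if p not in PARAM_COLUMNS]
    if unknown:
        raise ValueError(f"unknown parameters: {unknown}")
    rows = []
    fixed = {}
    rng = np.random.default_rng(seed)
    for name in wanted:
        y = data[name].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            if y[0] != 0.0:
                fixed[name] = float(y[0])
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees, min_samples_leaf=node_size,
            max_features=min(mtry, len(STAT_NAMES)), oob_score=True,
            bootstrap=True, random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1)
        rf.fit(Xs, y)
        w = _qrf_weights(rf, Xs, obs_s)
        mean = float(np.average(y, weights=w))
        q025, med, q975 = _weighted_quantile(y, w, [0.025, 0.5, 0.975])
        oob = rf.oob_prediction_
        denom = np.abs(y)
        okd = denom > 0
        nmae = float(np.mean(np.abs(oob[okd] - y[okd]) / denom[okd]))
        rows.append({"parameter": name, "mean": mean, "median": float(med),
                     "q2.5": float(q025), "q97.5": float(q975),
                     "nmae": nmae})
    table = pd.DataFrame.from_records(rows).set_index("parameter")
    return PosteriorEstimate(table=table, fixed=fixed)


def tune_forest(ref: ReferenceTable, node_sizes, mtries,
                n_trees: int = 200, seed: int = 0,
                parameter: str | None = None):
    """Pick (node_size, mtry) minimizing out-of-bag prediction error.

    The error is the out-of-bag MSE summed over the varying parameters
    (or the one named); ties break to the smallest node size, then the
    smallest mtry.  The returned pair is always a member of the grid.
    """
    node_sizes = list(node_sizes)
    mtries = list(mtries)
    if not node_sizes or not mtries:
        raise ValueError("grid must be nonempty")
    data = _canonical_sort(ref.data)
    X, _, _ = _standardize(data[list(STAT_NAMES)].to_numpy(dtype=float))
    params = [p for p in (PARAM_COLUMNS if parameter is None else [parameter])
              if not np.allclose(data[p], data[p].iloc[0])]
    if not params:
        raise ValueError("no varying parameter to tune on")
    best = None
    for ns in node_sizes:
        for mt in mtries:
            err = 0.0
            for i, pname in enumerate(params):
                y = data[pname].to_numpy(dtype=float)
                rf = RandomForestRegressor(
                    n_estimators=n_trees, min_samples_leaf=ns,
                    max_features=min(mt, X.shape[1]), oob_score=True,
                    bootstrap=True, random_state=seed + i, n_jobs=1)
                rf.fit(X, y)
                scale = y.std() or 1.0
                err += float(np.mean((rf.oob_prediction_ - y) ** 2)) / scale**2
            if best is None or err < best[0] - 1e-12:
                best = (err, ns, mt)
    return best[1], best[2]
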