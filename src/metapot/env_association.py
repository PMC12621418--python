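"""Associating metabolite-group producibility with soil physicochemistry.

Each environmental variable (pH, electrical conductivity, organic matter,
element concentrations...) is regressed on the binary producibility profiles
of metabolite groups with an elastic net (mixing 0.85 between lasso and
ridge). Groups whose standardized coefficient exceeds 0.3 in absolute value
for at least one variable are *selected*; the union of their member
metabolites is the set of *key metabolites*. Variables are then clustered by
their |coefficient| profiles (Bray-Curtis dissimilarity, Ward-type linkage).

Coefficient magnitudes are descriptive, not inferential: no significance
testing or multiple-testing control is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import GroupKFold

from .producibility_matrix import MetaboliteGroup, ProducibilityMatrix, groups_to_frame

logger = logging.getLogger("metapot")

__all__ = [
    "standardize_env",
    "Design",
    "build_design",
    "AssociationResult",
    "fit_elastic_net",
    "fit_all_variables",
    "KeyMetaboliteSet",
    "select_key_metabolites",
    "VariableClustering",
    "cluster_variables",
]


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Center each variable to mean 0 and scale to unit (population) sd.

    Measurements arrive in incommensurable units (pH units, mS/cm, %, mg/kg);
    scaling puts them on one scale so a single coefficient threshold is
    meaningful across variables. A constant variable cannot be scaled and is
    an error. Missing values are an error: zeros are data here.
    """
    if env.isna().any().any():
        bad = sorted(env.columns[env.isna().any()])
        raise ValueError(f"environmental table has missing values in {bad}")
    sd = env.std(axis=0, ddof=0)
    constant = sorted(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant environmental variable(s): {constant}")
    return (env - env.mean(axis=0)) / sd


@dataclass
class Design:
    """Regression design: predictors, responses, and site fold labels.

    ``X`` has one row per observation and one binary column per metabolite
    group; ``y`` holds every standardized environmental variable;
    ``site_of_obs`` labels each observation's site for grouped
    cross-validation. ``zero_variance`` lists groups constant across
    observations (uninformative; excluded from fitting, coefficient 0).
    """

    X: pd.DataFrame
    y: pd.DataFrame
    site_of_obs: pd.Series
    unit: str
    zero_variance: list[str] = field(default_factory=list)


def build_design(
    groups: list[MetaboliteGroup],
    matrix: ProducibilityMatrix,
    env: pd.DataFrame,
    *,
    unit: str = "simulation",
) -> Design:
    """Assemble the elastic-net design from the group matrix and env table.

    Default ``unit="simulation"``: one observation per simulation column, the
    predictor being the group's producibility in that column and the response
    the site's standardized measurement replicated across the site's columns.
    ``unit="site"`` aggregates to one observation per site with mean
    producibility per group. Every simulation's site must appear in ``env``.
    """
    if unit not in {"simulation", "site"}:
        raise ValueError(f"unknown design unit {unit!r}")
    gframe = groups_to_frame(groups, matrix)  # groups x simulations
    sites = matrix.meta["site"]
    unmapped = sorted(set(sites) - set(env.index))
    if unmapped:
        raise ValueError(f"sites missing from environmental table: {unmapped}")
    env_std = standardize_env(env)

    if unit == "simulation":
        X = gframe.T.astype(float)  # simulations x groups
        site_of_obs = sites.copy()
        y = env_std.loc[site_of_obs].set_axis(X.index)
    else:
        X = gframe.T.groupby(sites).mean()  # sites x groups
        site_of_obs = pd.Series(X.index, index=X.index)
        y = env_std.loc[X.index]

    zero_variance = sorted(X.columns[X.nunique(axis=0) <= 1])
    if zero_variance:
        logger.info("design: %d zero-variance group predictor(s) flagged", len(zero_variance))
    return Design(X=X, y=y, site_of_obs=site_of_obs, unit=unit, zero_variance=zero_variance)


@dataclass
class AssociationResult:
    """Elastic-net fit for one environmental variable.

    Coefficients are on the standardized scale (predictors and response both
    standardized before fitting); the intercept is stored separately and is 0
    by construction for centered data.
    """

    variable: str
    coefficients: pd.Series
    intercept: float
    mixing: float
    penalty: float
    n_obs: int
    unit: str
    seed: int


def _site_folds(site_of_obs: pd.Series, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Grouped CV folds, one held-out site each (leave-one-site-out)."""
    sites = site_of_obs.to_numpy()
    n_sites = len(np.unique(sites))
    if n_sites < 2:
        raise ValueError("grouped cross-validation needs at least 2 sites")
    n_splits = n_sites
    if n_splits > len(sites):
        warnings.warn(
            "fewer observations than sites; falling back to leave-one-out folds",
            stacklevel=2,
        )
        n_splits = len(sites)
    splitter = GroupKFold(n_splits=n_splits)
    X_dummy = np.zeros((len(sites), 1))
    return list(splitter.split(X_dummy, groups=sites))


def fit_elastic_net(
    X: pd.DataFrame,
    y: pd.Series,
    site_of_obs: pd.Series,
    *,
    mixing: float = 0.85,
    zero_variance: Sequence[str] = (),
    seed: int = 0,
    n_penalties: int = 100,
    penalty_rule: str = "1se",
) -> AssociationResult:
    """Elastic-net penalized least squares for one response variable.

    The penalty is ``lam * (mixing * ||b||_1 + (1 - mixing)/2 * ||b||_2^2)``
    with the squared-error loss scaled by 1/(2n). Predictors and response are
    standardized (population sd) before fitting, so coefficients are
    comparable across groups and variables. Penalty strength is chosen by
    grouped cross-validation with one fold per site — responses are
    replicated within a site, so ungrouped CV would leak the held-out site's
    value into training folds.

    ``penalty_rule`` picks the penalty from the CV curve: ``"1se"`` (default)
    takes the largest penalty whose mean CV error is within one standard
    error of the minimum — the parsimony convention glmnet reports by
    default, which damps chance selections when there are only a handful of
    sites; ``"min"`` takes the error-minimizing penalty.
    """
    if penalty_rule not in {"1se", "min"}:
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")
    informative = [c for c in X.columns if c not in set(zero_variance)]
    Xi = X[informative].to_numpy(dtype=float)
    mu, sd = Xi.mean(axis=0), Xi.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xi - mu) / sd
    yv = y.to_numpy(dtype=float)
    y_sd = yv.std() or 1.0
    ys = (yv - yv.mean()) / y_sd

    folds = _site_folds(site_of_obs, seed)
    model = ElasticNetCV(
        l1_ratio=mixing,
        alphas=n_penalties,  # size of the automatic penalty path
        cv=folds,
        fit_intercept=True,
        max_iter=50_000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny folds
        model.fit(Xs, ys)
        penalty = float(model.alpha_)
        coefs = model.coef_
        intercept = float(model.intercept_)
        if penalty_rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            imin = int(np.argmin(mse))
            within = np.flatnonzero(mse <= mse[imin] + se[imin])
            penalty = float(model.alphas_[within].max())
            refit = ElasticNet(
                alpha=penalty, l1_ratio=mixing, fit_intercept=True, max_iter=50_000
            )
            refit.fit(Xs, ys)
            coefs = refit.coef_
            intercept = float(refit.intercept_)

    coef = pd.Series(0.0, index=X.columns, name=y.name)
    coef[informative] = coefs
    return AssociationResult(
        variable=str(y.name),
        coefficients=coef,
        intercept=intercept,
        mixing=mixing,
        penalty=penalty,
        n_obs=len(ys),
        unit="simulation",
        seed=seed,
    )


def fit_all_variables(
    design: Design, *, mixing: float = 0.85, seed: int = 0, penalty_rule: str = "1se"
) -> dict[str, AssociationResult]:
    """Fit one elastic net per environmental variable."""
    results: dict[str, AssociationResult] = {}
    for var in design.y.columns:
        res = fit_elastic_net(
            design.X,
            design.y[var],
            design.site_of_obs,
            mixing=mixing,
            zero_variance=design.zero_variance,
            seed=seed,
            penalty_rule=penalty_rule,
        )
        res.unit = design.unit
        results[var] = res
    return results


@dataclass
class KeyMetaboliteSet:
    """Groups passing the coefficient threshold and their member metabolites."""

    threshold: float
    selected_groups: list[str]
    coefficients: pd.DataFrame  # selected groups x variables, signed
    key_metabolites: frozenset[str]

    def coefficient_table(self) -> pd.DataFrame:
        """Long-format (group, variable, coefficient) table of selections."""
        rows = []
        for gid in self.coefficients.index:
            for var in self.coefficients.columns:
                c = self.coefficients.loc[gid, var]
                if abs(c) > self.threshold:
                    rows.append({"group": gid, "variable": var, "coefficient": c})
        return pd.DataFrame(rows, columns=["group", "variable", "coefficient"])


def select_key_metabolites(
    results: Mapping[str, AssociationResult],
    groups: list[MetaboliteGroup],
    threshold: float = 0.3,
) -> KeyMetaboliteSet:
    """Select groups with |coefficient| strictly greater than ``threshold``
    for at least one variable; key metabolites are their pooled members.

    Selection is monotone in the threshold: raising it never adds a group.
    """
    coef = pd.DataFrame({var: r.coefficients for var, r in results.items()})
    selected_mask = (coef.abs() > threshold).any(axis=1)
    selected = sorted(coef.index[selected_mask])
    by_id = {g.id: g for g in groups}
    members: set[str] = set()
    for gid in selected:
        members.update(by_id[gid].members)
    return KeyMetaboliteSet(
        threshold=threshold,
        selected_groups=selected,
        coefficients=coef.loc[selected],
        key_metabolites=frozenset(members),
    )


@dataclass
class VariableClustering:
    """Dendrogram over environmental variables plus a flat cut."""

    variables: list[str]
    linkage_matrix: np.ndarray
    flat_clusters: dict[str, int]


def cluster_variables(
    coefficients: pd.DataFrame, *, n_clusters: int = 3
) -> VariableClustering:
    """Cluster variables by their |coefficient| profiles over selected groups.

    Uses Bray-Curtis dissimilarity between the absolute coefficient profiles
    and Ward-type agglomeration on those dissimilarities (the ward.D2-style
    treatment of a precomputed distance matrix). A variable with an all-zero
    profile has no defined Bray-Curtis distance and is an error.
    """
    if coefficients.shape[1] < 2:
        raise ValueError("need at least 2 variables to cluster")
    profiles = coefficients.abs().T  # variables x groups
    dead = sorted(profiles.index[(profiles.sum(axis=1) == 0)])
    if dead:
        raise ValueError(f"all-zero coefficient profile for variable(s): {dead}")
    dists = pdist(profiles.to_numpy(), metric="braycurtis")
    Z = linkage(dists, method="ward")
    flat = fcluster(Z, t=min(n_clusters, len(profiles)), criterion="maxclust")
    return VariableClustering(
        variables=list(profiles.index),
        linkage_matrix=Z,
        flat_clusters={v: int(c) for v, c in zip(profiles.index, flat)},
    )
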