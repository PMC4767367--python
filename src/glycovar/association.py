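"""Genotype-group comparison with family-cluster-robust inference.

The analysis contrasts risk-allele carriers (CT/TT) against non-carriers
(CC) on continuous outcomes (CGM summary statistics, fasting labs,
anthropometrics) with covariate adjustment, in cohorts containing sibling
pairs. Inference uses the cluster-robust sandwich variance grouped by
family, with the small-sample factor [G/(G-1)]*[(N-1)/(N-k)] and a t(G-1)
reference distribution (G clusters, N rows, k parameters) -- the behaviour
of the clustered-robust option in the major commercial statistics packages,
so results are comparable with the published inference style. Model
p-values are complemented by Monte Carlo permutation p-values in which
group labels are shuffled across family clusters (members of a cluster move
together, preserving the exchangeability the clustered model assumes).

Mediation is quantified as percent-of-effect-explained: the relative drop
in the adjusted group coefficient when candidate mediators are added to the
model, after checking for group x mediator interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

MIN_ROWS = 10
MIN_CLUSTERS_FOR_PERMUTATION = 8


@dataclass
class ComparisonResult:
    """Adjusted group comparison for one outcome.

    ``beta`` is CT/TT minus CC on the model scale (log scale when
    ``scale == "log"``); group means/CIs are evaluated at covariate means
    and back-transformed to geometric means on the log scale.
    """

    outcome_name: str
    beta: float
    se_robust: float
    p_model: float
    p_permutation: float | None
    group_means: dict  # {"CC": (mean, lo, hi), "CT/TT": (mean, lo, hi)}
    n_cc: int
    n_ctt: int
    n_clusters: int
    scale: str  # "identity" | "log"


@dataclass
class MediationResult:
    """Percent-of-effect-explained mediation for one outcome."""

    outcome_name: str
    beta_unadjusted: float
    se_unadjusted: float
    p_unadjusted: float
    beta_adjusted: float
    se_adjusted: float
    p_adjusted: float
    percent_mediated: float
    interaction_p: dict  # mediator -> p-value
    n_analyzed: int
    interaction_flag: bool  # True when any interaction p < 0.05
    outside_0_100: bool


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _design(
    table: pd.DataFrame, group: str, covariates: list[str]
) -> pd.DataFrame:
    """const + group indicator + covariates, with string covariates dummy-coded."""
    cols = {"const": np.ones(len(table)), group: table[group].astype(float)}
    for cov in covariates:
        col = table[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[cov] = col.astype(float).to_numpy()
    return pd.DataFrame(cols, index=table.index)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for c in X.columns:
            if c == "const":
                continue
            sub = X.drop(columns=[c]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(c)
        raise ValueError(f"singular design; collinear columns: {bad or list(X.columns)}")


def _complete_cases(
    table: pd.DataFrame, cols: list[str]
) -> pd.DataFrame:
    return table.dropna(subset=[c for c in cols if c in table.columns])


def _fit_cluster_ols(y: np.ndarray, X: pd.DataFrame, clusters: np.ndarray):
    """OLS with Stata-style cluster-robust covariance and t(G-1) inference."""
    model = sm.OLS(np.asarray(y, dtype=float), X.astype(float))
    return model.fit(
        cov_type="cluster",
        cov_kwds={"groups": pd.Series(clusters).astype("category").cat.codes},
        use_t=True,
    )


# ---------------------------------------------------------------------------
# main operations


def fit_adjusted_comparison(
    table: pd.DataFrame,
    outcome: str,
    group: str = "risk_group",
    covariates: list[str] | None = None,
    cluster: str = "family_id",
    log_scale: bool = False,
) -> ComparisonResult:
    """Covariate-adjusted CT/TT-vs-CC comparison with cluster-robust SEs.

    Fits OLS of the (optionally log-transformed) outcome on the group
    indicator plus covariates; the cluster-robust sandwich grouped by family
    gives the SE and p-value. Adjusted group means are evaluated at the
    covariate means of the analysis sample and exponentiated to geometric
    means when ``log_scale``.
    """
    covariates = list(covariates or [])
    data = _complete_cases(table, [outcome, group, cluster] + covariates)
    if len(data) < MIN_ROWS:
        raise ValueError(
            f"{outcome}: only {len(data)} complete rows (need >= {MIN_ROWS})"
        )
    groups_present = data[group].astype(int).nunique()
    if groups_present < 2:
        raise ValueError(f"{outcome}: both genotype groups must be represented")

    y = data[outcome].to_numpy(dtype=float)
    if log_scale:
        if np.any(y <= 0):
            raise ValueError(f"{outcome}: log scale requires positive outcome")
        y = np.log(y)

    X = _design(data, group, covariates)
    _check_rank(X)
    res = _fit_cluster_ols(y, X, data[cluster].to_numpy())

    beta = float(res.params[group])
    se = float(res.bse[group])
    p_model = float(res.pvalues[group])

    # adjusted means at covariate means; CI from the robust covariance with
    # the same t(G-1) reference the coefficient test uses
    G = int(data[cluster].nunique())
    tcrit = stats.t.ppf(0.975, G - 1)
    cov = np.asarray(res.cov_params())
    xbar = X.mean(axis=0).to_numpy()
    gi = list(X.columns).index(group)
    means: dict[str, tuple[float, float, float]] = {}
    for label, gval in (("CC", 0.0), ("CT/TT", 1.0)):
        L = xbar.copy()
        L[gi] = gval
        m = float(L @ res.params.to_numpy())
        s = float(np.sqrt(L @ cov @ L))
        lo, hi = m - tcrit * s, m + tcrit * s
        if log_scale:
            m, lo, hi = np.exp(m), np.exp(lo), np.exp(hi)
        means[label] = (float(m), float(lo), float(hi))

    g = data[group].astype(int).to_numpy()
    return ComparisonResult(
        outcome_name=outcome,
        beta=beta,
        se_robust=se,
        p_model=p_model,
        p_permutation=None,
        group_means=means,
        n_cc=int((g == 0).sum()),
        n_ctt=int((g == 1).sum()),
        n_clusters=G,
        scale="log" if log_scale else "identity",
    )


def permutation_pvalue(
    table: pd.DataFrame,
    outcome: str,
    group: str = "risk_group",
    covariates: list[str] | None = None,
    cluster: str = "family_id",
    n_perm: int = 1000,
    seed: int = 0,
    log_scale: bool = False,
    unit: str = "cluster",
) -> float:
    """Monte Carlo permutation p-value for the adjusted group coefficient.

    The reference statistic is |beta| from the observed fit. By default the
    permutation unit is the family cluster: each cluster's vector of group
    labels moves as a unit, shuffled across clusters of the same size
    (genotype is family-correlated, so individual-level shuffling would
    break the exchangeability the clustered model assumes; equal-size
    clusters are exchangeable under the null, and sibling pairs whose
    members differ in genotype keep their internal pattern).
    ``unit="individual"`` shuffles labels across rows instead. Returns the
    add-one estimator (1 + #{|beta*| >= |beta|}) / (n_perm + 1).
    """
    covariates = list(covariates or [])
    data = _complete_cases(table, [outcome, group, cluster] + covariates)
    # permutation only needs a well-posed refit, so the gate is residual
    # degrees of freedom rather than the comparison's minimum sample size
    if len(data) < 4 + len(covariates):
        raise ValueError(f"{outcome}: too few complete rows for permutation")
    y = data[outcome].to_numpy(dtype=float)
    if log_scale:
        if np.any(y <= 0):
            raise ValueError(f"{outcome}: log scale requires positive outcome")
        y = np.log(y)

    X = _design(data, group, covariates)
    _check_rank(X)
    Xmat = X.to_numpy(dtype=float)
    gi = list(X.columns).index(group)

    beta_obs = abs(np.linalg.lstsq(Xmat, y, rcond=None)[0][gi])

    rng = np.random.default_rng(seed)
    if unit == "cluster":
        codes = pd.Series(data[cluster].to_numpy()).astype("category").cat.codes.to_numpy()
        n_clusters = codes.max() + 1
        if n_clusters < MIN_CLUSTERS_FOR_PERMUTATION:
            logger.warning(
                "%s: only %d clusters; permutation resolution is coarse",
                outcome,
                n_clusters,
            )
        # each cluster keeps its internal label pattern; the label vectors
        # are shuffled across clusters of the same size (clusters of equal
        # size are exchangeable under the null, and sibling pairs whose
        # members differ in genotype move as a unit)
        glabels = data[group].astype(float).to_numpy()
        members = [np.flatnonzero(codes == c) for c in range(n_clusters)]
        strata: dict[int, list[int]] = {}
        for c, rows_c in enumerate(members):
            strata.setdefault(rows_c.size, []).append(c)
        strata_rows = []  # (row index matrix, label vector matrix) per stratum
        for size, cl in strata.items():
            R = np.vstack([members[c] for c in cl])
            L = np.vstack([glabels[members[c]] for c in cl])
            strata_rows.append((R, L))
        exceed = 0
        Xp = Xmat.copy()
        perm_labels = np.empty_like(glabels)
        for _ in range(n_perm):
            for R, L in strata_rows:
                order = rng.permutation(L.shape[0])
                perm_labels[R.ravel()] = L[order].ravel()
            Xp[:, gi] = perm_labels
            b = np.linalg.lstsq(Xp, y, rcond=None)[0][gi]
            if abs(b) >= beta_obs - 1e-12:
                exceed += 1
    elif unit == "individual":
        glabels = data[group].astype(float).to_numpy()
        exceed = 0
        Xp = Xmat.copy()
        for _ in range(n_perm):
            Xp[:, gi] = rng.permutation(glabels)
            b = np.linalg.lstsq(Xp, y, rcond=None)[0][gi]
            if abs(b) >= beta_obs - 1e-12:
                exceed += 1
    else:
        raise ValueError("unit must be 'cluster' or 'individual'")

    return float((1 + exceed) / (n_perm + 1))


def interaction_test(
    table: pd.DataFrame,
    outcome: str,
    group: str = "risk_group",
    mediator: str = "weight",
    covariates: list[str] | None = None,
    cluster: str = "family_id",
) -> float:
    """Cluster-robust p-value of the group x mediator product term.

    The mediator is mean-centred before forming the product so the group
    main effect keeps its interpretation at the mediator mean.
    """
    covariates = list(covariates or [])
    data = _complete_cases(
        table, [outcome, group, cluster, mediator] + covariates
    ).copy()
    if len(data) < MIN_ROWS:
        raise ValueError(f"{outcome}: too few complete rows for interaction test")
    med_c = data[mediator].astype(float) - data[mediator].astype(float).mean()
    data["_med_c"] = med_c
    data["_interaction"] = med_c * data[group].astype(float)

    X = _design(data, group, covariates + ["_med_c", "_interaction"])
    _check_rank(X)
    y = data[outcome].to_numpy(dtype=float)
    res = _fit_cluster_ols(y, X, data[cluster].to_numpy())
    return float(res.pvalues["_interaction"])


def percent_mediated(beta_unadjusted: float, beta_adjusted: float) -> float:
    """Percent of the group effect explained by the added mediators.

    100 * (beta_unadjusted - beta_adjusted) / beta_unadjusted. May be
    negative or exceed 100 (suppression); callers flag that case.
    """
    if beta_unadjusted == 0:
        raise ValueError("percent mediated undefined for zero unadjusted effect")
    return float(100.0 * (beta_unadjusted - beta_adjusted) / beta_unadjusted)


def run_mediation(
    table: pd.DataFrame,
    outcome: str,
    group: str = "risk_group",
    mediators: list[str] | None = None,
    covariates: list[str] | None = None,
    cluster: str = "family_id",
) -> MediationResult:
    """Mediation as percent-of-effect-explained on a common complete-case set.

    Restricts to rows complete on outcome, mediators and covariates; tests
    group x mediator interaction per mediator first (an interaction p < 0.05
    flags the percent-mediated interpretation as invalid but the result is
    still returned); then fits the base and base+mediators models on the
    same rows and reports the relative coefficient drop.
    """
    mediators = list(mediators or ["weight", "pbf"])
    covariates = list(covariates or [])
    data = _complete_cases(
        table, [outcome, group, cluster] + covariates + mediators
    )
    if len(data) < MIN_ROWS:
        raise ValueError(f"{outcome}: too few complete rows for mediation")

    interaction_p = {
        m: interaction_test(data, outcome, group, m, covariates, cluster)
        for m in mediators
    }
    flag = any(p < 0.05 for p in interaction_p.values())
    if flag:
        logger.warning(
            "%s: mediation interpretation invalid under interaction (%s)",
            outcome,
            interaction_p,
        )

    base = fit_adjusted_comparison(data, outcome, group, covariates, cluster)
    full = fit_adjusted_comparison(
        data, outcome, group, covariates + mediators, cluster
    )
    pm = percent_mediated(base.beta, full.beta)
    return MediationResult(
        outcome_name=outcome,
        beta_unadjusted=base.beta,
        se_unadjusted=base.se_robust,
        p_unadjusted=base.p_model,
        beta_adjusted=full.beta,
        se_adjusted=full.se_robust,
        p_adjusted=full.p_model,
        percent_mediated=pm,
        interaction_p=interaction_p,
        n_analyzed=len(data),
        interaction_flag=flag,
        outside_0_100=not (0.0 <= pm <= 100.0),
    )


def hwe_test(n_cc: int, n_ct: int, n_tt: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Expected counts come from the observed T-allele frequency; a
    monomorphic sample is in trivial equilibrium (p = 1).
    """
    counts = np.array([n_cc, n_ct, n_tt], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p_t = (2 * n_tt + n_ct) / (2 * n)
    if p_t in (0.0, 1.0):
        logger.info("monomorphic sample; HWE p = 1 by convention")
        return 1.0
    expected = n * np.array([(1 - p_t) ** 2, 2 * p_t * (1 - p_t), p_t**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))
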