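"""Group-comparison models on home-level summaries and trends.

The daily-summary model regresses each home-level outcome on household type
(2-person vs 1-person), MCI-home status, their interaction, and demographic
covariates of the home:

    outcome ~ b0 + b1*two_person + b2*mci + b3*(two_person x mci)
              + b4*age + b5*females + b6*males + b7*white
              + b8*other_ethnicity + b9*rooms + b10*education

If the interaction is significant at alpha the analysis is stratified by
household type (dropping the household and interaction terms); otherwise the
interaction is removed and the pooled model refitted.  For the percentage of
rooms used the rooms covariate is excluded, since room count is already in
the outcome's denominator.

Note that females + males equals the resident count (1 + two_person) and
likewise white + other_ethnicity, so the stated design is structurally rank
deficient.  As in R's ``lm`` — which silently aliases such columns — exactly
collinear columns are detected and dropped (greedily, keeping the earliest
terms), and the dropped terms are recorded on the result.

Trajectory-class membership is tested with multinomial logistic regression
against the same covariates, with the largest class as reference.  Perfect
separation (a hazard with near-deterministic class/covariate relationships)
is detected and reported; a lightly ridge-penalized refit is returned in its
place, flagged unstable, rather than silently emitting divergent estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

ALPHA = 0.05  # two-sided significance threshold throughout

FULL_TERMS = [
    "intercept",
    "two_person",
    "mci",
    "two_person_x_mci",
    "age",
    "females",
    "males",
    "white",
    "other_ethnicity",
    "rooms",
    "education",
]
TREND_TERMS = ["intercept", "two_person", "mci", "two_person_x_mci", "age"]
SMALL_CLASS_MAX = 5  # classes with <= this many homes are not interpretable


@dataclass
class LinearModelResult:
    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_homes: int
    stratified: bool = False
    interaction_p: float | None = None
    dropped_terms: list[str] = field(default_factory=list)
    strata: dict[str, "LinearModelResult"] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse, "p": self.pvalues})


@dataclass
class ClassMembershipResult:
    outcome: str
    reference_class: int
    params: pd.DataFrame  # rows: terms, columns: non-reference classes
    bse: pd.DataFrame
    pvalues: pd.DataFrame
    class_sizes: dict[int, int]
    small_classes: list[int]
    separation: bool = False
    unstable: bool = False


def design_matrix(metadata: pd.DataFrame, terms=FULL_TERMS) -> pd.DataFrame:
    """Build the covariate design for a set of homes (indexed by home_id)."""
    two_person = (metadata["n_residents"] == 2).astype(float)
    mci = metadata["mci_home"].astype(float)
    cols = {
        "intercept": pd.Series(1.0, index=metadata.index),
        "two_person": two_person,
        "mci": mci,
        "two_person_x_mci": two_person * mci,
        "age": metadata["mean_age"].astype(float),
        "females": metadata["n_female"].astype(float),
        "males": metadata["n_male"].astype(float),
        "white": metadata["n_white"].astype(float),
        "other_ethnicity": metadata["n_other_ethnicity"].astype(float),
        "rooms": metadata["n_rooms"].astype(float),
        "education": metadata["mean_education"].astype(float),
    }
    return pd.DataFrame({t: cols[t] for t in terms})


def drop_collinear(X: pd.DataFrame, tol: float = 1e-8) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that are (near-)exact linear combinations of
    earlier columns, mirroring R's coefficient aliasing."""
    kept: list[str] = []
    dropped: list[str] = []
    M = X.to_numpy(dtype=float)
    basis = np.empty((len(X), 0))
    for j, name in enumerate(X.columns):
        col = M[:, j]
        scale = np.linalg.norm(col)
        if scale == 0:
            dropped.append(name)
            continue
        if basis.shape[1]:
            coef, *_ = np.linalg.lstsq(basis, col, rcond=None)
            resid = col - basis @ coef
        else:
            resid = col
        if np.linalg.norm(resid) <= tol * max(scale, 1.0):
            dropped.append(name)
        else:
            kept.append(name)
            basis = np.column_stack([basis, col])
    if dropped:
        logger.warning("dropping collinear design columns: %s", dropped)
    return X[kept], dropped


def _ols(y: pd.Series, X: pd.DataFrame, outcome: str, **extra) -> LinearModelResult:
    Xr, dropped = drop_collinear(X)
    if np.linalg.matrix_rank(Xr.to_numpy()) < Xr.shape[1]:
        raise np.linalg.LinAlgError(f"design still rank deficient: {list(Xr.columns)}")
    fit = sm.OLS(y.to_numpy(dtype=float), Xr).fit()
    return LinearModelResult(
        outcome=outcome,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        n_homes=len(y),
        dropped_terms=dropped,
        **extra,
    )


def fit_daily_lm(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    outcome: str,
    alpha: float = ALPHA,
    terms=FULL_TERMS,
) -> LinearModelResult:
    """Fit the daily-summary group comparison for one outcome.

    ``summaries`` is indexed by home_id with one column per outcome (homes
    already outlier-filtered).  Returns either the pooled fit without the
    interaction term, or — when the interaction is significant — a stratified
    result holding one fit per household type.
    """
    terms = list(terms)
    if outcome == "pct_rooms_used" and "rooms" in terms:
        terms.remove("rooms")
    homes = summaries.index.intersection(metadata.index)
    y = summaries.loc[homes, outcome]
    meta = metadata.loc[homes]
    X = design_matrix(meta, terms)

    full = _ols(y, X, outcome)
    p_int = float(full.pvalues.get("two_person_x_mci", np.nan))

    if np.isfinite(p_int) and p_int < alpha:
        strata = {}
        strat_terms = [t for t in terms if t not in ("two_person", "two_person_x_mci")]
        for label, n_res in (("one_person", 1), ("two_person", 2)):
            sel = meta["n_residents"] == n_res
            strata[label] = _ols(
                y[sel], design_matrix(meta[sel], strat_terms), outcome,
                interaction_p=p_int,
            )
        return LinearModelResult(
            outcome=outcome,
            params=full.params,
            bse=full.bse,
            pvalues=full.pvalues,
            n_homes=len(y),
            stratified=True,
            interaction_p=p_int,
            dropped_terms=full.dropped_terms,
            strata=strata,
        )
    pooled_terms = [t for t in terms if t != "two_person_x_mci"]
    return _ols(y, design_matrix(meta, pooled_terms), outcome, interaction_p=p_int)


def fit_trend_lm(
    trends: pd.DataFrame,
    metadata: pd.DataFrame,
    outcome: str,
    statistic: str = "slope",
    alpha: float = ALPHA,
) -> LinearModelResult:
    """Compare per-home trend slopes or variability between groups.

    Covariates are household type, MCI status, their interaction and mean
    age only; the same stratify-on-interaction rule applies.
    """
    if statistic not in {"slope", "variability"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    sub = trends[trends["outcome"] == outcome].set_index("home_id")
    wide = sub[[statistic]].rename(columns={statistic: outcome})
    return fit_daily_lm(wide, metadata, outcome, alpha=alpha, terms=TREND_TERMS)


def fit_class_membership(
    assignments: pd.Series,
    metadata: pd.DataFrame,
    outcome: str = "",
    terms=FULL_TERMS,
    separation_threshold: float = 30.0,
    ridge_alpha: float = 1e-4,
) -> ClassMembershipResult:
    """Multinomial logistic regression of trajectory class on covariates.

    ``assignments`` maps home_id to a class label.  The largest class is the
    reference; coefficients are log-odds of each other class versus it.
    Classes with <= 5 homes are fitted but flagged as too small to interpret.
    On (quasi-)separation the maximum-likelihood estimates diverge; this is
    detected (non-convergence or runaway coefficients) and a tiny-ridge refit
    is reported instead, flagged ``unstable``.
    """
    homes = assignments.index.intersection(metadata.index)
    y_raw = assignments.loc[homes]
    sizes = y_raw.value_counts().to_dict()
    if len(sizes) < 2:
        raise ValueError("need at least 2 classes with members")
    reference = sorted(sizes, key=lambda c: (-sizes[c], _class_key(c)))[0]
    order = [reference] + sorted((c for c in sizes if c != reference), key=_class_key)
    codes = y_raw.map({c: i for i, c in enumerate(order)}).to_numpy()

    X, dropped = drop_collinear(design_matrix(metadata.loc[homes], list(terms)))
    model = sm.MNLogit(codes, X.to_numpy())
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(method="bfgs", maxiter=500, disp=0)
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception:  # singular Hessian etc.
            fit, converged = None, False
    if fit is not None:
        try:
            bse = np.asarray(fit.bse, dtype=float)
            exploded = (
                np.abs(fit.params).max() > separation_threshold
                or not np.all(np.isfinite(bse))
                or bse.max() > 50.0  # log-odds SEs this large mean a flat ridge
            )
        except (ValueError, np.linalg.LinAlgError):  # singular Hessian
            exploded = True
    if fit is None or not converged or exploded:
        separation = True
        logger.warning(
            "class-membership model for %s: separation suspected; "
            "reporting ridge-penalized fit (alpha=%g), flagged unstable",
            outcome or "<outcome>", ridge_alpha,
        )
        params_a, bse_a, pvalues_a = _ridge_mnlogit(
            X.to_numpy(), codes, len(order), ridge_alpha * len(codes)
        )
    else:
        params_a = np.asarray(fit.params)
        bse_a = np.asarray(fit.bse)
        pvalues_a = np.asarray(fit.pvalues)

    non_ref = order[1:]
    params = pd.DataFrame(params_a, index=X.columns, columns=non_ref)
    bse = pd.DataFrame(bse_a, index=X.columns, columns=non_ref)
    pvalues = pd.DataFrame(pvalues_a, index=X.columns, columns=non_ref)
    small = [c for c, n in sizes.items() if n <= SMALL_CLASS_MAX]
    return ClassMembershipResult(
        outcome=outcome,
        reference_class=reference,
        params=params,
        bse=bse,
        pvalues=pvalues,
        class_sizes=sizes,
        small_classes=small,
        separation=separation,
        unstable=separation,
    )


def _ridge_mnlogit(X: np.ndarray, codes: np.ndarray, n_classes: int, penalty: float):
    """Newton fit of a multinomial logit with a small L2 penalty.

    Used only when the unpenalized likelihood diverges (separation); the
    penalty keeps the optimum finite and the penalized observed-information
    matrix supplies Wald standard errors.  Class 0 is the reference.
    """
    from scipy.stats import norm

    n, p = X.shape
    m = n_classes - 1
    Y = np.zeros((n, m))
    for k in range(1, n_classes):
        Y[:, k - 1] = codes == k
    B = np.zeros((p, m))
    for _ in range(200):
        eta = X @ B
        denom = 1.0 + np.exp(eta).sum(axis=1, keepdims=True)
        P = np.exp(eta) / denom  # (n, m)
        grad = X.T @ (P - Y) + penalty * B
        Hess = np.empty((p * m, p * m))
        for a in range(m):
            for b in range(m):
                w = P[:, a] * ((a == b) - P[:, b])
                Hess[a * p : (a + 1) * p, b * p : (b + 1) * p] = X.T @ (X * w[:, None])
        Hess += penalty * np.eye(p * m)
        step = np.linalg.solve(Hess, grad.T.ravel()).reshape(m, p).T
        B -= step
        if np.abs(step).max() < 1e-9:
            break
    cov = np.linalg.inv(Hess)
    se = np.sqrt(np.diag(cov)).reshape(m, p).T
    z = B / se
    pvals = 2 * norm.sf(np.abs(z))
    return B, se, pvals


def _class_key(c):
    return (0, int(c), "") if isinstance(c, (int, np.integer)) else (1, 0, str(c))


def benjamini_hochberg(pvalues: pd.Series, alpha: float = ALPHA) -> pd.Series:
    """Optional FDR adjustment for users who want multiplicity control
    (the default analysis applies none)."""
    from statsmodels.stats.multitest import multipletests

    _, adjusted, *_ = multipletests(pvalues.to_numpy(), alpha=alpha, method="fdr_bh")
    return pd.Series(adjusted, index=pvalues.index)
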