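"""Latent-class trajectory models for 24-point hour-to-hour profiles.

Each home contributes one profile per outcome: 24 values, the mean percent
of each clock hour spent in the outcome.  The model is a finite mixture of
polynomial growth curves over clock time: conditional on class ``k`` a
profile is

    y_i = X b_k + Z u_i + e_i,   u_i ~ N(0, G_k),   e_i ~ N(0, s2_k I),

with ``X`` a polynomial basis in the hour (scaled to [0, 1] so quartic
designs stay well conditioned) and ``Z`` a leading sub-basis for the random
effects.  Because the model is linear and Gaussian, the class marginal is
available in closed form, ``y_i | k ~ N(X b_k, Z G_k Z' + s2_k I)`` — no
numerical integration is involved.

Nine variance-structure families are supported:

====== ============ ======================================================
family fixed order  random effects / residual structure
====== ============ ======================================================
A      quadratic    none; one shared residual variance (homoscedastic)
B      quadratic    none; class-specific residual variances
C      quadratic    random intercept, shared G and residual variance
D      quadratic    random slope (intercept+linear), shared G
E      quadratic    random quadratic, G common across classes
F      quadratic    random quadratic, G_k = tau_k * G0 (proportional)
G      quadratic    random quadratic, unrestricted class-specific G_k, s2_k
H      cubic        as G with cubic fixed and random effects
I      quartic      as G with quartic fixed and random effects
====== ============ ======================================================

Fitting is by EM treating both the class label and the random effects as
missing data, so the observed-data log-likelihood is non-decreasing across
iterations (asserted on every run).  Model selection takes the lowest BIC
among converged fits; if the winner assigns fewer than 2 homes to some
class, the class count is lowered and the search repeated.  Labels are
canonicalized by descending class size so results do not depend on the
initial labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

N_HOURS = 24
MIN_CLASS_HOMES = 2  # selection rule: every class must hold >= 2 homes
SMALL_CLASS_MAX = 5


@dataclass(frozen=True)
class TrajectoryModelSpec:
    """One cell of the family x class-count grid."""

    family: str
    n_classes: int

    #: polynomial order of the class mean curves per family
    _ORDERS = {"A": 2, "B": 2, "C": 2, "D": 2, "E": 2, "F": 2, "G": 2, "H": 3, "I": 4}
    #: random-effect polynomial order (None = fixed effects only)
    _RE_ORDERS = {"A": None, "B": None, "C": 0, "D": 1, "E": 2, "F": 2, "G": 2, "H": 3, "I": 4}
    #: how G varies across classes: shared / proportional / free
    _G_KIND = {"C": "shared", "D": "shared", "E": "shared", "F": "proportional",
               "G": "free", "H": "free", "I": "free"}
    #: residual variance shared across classes?
    _SIGMA_SHARED = {"A": True, "B": False, "C": True, "D": True, "E": True,
                     "F": True, "G": False, "H": False, "I": False}

    def __post_init__(self):
        if self.family not in self._ORDERS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def order(self) -> int:
        return self._ORDERS[self.family]

    @property
    def re_order(self) -> int | None:
        return self._RE_ORDERS[self.family]

    @property
    def g_kind(self) -> str | None:
        return self._G_KIND.get(self.family)

    @property
    def sigma_shared(self) -> bool:
        return self._SIGMA_SHARED[self.family]

    def n_parameters(self) -> int:
        """Count of free parameters, audited per family.

        K(d+1) fixed effects + (K-1) mixing proportions + residual
        variance(s) + free elements of the random-effect covariance(s).
        Family A with K classes and quadratic curves gives 3K + (K-1) + 1.
        """
        K, d = self.n_classes, self.order
        p = K * (d + 1) + (K - 1)
        p += 1 if self.sigma_shared else K
        q = self.re_order
        if q is not None:
            tri = (q + 1) * (q + 2) // 2
            if self.g_kind == "shared":
                p += tri
            elif self.g_kind == "proportional":
                p += tri + (K - 1)  # tau_1 fixed at 1
            else:
                p += tri * K
        return p


@dataclass
class TrajectoryFit:
    spec: TrajectoryModelSpec
    beta: np.ndarray  # (K, d+1) on the scaled basis
    G: np.ndarray | None  # (K, q+1, q+1) or None for fixed-effect families
    sigma2: np.ndarray  # (K,)
    weights: np.ndarray  # (K,) mixing proportions
    posteriors: np.ndarray  # (N, K)
    modal: np.ndarray  # (N,) modal class, 0-based after canonical ordering
    loglik: float
    bic: float
    n_params: int
    converged: bool
    n_iter: int
    seed: int
    home_ids: list = field(default_factory=list)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.modal, minlength=self.spec.n_classes)

    def mean_curves(self, X: np.ndarray | None = None) -> np.ndarray:
        """Fitted class mean curves evaluated at the 24 hours, (K, 24)."""
        if X is None:
            X = design(self.spec.order)
        return self.beta @ X.T


def hour_times() -> np.ndarray:
    """Clock hours 0..23 scaled to [0, 1]."""
    return np.arange(N_HOURS) / (N_HOURS - 1)


def design(order: int) -> np.ndarray:
    t = hour_times()
    return np.vander(t, order + 1, increasing=True)


def rescale_coefficients(beta_scaled: np.ndarray) -> np.ndarray:
    """Convert coefficients on the scaled time basis back to raw hours.

    With t = h / 23, a polynomial sum_j b_j t^j equals sum_j (b_j / 23^j) h^j.
    """
    j = np.arange(beta_scaled.shape[-1])
    return beta_scaled / (N_HOURS - 1) ** j


def _mvn_logpdf(resid: np.ndarray, V: np.ndarray) -> np.ndarray:
    """log N(resid; 0, V) for rows of resid; V is (n, n) SPD."""
    c, low = cho_factor(V, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    sol = cho_solve((c, low), resid.T)  # (n, N)
    quad = np.einsum("in,ni->i", resid, sol)
    n = V.shape[0]
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


class _DegenerateFit(Exception):
    pass


def _em_once(
    Y: np.ndarray,
    spec: TrajectoryModelSpec,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> dict:
    """One EM run from a k-means++ start.  Raises _DegenerateFit on collapse."""
    N, n = Y.shape
    K, d, q = spec.n_classes, spec.order, spec.re_order
    X = design(d)
    XtX_inv_Xt = np.linalg.solve(X.T @ X, X.T)
    Z = X[:, : q + 1] if q is not None else None

    # ---- initialization: k-means++ on the raw 24-vectors ----
    from sklearn.cluster import kmeans_plusplus

    if K == 1:
        labels = np.zeros(N, dtype=int)
    else:
        centers, _ = kmeans_plusplus(
            Y, n_clusters=K, random_state=int(rng.integers(2**31 - 1))
        )
        d2 = ((Y[:, None, :] - centers[None]) ** 2).sum(-1)
        labels = d2.argmin(1)
    beta = np.empty((K, d + 1))
    sigma2 = np.empty(K)
    var_y = max(Y.var(), 1e-6)
    for k in range(K):
        members = Y[labels == k]
        if len(members) == 0:
            members = Y[rng.integers(0, N, size=2)]
        beta[k] = XtX_inv_Xt @ members.mean(0)
        resid = members - X @ beta[k]
        sigma2[k] = max(resid.var(), 1e-4 * var_y, 1e-10)
    if spec.sigma_shared:
        sigma2[:] = sigma2.mean()
    weights = np.bincount(labels, minlength=K).astype(float) + 1.0
    weights /= weights.sum()
    if q is not None:
        G = np.tile(np.eye(q + 1) * 0.1 * var_y, (K, 1, 1))
        tau = np.ones(K)
    else:
        G = None

    trace = []
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # ---- E-step: class responsibilities from the closed-form marginal
        logp = np.empty((N, K))
        chols = []
        for k in range(K):
            V = sigma2[k] * np.eye(n)
            if Z is not None:
                V = V + Z @ G[k] @ Z.T
            try:
                logp[:, k] = _mvn_logpdf(Y - X @ beta[k], V)
            except np.linalg.LinAlgError as err:
                raise _DegenerateFit("covariance not SPD") from err
        logp += np.log(weights)
        norm = logsumexp(logp, axis=1)
        new_loglik = float(norm.sum())
        if not np.isfinite(new_loglik):
            raise _DegenerateFit("non-finite log-likelihood")
        # EM guarantee: observed-data log-likelihood never decreases
        assert new_loglik >= loglik - 1e-7 * max(1.0, abs(loglik)), (
            f"EM log-likelihood decreased: {loglik} -> {new_loglik}"
        )
        resp = np.exp(logp - norm[:, None])
        trace.append(new_loglik)
        if loglik > -np.inf and (new_loglik - loglik) <= tol * max(1.0, abs(loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        # ---- M-step (class + random effects as missing data)
        wk = resp.sum(0)  # (K,)
        if wk.min() < 1e-8:
            raise _DegenerateFit("empty class")
        weights = wk / N

        if Z is None:
            rss = np.empty(K)
            for k in range(K):
                ybar = (resp[:, k] @ Y) / wk[k]
                beta[k] = XtX_inv_Xt @ ybar
                r = Y - X @ beta[k]
                rss[k] = resp[:, k] @ (r * r).sum(1)
            if spec.sigma_shared:
                sigma2[:] = rss.sum() / (N * n)
            else:
                sigma2 = rss / (wk * n)
        else:
            S = np.empty((K, q + 1, q + 1))  # E[u u'] per class
            rss = np.empty(K)
            tr_zsz = np.empty(K)
            for k in range(K):
                Ginv = np.linalg.inv(G[k])
                A = Z.T @ Z / sigma2[k] + Ginv
                Sigma_u = np.linalg.inv(A)
                R = Y - X @ beta[k]
                u_hat = (R @ Z) @ Sigma_u.T / sigma2[k]  # (N, q+1), E-step moments
                # joint M-step: beta from RE-corrected responses, then G and
                # sigma2 from the same (fixed) posterior moments
                ybar = (resp[:, k] @ (Y - u_hat @ Z.T)) / wk[k]
                beta[k] = XtX_inv_Xt @ ybar
                S[k] = (u_hat.T * resp[:, k]) @ u_hat / wk[k] + Sigma_u
                E = (Y - X @ beta[k]) - u_hat @ Z.T
                rss[k] = resp[:, k] @ (E * E).sum(1)
                tr_zsz[k] = np.trace(Z @ Sigma_u @ Z.T)
            if spec.sigma_shared:
                sigma2[:] = (rss.sum() + (wk * tr_zsz).sum()) / (N * n)
            else:
                sigma2 = rss / (wk * n) + tr_zsz / n
            if sigma2.min() < 1e-12:
                raise _DegenerateFit("residual variance collapsed")

            kind = spec.g_kind
            if kind == "shared":
                G_new = np.einsum("k,kij->ij", wk, S) / N
                G = np.tile(_spd_floor(G_new, var_y), (K, 1, 1))
            elif kind == "proportional":
                # G_k = tau_k * G0: one coordinate update each of G0 and tau
                G0 = np.einsum("k,kij->ij", wk / tau, S) / N
                G0 = _spd_floor(G0, var_y)
                G0_inv = np.linalg.inv(G0)
                tau = np.array(
                    [max(np.trace(G0_inv @ S[k]) / (q + 1), 1e-10) for k in range(K)]
                )
                # identifiability: absorb tau_1 into G0
                G0, tau = G0 * tau[0], tau / tau[0]
                G = tau[:, None, None] * G0
            else:  # free
                G = np.stack([_spd_floor(S[k], var_y) for k in range(K)])
    return {
        "beta": beta,
        "G": G,
        "sigma2": np.array(sigma2, dtype=float),
        "weights": weights,
        "posteriors": resp,
        "loglik": loglik,
        "converged": converged,
        "n_iter": it,
        "trace": np.array(trace),
    }


def _spd_floor(M: np.ndarray, scale: float) -> np.ndarray:
    """Symmetrize and floor eigenvalues so G stays invertible."""
    M = (M + M.T) / 2
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, 1e-10 * scale)
    return (V * w) @ V.T


def fit_lctm(
    profiles: pd.DataFrame | np.ndarray,
    family: str = "A",
    n_classes: int = 1,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> TrajectoryFit:
    """Fit one latent-class trajectory model by EM with multiple restarts.

    ``profiles`` holds one 24-value row per home (a DataFrame index supplies
    home ids).  Restarts are seeded from ``seed``; the best converged run by
    log-likelihood wins.  If every restart collapses (a class emptying or a
    variance degenerating) the fit is returned with ``converged=False``.
    """
    if isinstance(profiles, pd.DataFrame):
        home_ids = list(profiles.index)
        Y = profiles.to_numpy(dtype=float)
    else:
        Y = np.asarray(profiles, dtype=float)
        home_ids = list(range(len(Y)))
    if Y.ndim != 2 or Y.shape[1] != N_HOURS:
        raise ValueError(f"profiles must be (n_homes, {N_HOURS})")
    if not np.all(np.isfinite(Y)):
        raise ValueError("profiles contain non-finite values")
    spec = TrajectoryModelSpec(family, n_classes)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        try:
            run = _em_once(Y, spec, rng, max_iter, tol)
        except _DegenerateFit as err:
            logger.debug("restart degenerate (%s), retrying", err)
            continue
        if best is None or run["loglik"] > best["loglik"]:
            best = run
    if best is None:
        zeros = np.zeros
        return TrajectoryFit(
            spec=spec, beta=zeros((n_classes, spec.order + 1)), G=None,
            sigma2=zeros(n_classes), weights=np.full(n_classes, 1 / n_classes),
            posteriors=np.full((len(Y), n_classes), 1 / n_classes),
            modal=zeros(len(Y), dtype=int), loglik=-np.inf, bic=np.inf,
            n_params=spec.n_parameters(), converged=False, n_iter=0,
            seed=seed, home_ids=home_ids,
        )
    fit = _package(best, spec, home_ids, seed, n_obs=len(Y))
    return fit


def _package(run: dict, spec, home_ids, seed, n_obs) -> TrajectoryFit:
    modal = run["posteriors"].argmax(1)
    # canonical labels: descending class size, ties by mean level then index
    sizes = np.bincount(modal, minlength=spec.n_classes)
    level = design(spec.order) @ run["beta"].T  # (24, K)
    order = sorted(
        range(spec.n_classes), key=lambda k: (-sizes[k], -level[:, k].mean(), k)
    )
    perm = np.array(order)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    n_params = spec.n_parameters()
    loglik = run["loglik"]
    return TrajectoryFit(
        spec=spec,
        beta=run["beta"][perm],
        G=None if run["G"] is None else run["G"][perm],
        sigma2=run["sigma2"][perm],
        weights=run["weights"][perm],
        posteriors=run["posteriors"][:, perm],
        modal=inv[modal],
        loglik=loglik,
        bic=-2.0 * loglik + n_params * np.log(n_obs),
        n_params=n_params,
        converged=run["converged"],
        n_iter=run["n_iter"],
        seed=seed,
        home_ids=home_ids,
        loglik_trace=run["trace"],
    )


def select_model(
    profiles,
    k_range=range(1, 7),
    families: str = "ABCDEFGHI",
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[TrajectoryFit, pd.DataFrame]:
    """Grid search over families and class counts with BIC selection.

    Non-converged fits are excluded from the ranking.  If the BIC winner has
    a class with fewer than 2 homes, the class count is capped below the
    winner's and the selection repeated (the variance-family choice stays
    open), mirroring the rule of lowering the number of classes until every
    class holds at least 2 homes.  Returns the chosen fit and the full
    ranking table.
    """
    fits: dict[tuple[str, int], TrajectoryFit] = {}
    rows = []
    for fam in families:
        for k in k_range:
            fit = fit_lctm(
                profiles, fam, k, seed=seed + 1000 * (ord(fam) * 7 + k),
                n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            )
            fits[(fam, k)] = fit
            rows.append(
                {
                    "family": fam,
                    "n_classes": k,
                    "loglik": fit.loglik,
                    "bic": fit.bic,
                    "n_params": fit.n_params,
                    "converged": fit.converged,
                    "min_class_size": int(fit.class_sizes.min()) if fit.converged else 0,
                }
            )
    ranking = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    return choose_from_ranking(fits, ranking), ranking


def choose_from_ranking(
    fits: dict[tuple[str, int], TrajectoryFit], ranking: pd.DataFrame
) -> TrajectoryFit:
    """Apply the converged-lowest-BIC rule with the <2-home class collapse."""
    k_cap = None
    while True:
        candidates = ranking[ranking["converged"]]
        if k_cap is not None:
            candidates = candidates[candidates["n_classes"] < k_cap]
        if candidates.empty:
            raise RuntimeError(
                "no converged model satisfies the class-size rule; "
                f"ranking:\n{ranking.to_string()}"
            )
        top = candidates.iloc[0]
        fit = fits[(top["family"], int(top["n_classes"]))]
        if fit.class_sizes.min() >= MIN_CLASS_HOMES:
            return fit
        logger.info(
            "model %s/K=%d has a class with <%d homes; lowering class count",
            top["family"], top["n_classes"], MIN_CLASS_HOMES,
        )
        k_cap = int(top["n_classes"])


def assign_classes(fit: TrajectoryFit) -> pd.DataFrame:
    """Modal class per home, with too-small classes flagged.

    Classes with <= 5 homes are kept but flagged: they are too small for the
    downstream membership regression to be interpretable.
    """
    if not fit.converged:
        raise ValueError("cannot assign classes from a non-converged fit")
    sizes = fit.class_sizes
    return pd.DataFrame(
        {
            "home_id": fit.home_ids,
            "class": fit.modal,
            "posterior": fit.posteriors.max(1),
            "small_class": sizes[fit.modal] <= SMALL_CLASS_MAX,
        }
    ).set_index("home_id")
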