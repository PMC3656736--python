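"""REML variance components and BLUP/GBLUP breeding-value prediction.

The model is the clone-repeatability animal model

    y = X b + Z u + e,   Var(u) = K sigma2_a,   Var(e) = I sigma2_e,

with y tree-level records, X fixed site effects (cell-means coding, one
column per site), Z the tree-to-clone incidence, and K a relationship
matrix: A (pedigree), G (markers), or I (no relationships, clone means
only).

Variance components are estimated by exact REML: the restricted
log-likelihood is profiled down to the single variance ratio
gamma = sigma2_a / sigma2_e using the mixed-model-equation determinant
identities, and the profile is minimized by bounded scalar search on
log(gamma).  Predictions come either from Henderson's mixed-model equations
on tree-level records (with prediction-error variances from the inverse
coefficient matrix) or from the two clone-mean GBLUP forms

    u_hat = G [G + R lambda]^-1 (ybar - X b_hat)            (selection index)
    u_hat = [R^-1 + G^-1 lambda]^-1 R^-1 (ybar - X b_hat)   (inverted-G MME)

which are algebraically identical when G is invertible; both use the GLS
fixed-effect solution so all three routes agree to numerical precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .datatypes import validate_phenotypes
from .relationships import RelationshipMatrix

logger = logging.getLogger("clonalgp")

_LOG_GAMMA_BOUNDS = (-14.0, 14.0)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    converged: bool = True
    boundary: bool = False
    n_evaluations: int = 0
    neg2_restricted_ll: float = math.nan  # up to an additive constant

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio lambda = sigma2_e / sigma2_a."""
        return self.sigma2_e / self.sigma2_a

    @property
    def heritability(self) -> float:
        """Individual-tree (single-ramet) heritability."""
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)

    def marker_variance(self, freqs: np.ndarray) -> float:
        """Per-marker variance sigma2_m = sigma2_a / (2 sum p_i (1 - p_i))."""
        freqs = np.asarray(freqs, dtype=float)
        return self.sigma2_a / (2.0 * float(np.sum(freqs * (1.0 - freqs))))


@dataclass
class BreedingValueSet:
    """Per-clone predictions with prediction SE and reliability accuracy."""

    table: pd.DataFrame  # index clone_id; columns value, se, accuracy
    method: str
    meta: dict = field(default_factory=dict)

    def values_for(self, ids) -> np.ndarray:
        return self.table.loc[list(ids), "value"].to_numpy()

    def se_for(self, ids) -> np.ndarray:
        return self.table.loc[list(ids), "se"].to_numpy()


@dataclass
class MixedModelSpec:
    """Design matrices for the clone model, bound to a relationship matrix."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    K: RelationshipMatrix
    clone_ids: np.ndarray
    site_levels: tuple

    @classmethod
    def from_tables(cls, pheno: pd.DataFrame, K: RelationshipMatrix) -> "MixedModelSpec":
        """Build y, X (site cell-means), Z (tree->clone) from a phenotype
        table.  Every phenotyped clone must appear in K; clones in K without
        phenotypes get zero columns in Z and are predicted from relatives."""
        validate_phenotypes(pheno)
        clones = np.asarray(K.ids, dtype=object)
        pos = {c: i for i, c in enumerate(clones)}
        unknown = set(pheno["clone_id"]) - set(clones)
        if unknown:
            raise ValueError(
                f"phenotyped clones absent from relationship matrix: "
                f"{sorted(unknown)[:5]}"
            )
        y = pheno["volume"].to_numpy(dtype=float)
        sites = tuple(sorted(pheno["site_id"].astype(str).unique()))
        site_idx = pheno["site_id"].astype(str).map({s: i for i, s in enumerate(sites)})
        X = np.zeros((len(pheno), len(sites)))
        X[np.arange(len(pheno)), site_idx.to_numpy()] = 1.0
        Z = np.zeros((len(pheno), len(clones)))
        clone_idx = pheno["clone_id"].map(pos).to_numpy()
        Z[np.arange(len(pheno)), clone_idx] = 1.0
        return cls(y=y, X=X, Z=Z, K=K, clone_ids=clones, site_levels=sites)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)


class _CrossProducts:
    """Sufficient statistics of the MME, computed once per data set."""

    def __init__(self, spec: MixedModelSpec):
        X, Z, y = spec.X, spec.Z, spec.y
        self.XtX = X.T @ X
        self.XtZ = X.T @ Z
        self.ZtZ = Z.T @ Z
        self.Xty = X.T @ y
        self.Zty = Z.T @ y
        self.yty = float(y @ y)
        self.n = spec.n
        self.p = spec.n_fixed
        self.q = spec.n_clones
        self.rhs = np.concatenate([self.Xty, self.Zty])

    def coefficient_matrix(self, lam: float, Kinv: np.ndarray) -> np.ndarray:
        p, q = self.p, self.q
        M = np.empty((p + q, p + q))
        M[:p, :p] = self.XtX
        M[:p, p:] = self.XtZ
        M[p:, :p] = self.XtZ.T
        M[p:, p:] = self.ZtZ + lam * Kinv
        return M


def _safe_cho_factor(mat: np.ndarray, what: str):
    """Cholesky with an escalating relative ridge fallback (logged)."""
    scale = max(float(np.mean(np.diag(mat))), 1e-300)
    for ridge in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return cho_factor(mat + (ridge * scale) * np.eye(mat.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            if ridge > 0:
                logger.warning("%s not positive definite at ridge %g", what, ridge)
            continue
    raise np.linalg.LinAlgError(f"{what} is singular; blend the relationship matrix with A")


def _kinv_logdet(K: RelationshipMatrix) -> tuple[np.ndarray, float]:
    cf = _safe_cho_factor(K.values, f"{K.flavor} relationship matrix")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Kinv = cho_solve(cf, np.eye(len(K)))
    return 0.5 * (Kinv + Kinv.T), logdet


def _neg2ll_profiled(
    log_gamma: float, cp: _CrossProducts, Kinv: np.ndarray, logdetK: float
) -> tuple[float, float, np.ndarray]:
    """Profiled -2 restricted log-likelihood at gamma = exp(log_gamma).

    Uses |V0| |X'V0^-1 X| = |gamma K| |M(1/gamma)| where M is the unscaled
    MME coefficient matrix, and y'P0y from the MME solutions.
    """
    gamma = math.exp(log_gamma)
    M = cp.coefficient_matrix(1.0 / gamma, Kinv)
    cf = _safe_cho_factor(M, "MME coefficient matrix")
    logdetM = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sol = cho_solve(cf, cp.rhs)
    yPy = max(cp.yty - float(cp.rhs @ sol), 1e-300)
    df = cp.n - cp.p
    val = df * math.log(yPy) + logdetM + logdetK + cp.q * math.log(gamma)
    return val, yPy, sol


def fit_reml(
    spec: MixedModelSpec,
    xatol: float = 1e-10,
    bounds: tuple = _LOG_GAMMA_BOUNDS,
) -> VarianceComponents:
    """Exact REML for the two-component clone model.

    Deterministic given the data and tolerances.  If the optimum sits at the
    search boundary (a variance effectively zero), the corresponding
    component is clamped at a small positive floor and flagged.
    """
    if spec.n <= spec.n_fixed + 1:
        raise ValueError("too few records to estimate variance components")
    if len(np.unique(spec.Z.argmax(axis=1)[spec.Z.any(axis=1)])) < 2:
        raise ValueError("need phenotypes on at least two clones")
    cp = _CrossProducts(spec)
    Kinv, logdetK = _kinv_logdet(spec.K)
    evals = [0]

    def objective(lg: float) -> float:
        evals[0] += 1
        return _neg2ll_profiled(lg, cp, Kinv, logdetK)[0]

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    lg = float(res.x)
    val, yPy, _ = _neg2ll_profiled(lg, cp, Kinv, logdetK)
    df = cp.n - cp.p
    sigma2_e = yPy / df
    sigma2_a = math.exp(lg) * sigma2_e
    boundary = (lg - bounds[0] < 0.01) or (bounds[1] - lg < 0.01)
    floor = 1e-9 * (cp.yty / cp.n + 1.0)
    if sigma2_e < floor or sigma2_a < floor:
        boundary = True
    if boundary:
        logger.warning(
            "REML estimate at boundary (log-ratio %.2f); clamping at floor", lg
        )
    sigma2_e = max(sigma2_e, floor)
    sigma2_a = max(sigma2_a, floor)
    return VarianceComponents(
        sigma2_a=float(sigma2_a),
        sigma2_e=float(sigma2_e),
        converged=bool(res.success),
        boundary=boundary,
        n_evaluations=evals[0],
        neg2_restricted_ll=float(val),
    )


def accuracy_from_se(se: float, f: float, sigma2_a: float) -> float:
    """Reliability-based accuracy r = sqrt(1 - SE^2 / ((1 + f) sigma2_a)).

    SE is the prediction standard error, f the (pedigree or genomic)
    inbreeding coefficient, sigma2_a the additive variance.  Values where
    SE^2 exceeds (1 + f) sigma2_a (numerical overshoot) clamp to 0 with a
    warning."""
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    if se < 0:
        raise ValueError("SE must be non-negative")
    denom = (1.0 + f) * sigma2_a
    inside = 1.0 - se * se / denom
    if inside < 0:
        logger.warning("SE^2 exceeds (1+f) sigma2_a; accuracy clamped to 0")
        return 0.0
    return min(math.sqrt(inside), 1.0)


def _accuracies(se: np.ndarray, f: np.ndarray, sigma2_a: float) -> np.ndarray:
    return np.array([accuracy_from_se(s, fi, sigma2_a) for s, fi in zip(se, f)])


def solve_blup(
    spec: MixedModelSpec, vc: VarianceComponents, method: str = "EBV"
) -> BreedingValueSet:
    """Henderson's mixed-model equations on tree-level records.

    Returns per-clone predictions, SE = sqrt(PEV) from the u-block of the
    inverse coefficient matrix, and the reliability accuracy with
    f = diag(K) - 1.  Fixed-effect (site) solutions are stored in ``meta``.
    """
    cp = _CrossProducts(spec)
    Kinv, _ = _kinv_logdet(spec.K)
    M = cp.coefficient_matrix(vc.lambda_, Kinv)
    try:
        cf = cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations: fixed effects confounded with "
            "clones, or relationship matrix singular"
        ) from None
    sol = cho_solve(cf, cp.rhs)
    Minv = cho_solve(cf, np.eye(M.shape[0]))
    p = cp.p
    u = sol[p:]
    pev = vc.sigma2_e * np.diag(Minv)[p:]
    se = np.sqrt(np.maximum(pev, 0.0))
    f = spec.K.diagonal() - 1.0
    table = pd.DataFrame(
        {
            "value": u,
            "se": se,
            "accuracy": _accuracies(se, f, vc.sigma2_a),
        },
        index=list(spec.clone_ids),
    )
    table.index.name = "clone_id"
    return BreedingValueSet(
        table=table,
        method=method,
        meta={
            "fixed_effects": dict(zip(spec.site_levels, sol[:p])),
            "relationship_flavor": spec.K.flavor,
        },
    )


def _adjusted_clone_means(spec: MixedModelSpec, vc: VarianceComponents):
    """GLS fixed effects via the MME, then fixed-effect-adjusted clone means.

    Returns (b_hat, ybar_adj over observed clones, ramet counts n_i,
    observed-clone boolean mask, Kinv)."""
    cp = _CrossProducts(spec)
    Kinv, _ = _kinv_logdet(spec.K)
    M = cp.coefficient_matrix(vc.lambda_, Kinv)
    cf = _safe_cho_factor(M, "MME coefficient matrix")
    sol = cho_solve(cf, cp.rhs)
    b = sol[: cp.p]
    resid = spec.y - spec.X @ b
    clone_sums = spec.Z.T @ resid
    n_i = np.diag(cp.ZtZ).copy()
    obs = n_i > 0
    ybar = np.zeros_like(clone_sums)
    ybar[obs] = clone_sums[obs] / n_i[obs]
    return b, ybar, n_i, obs, Kinv


def gblup_selection_index(
    pheno: pd.DataFrame,
    G: RelationshipMatrix,
    vc: VarianceComponents,
    method: str = "GEBVa",
) -> BreedingValueSet:
    """GBLUP in selection-index form: u_hat = G [G + R lambda]^-1 (ybar - Xb).

    Operates on fixed-effect-adjusted clone means with R = diag(1/n_i)
    (clone-mean residual variance sigma2_e / n_i).  Predictions are produced
    for every clone in G, including unphenotyped ones, through the index
    weights on relatives; no inverse of G is required.
    """
    spec = MixedModelSpec.from_tables(pheno, G)
    b, ybar, n_i, obs, _ = _adjusted_clone_means(spec, vc)
    lam = vc.lambda_
    g = G.values
    C_oo = g[np.ix_(obs, obs)] + lam * np.diag(1.0 / n_i[obs])
    try:
        cf = cho_factor(C_oo, lower=True)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "G + R*lambda is singular; consider blend_with_A"
        ) from None
    w = cho_solve(cf, ybar[obs])
    u = g[:, obs] @ w
    T = cho_solve(cf, g[obs, :])
    pev = vc.sigma2_a * (np.diag(g) - np.einsum("io,oi->i", g[:, obs], T))
    se = np.sqrt(np.maximum(pev, 0.0))
    f = np.diag(g) - 1.0
    table = pd.DataFrame(
        {"value": u, "se": se, "accuracy": _accuracies(se, f, vc.sigma2_a)},
        index=list(spec.clone_ids),
    )
    table.index.name = "clone_id"
    return BreedingValueSet(
        table=table, method=method,
        meta={"form": "selection_index", "fixed_effects": dict(zip(spec.site_levels, b))},
    )


def gblup_mme(
    pheno: pd.DataFrame,
    G: RelationshipMatrix,
    vc: VarianceComponents,
    method: str = "GEBVb",
) -> BreedingValueSet:
    """GBLUP in inverted-G form: u_hat = [R^-1 + G^-1 lambda]^-1 R^-1 (ybar - Xb).

    Same adjusted clone-mean data as the selection-index form, but solved
    through G^-1 (efficient when G is invertible and R diagonal).  PEV per
    clone from the inverse of (D / sigma2_e + G^-1 / sigma2_a).
    """
    spec = MixedModelSpec.from_tables(pheno, G)
    b, ybar, n_i, obs, Ginv = _adjusted_clone_means(spec, vc)
    B = np.diag(n_i / vc.sigma2_e) + Ginv / vc.sigma2_a
    cf = _safe_cho_factor(B, "inverted-G GBLUP system")
    u = cho_solve(cf, (n_i * ybar) / vc.sigma2_e)
    Binv = cho_solve(cf, np.eye(B.shape[0]))
    pev = np.diag(Binv)
    se = np.sqrt(np.maximum(pev, 0.0))
    f = G.diagonal() - 1.0
    table = pd.DataFrame(
        {"value": u, "se": se, "accuracy": _accuracies(se, f, vc.sigma2_a)},
        index=list(spec.clone_ids),
    )
    table.index.name = "clone_id"
    return BreedingValueSet(
        table=table, method=method,
        meta={"form": "inverted_G_mme", "fixed_effects": dict(zip(spec.site_levels, b))},
    )


def blup_joint_inverse(
    pheno: pd.DataFrame, K: RelationshipMatrix, vc: VarianceComponents
) -> np.ndarray:
    """Brute-force BLUP through the full n x n phenotypic covariance matrix:
    b = (X'V^-1X)^-1 X'V^-1 y, u = sigma2_a K Z' V^-1 (y - Xb).

    Reference route for small problems; O(n^3) in the number of trees.
    """
    spec = MixedModelSpec.from_tables(pheno, K)
    V = vc.sigma2_a * (spec.Z @ K.values @ spec.Z.T) + vc.sigma2_e * np.eye(spec.n)
    Vinv = np.linalg.inv(V)
    XtVinv = spec.X.T @ Vinv
    b = np.linalg.solve(XtVinv @ spec.X, XtVinv @ spec.y)
    return vc.sigma2_a * (K.values @ (spec.Z.T @ (Vinv @ (spec.y - spec.X @ b))))
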