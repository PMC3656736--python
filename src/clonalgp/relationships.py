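"""Pedigree (A) and realized genomic (G) relationship matrices.

Two constructions of G are provided.  The allele-frequency method centers
dosages at twice the allele frequency and scales by twice the summed marker
heterozygosity, G = ZZ'/(2 sum p_i(1-p_i)), so that G is on the same scale as
the numerator relationship matrix A.  The regression method codes dosages as
M = dosage - 1 and regresses the cells of MM' on the corresponding cells of A
(MM' = g0 11' + g1 A + e); G = (MM' - g0 11')/g1 then has expectation A plus
a constant under the model, without needing allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import UNKNOWN_PARENT, GenotypeMatrix, PedigreeTable

logger = logging.getLogger("clonalgp")

_SYMMETRY_TOL = 1e-8


@dataclass
class RelationshipMatrix:
    """Labeled symmetric relationship matrix (A, G, or identity flavor)."""

    ids: np.ndarray
    values: np.ndarray
    flavor: str = "A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("relationship matrix is not symmetric")
        # enforce exact symmetry for downstream factorizations
        self.values = 0.5 * (self.values + self.values.T)

    def __len__(self) -> int:
        return len(self.ids)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values).copy()

    def submatrix(self, ids) -> "RelationshipMatrix":
        pos = {c: i for i, c in enumerate(self.ids)}
        idx = np.array([pos[c] for c in ids])
        return RelationshipMatrix(
            np.asarray(list(ids), dtype=object),
            self.values[np.ix_(idx, idx)],
            flavor=self.flavor,
            meta=dict(self.meta),
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_singular(self, tol: float = 1e-8) -> bool:
        scale = max(float(np.mean(self.diagonal())), 1e-300)
        return self.min_eigenvalue() < tol * scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def identity(cls, ids) -> "RelationshipMatrix":
        ids = np.asarray(list(ids), dtype=object)
        return cls(ids, np.eye(len(ids)), flavor="I")


@dataclass
class RegressionFit:
    """Intercept/slope of the MM'-on-A regression behind the G_reg matrix."""

    g0: float
    g1: float


def build_numerator_relationship(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular (recursive) method.

    Requires the pedigree's topological order (parents first), which
    :class:`PedigreeTable` guarantees.  Unknown parents contribute zero, so
    founders are treated as unrelated and non-inbred.
    """
    n = len(ped)
    pos = {ind: i for i, ind in enumerate(ped.individual)}
    A = np.zeros((n, n))
    for j, (ind, s, d) in enumerate(zip(ped.individual, ped.sire, ped.dam)):
        si = pos[s] if s != UNKNOWN_PARENT else -1
        di = pos[d] if d != UNKNOWN_PARENT else -1
        if si >= j or di >= j:
            raise ValueError(f"pedigree not sorted: parent of {ind} appears later")
        row = np.zeros(j)
        if si >= 0:
            row += 0.5 * A[si, :j]
        if di >= 0:
            row += 0.5 * A[di, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(np.asarray(ped.individual, dtype=object), A, flavor="A")


def build_G_allele_frequency(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Allele-frequency G: Z = dosage - 2p, G = ZZ' / (2 sum p_i (1 - p_i)).

    Parameters
    ----------
    freqs:
        Per-marker frequency of the counted allele.  Defaults to the sample
        frequencies; a breeding program would ideally supply frequencies from
        the unselected base population here.

    Notes
    -----
    With sample frequencies the column centering makes G exactly singular
    (the ones vector lies in its null space); blend with A before inverting.
    """
    if not geno.is_complete:
        raise ValueError("G requires a complete (imputed) dosage matrix")
    source = "sample"
    if freqs is None:
        freqs = geno.allele_frequencies()
    else:
        freqs = np.asarray(freqs, dtype=float)
        source = "supplied"
        if freqs.shape != (geno.n_markers,):
            raise ValueError("allele-frequency vector length mismatch")
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        bad = np.flatnonzero((freqs <= 0.0) | (freqs >= 1.0))[0]
        raise ValueError(
            f"marker {geno.marker_ids[bad]!r} has allele frequency "
            f"{freqs[bad]}; filter monomorphic markers first"
        )
    Z = geno.dosage - 2.0 * freqs
    denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(
        geno.clone_ids.copy(),
        G,
        flavor="G_freq",
        meta={"freq_source": source, "denominator": denom},
    )


def build_G_regression(
    geno: GenotypeMatrix, A: RelationshipMatrix
) -> tuple[RelationshipMatrix, RegressionFit]:
    """Regression G: solve MM' = g0 11' + g1 A + e over all n^2 cell pairs.

    M is the dosage matrix coded -1/0/1 (dosage - 1).  The 2x2 normal
    equations run over every (j, k) pair including diagonals.  A must cover
    the same individuals in the same order.
    """
    if not geno.is_complete:
        raise ValueError("G requires a complete (imputed) dosage matrix")
    if list(A.ids) != list(geno.clone_ids):
        A = A.submatrix(geno.clone_ids)
    n = geno.n_clones
    if geno.n_markers <= n:
        logger.warning(
            "number of markers (%d) does not exceed number of individuals (%d); "
            "the regression G may be singular", geno.n_markers, n,
        )
    M = geno.dosage - 1.0
    S = M @ M.T
    a = A.values
    lhs = np.array([[float(n) ** 2, a.sum()], [a.sum(), (a * a).sum()]])
    rhs = np.array([S.sum(), (S * a).sum()])
    g0, g1 = np.linalg.solve(lhs, rhs)
    if g1 <= 0:
        raise ValueError(f"regression slope g1 = {g1:.4g} is not positive")
    G = (S - g0) / g1
    fit = RegressionFit(g0=float(g0), g1=float(g1))
    return (
        RelationshipMatrix(
            geno.clone_ids.copy(), G, flavor="G_reg",
            meta={"g0": fit.g0, "g1": fit.g1},
        ),
        fit,
    )


def genomic_inbreeding(G: RelationshipMatrix) -> pd.Series:
    """Genomic inbreeding coefficient per individual: f_j = G_jj - 1."""
    return pd.Series(G.diagonal() - 1.0, index=list(G.ids), name="f")


def normalize_relationships(G: RelationshipMatrix) -> RelationshipMatrix:
    """Correlation form: divide G_jk by sqrt(G_jj G_kk); unit diagonal."""
    d = G.diagonal()
    if np.any(d <= 0):
        raise ValueError("cannot normalize: non-positive diagonal element")
    s = np.sqrt(d)
    vals = G.values / np.outer(s, s)
    np.fill_diagonal(vals, 1.0)
    return RelationshipMatrix(
        G.ids.copy(), vals, flavor=G.flavor, meta={**G.meta, "normalized": True}
    )


def blend_with_A(
    G: RelationshipMatrix, A: RelationshipMatrix, weight: float = 0.01
) -> RelationshipMatrix:
    """G* = (1 - w) G + w A; the standard fix for a singular G."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("blend weight must lie in [0, 1]")
    if list(A.ids) != list(G.ids):
        A = A.submatrix(G.ids)
    vals = (1.0 - weight) * G.values + weight * A.values
    return RelationshipMatrix(
        G.ids.copy(), vals, flavor=G.flavor,
        meta={**G.meta, "blended_with_A": weight},
    )


def ensure_invertible(
    K: RelationshipMatrix,
    A: RelationshipMatrix | None = None,
    weight: float = 0.01,
    tol: float = 1e-8,
) -> RelationshipMatrix:
    """Return K usable in factorizations, blending with A (or adding a small
    ridge) when the smallest eigenvalue is below tolerance.  Logged."""
    if not K.is_singular(tol):
        return K
    if A is not None:
        logger.warning(
            "%s matrix numerically singular; blending with A (w=%g)",
            K.flavor, weight,
        )
        out = blend_with_A(K, A, weight)
        if not out.is_singular(tol):
            return out
        K = out
    ridge = tol * float(np.mean(K.diagonal()))
    logger.warning("%s matrix still singular; adding ridge %.3g", K.flavor, ridge)
    vals = K.values + np.eye(len(K)) * max(ridge, abs(K.min_eigenvalue()) * 2 + ridge)
    return RelationshipMatrix(
        K.ids.copy(), vals, flavor=K.flavor, meta={**K.meta, "ridge": ridge}
    )
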