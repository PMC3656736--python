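"""Marker summary statistics, filtering, and missing-genotype imputation.

Marker filtering mirrors the usual SNP-array workflow for a structured
full-sib population: drop monomorphic loci first, then loci with too many
missing calls; the survivors are the "informative" set used to build G.

Four imputation methods are provided for the (typically ~1%) missing calls:

* ``stochastic`` - draw a categorical genotype from the locus's observed
  genotype-class frequencies (preserves genotype frequencies on average);
* ``major_homozygote`` - set missing calls to 0 copies of the minor allele;
* ``gene_content_scaled`` / ``gene_content_truncated`` - treat observed gene
  content at a locus as the response in a one-locus mixed model whose random
  individual effect has covariance proportional to the pedigree relationship
  matrix A, and predict missing individuals from their relatives; the two
  variants differ in how the continuous predictions are mapped back to the
  [0, 2] dosage scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .datatypes import GenotypeMatrix
from .relationships import RelationshipMatrix

logger = logging.getLogger("clonalgp")

IMPUTATION_METHODS = (
    "stochastic",
    "major_homozygote",
    "gene_content_scaled",
    "gene_content_truncated",
)


@dataclass
class MarkerReport:
    """Per-marker statistics plus filter totals."""

    per_marker: pd.DataFrame  # marker_id, maf, missing_frac, monomorphic, n_obs
    n_raw: int
    n_monomorphic: int
    n_high_missing: int
    n_informative: int


def recode_to_minor(geno: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray]:
    """Flip marker coding so dosage counts the minor allele (0 = major
    homozygote).  Columns whose counted-allele sample frequency exceeds 0.5
    are recoded as 2 - dosage; exact ties (p = 0.5) keep the input
    orientation.  Returns the recoded matrix and the boolean flip mask."""
    p = geno.allele_frequencies()
    flip = np.zeros(geno.n_markers, dtype=bool)
    with np.errstate(invalid="ignore"):
        flip[np.nan_to_num(p, nan=0.0) > 0.5] = True
    dosage = geno.dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    return GenotypeMatrix(geno.clone_ids.copy(), geno.marker_ids.copy(), dosage), flip


def summarize_markers(geno: GenotypeMatrix) -> MarkerReport:
    """Compute per-marker MAF, missing fraction and monomorphism flags.

    Statistics use non-missing entries only.  A marker with zero observed
    entries is flagged monomorphic (and fully missing).
    """
    mask = geno.mask
    n = geno.n_clones
    n_obs = n - mask.sum(axis=0)
    missing_frac = mask.sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(geno.dosage, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    mono = np.zeros(geno.n_markers, dtype=bool)
    for j in range(geno.n_markers):
        col = geno.dosage[~mask[:, j], j]
        mono[j] = col.size == 0 or np.all(col == col[0])
    per_marker = pd.DataFrame(
        {
            "marker_id": list(geno.marker_ids),
            "maf": maf,
            "missing_frac": missing_frac,
            "monomorphic": mono,
            "n_obs": n_obs,
        }
    )
    return MarkerReport(
        per_marker=per_marker,
        n_raw=geno.n_markers,
        n_monomorphic=int(mono.sum()),
        n_high_missing=0,  # filled in by filter_markers for a given threshold
        n_informative=geno.n_markers - int(mono.sum()),
    )


def filter_markers(
    geno: GenotypeMatrix, max_missing: float = 0.15
) -> tuple[GenotypeMatrix, MarkerReport]:
    """Drop monomorphic markers, then markers with missing fraction strictly
    above ``max_missing``; the remainder is the informative set."""
    report = summarize_markers(geno)
    pm = report.per_marker
    mono = pm["monomorphic"].to_numpy()
    high = (~mono) & (pm["missing_frac"].to_numpy() > max_missing)
    keep = ~(mono | high)
    if not keep.any():
        raise ValueError("marker filtering removed every marker")
    report.n_monomorphic = int(mono.sum())
    report.n_high_missing = int(high.sum())
    report.n_informative = int(keep.sum())
    logger.info(
        "marker filter: %d raw -> %d monomorphic, %d high-missing, %d informative",
        report.n_raw, report.n_monomorphic, report.n_high_missing, report.n_informative,
    )
    return geno.select_markers(keep), report


def missing_fraction(geno: GenotypeMatrix) -> float:
    """Fraction of missing cells over the whole matrix."""
    return float(geno.mask.mean())


def _check_observed_untouched(original, imputed):  # pragma: no cover - debug aid
    obs = ~original.mask
    assert np.array_equal(original.dosage[obs], imputed.dosage[obs])


def impute_stochastic_frequency(geno: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Draw each missing call from its locus's observed genotype-class
    frequencies.  Reproducible given the seed; on average preserves the
    genotype frequencies observed in the non-missing data."""
    rng = np.random.default_rng(seed)
    out = geno.copy()
    mask = geno.mask
    for j in np.flatnonzero(mask.any(axis=0)):
        col = geno.dosage[~mask[:, j], j]
        if col.size == 0:
            raise ValueError(
                f"marker {geno.marker_ids[j]!r} has no observed genotypes"
            )
        classes, counts = np.unique(col, return_counts=True)
        draws = rng.choice(classes, size=int(mask[:, j].sum()), p=counts / counts.sum())
        out.dosage[mask[:, j], j] = draws
    return out


def impute_major_homozygote(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Set missing calls to 0 (the major homozygote under minor-allele
    coding, i.e. 'missing genotypes converted to zero')."""
    out = geno.copy()
    out.dosage[geno.mask] = 0.0
    return out


def _gene_content_predictions(
    geno: GenotypeMatrix, A: RelationshipMatrix, heritability: float
) -> tuple[np.ndarray, np.ndarray]:
    """Raw mixed-model predictions of gene content at missing cells.

    Per locus, x_obs = mu + u_obs + eps with Var(u) proportional to A and a
    variance ratio fixed by the (near-1) heritability of gene content.
    Returns (predictions matrix with NaN where observed, mask).
    """
    if list(A.ids) != list(geno.clone_ids):
        A = A.submatrix(geno.clone_ids)
    lam = (1.0 - heritability) / heritability
    a = A.values
    mask = geno.mask
    pred = np.full_like(geno.dosage, np.nan)
    ones_cache: dict = {}
    for j in np.flatnonzero(mask.any(axis=0)):
        o = ~mask[:, j]
        m = mask[:, j]
        x = geno.dosage[o, j]
        if x.size == 0:
            raise ValueError(
                f"marker {geno.marker_ids[j]!r} has no observed genotypes"
            )
        key = o.tobytes()
        if key not in ones_cache:
            V = a[np.ix_(o, o)] + lam * np.eye(int(o.sum()))
            try:
                cf = cho_factor(V)
            except np.linalg.LinAlgError:
                logger.warning("singular gene-content system; adding ridge")
                cf = cho_factor(V + 1e-6 * np.eye(V.shape[0]))
            Vinv_one = cho_solve(cf, np.ones(x.size))
            ones_cache[key] = (cf, Vinv_one)
        cf, Vinv_one = ones_cache[key]
        mu = float(Vinv_one @ x) / float(Vinv_one.sum())
        alpha = cho_solve(cf, x - mu)
        pred[m, j] = mu + a[np.ix_(m, o)] @ alpha
    return pred, mask


def impute_gene_content(
    geno: GenotypeMatrix,
    A: RelationshipMatrix,
    variant: str = "truncated",
    heritability: float = 0.99,
) -> GenotypeMatrix:
    """Impute missing calls from relatives via the relationship matrix.

    The covariance between gene contents of two individuals is proportional
    to their additive relationship, so observed gene content at a locus is
    treated as a phenotype in a mixed model with individual effects having
    covariance A; BLUP solutions at missing individuals are continuous
    predictions centered on the locus mean.

    ``variant="truncated"`` clips the raw predictions to [0, 2];
    ``variant="scaled"`` first standardizes them by their mean and SD back to
    the observed locus scale (then clips, to keep dosages in range).
    """
    if variant not in ("scaled", "truncated"):
        raise ValueError(f"unknown gene-content variant: {variant!r}")
    if not 0.0 < heritability < 1.0:
        raise ValueError("gene-content heritability must lie in (0, 1)")
    pred, mask = _gene_content_predictions(geno, A, heritability)
    out = geno.copy()
    for j in np.flatnonzero(mask.any(axis=0)):
        m = mask[:, j]
        p = pred[m, j]
        if variant == "scaled":
            obs = geno.dosage[~m, j]
            sd_pred = p.std()
            if p.size >= 2 and sd_pred > 1e-12 and obs.std() > 0:
                p = 1.0 + (p - p.mean()) / sd_pred * obs.std()
        out.dosage[m, j] = np.clip(p, 0.0, 2.0)
    return out


def impute(
    geno: GenotypeMatrix,
    method: str,
    A: RelationshipMatrix | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Dispatch on imputation method name (see :data:`IMPUTATION_METHODS`)."""
    if method == "stochastic":
        return impute_stochastic_frequency(geno, seed)
    if method == "major_homozygote":
        return impute_major_homozygote(geno)
    if method in ("gene_content_scaled", "gene_content_truncated"):
        if A is None:
            raise ValueError("gene-content imputation requires the A matrix")
        variant = method.rsplit("_", 1)[1]
        return impute_gene_content(geno, A, variant=variant)
    raise ValueError(f"unknown imputation method: {method!r}")


def imputation_accuracy_comparison(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    methods=IMPUTATION_METHODS,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare imputation methods by the mean accuracy of the GEBVs each
    produces (the Table-1-style comparison).

    For each method: impute, build the allele-frequency G, fit the clone
    model by REML with K = G, run GBLUP on all phenotypes, and report the
    mean reliability-based accuracy over clones.
    """
    from .mixed_models import MixedModelSpec, fit_reml, gblup_mme
    from .relationships import build_G_allele_frequency, ensure_invertible

    rows = []
    for method in methods:
        imp = impute(geno, method, A=A, seed=seed)
        G = build_G_allele_frequency(imp)
        G = ensure_invertible(G, A.submatrix(imp.clone_ids))
        spec = MixedModelSpec.from_tables(pheno, G)
        vc = fit_reml(spec)
        bvs = gblup_mme(pheno, G, vc, method="GEBV")
        rows.append(
            {
                "method": method,
                "mean_accuracy": float(bvs.table["accuracy"].mean()),
                "mean_se": float(bvs.table["se"].mean()),
                "sigma2_a": vc.sigma2_a,
                "sigma2_e": vc.sigma2_e,
            }
        )
    return pd.DataFrame(rows)
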