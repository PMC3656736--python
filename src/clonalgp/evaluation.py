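"""Comparison study: EBV1/EBV2/GEBVa/GEBVb and cross-validation.

Four breeding-value flavors are compared:

* **EBV1** - clone model with K = I on *all* phenotypes: no pedigree, pure
  clone-mean information.  With heavy clonal replication this is nearly the
  true breeding value and serves as the reference standard.
* **EBV2** - pedigree BLUP (K = A) with the validation clones' phenotypes
  removed; unphenotyped full sibs all receive the family mid-parent value.
* **GEBVa** - GBLUP with the allele-frequency G, selection-index form.
* **GEBVb** - GBLUP with the regression G, inverted-G (MME) form.

Cross-validation draws training fractions of 90% or 50% of clones, either
within every full-sib family independently or at random, over several
replicates, and reports product-moment correlations of the validation-clone
GEBVs with EBV1 and EBV2 plus mean prediction SEs per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_models import (
    BreedingValueSet,
    MixedModelSpec,
    VarianceComponents,
    fit_reml,
    gblup_mme,
    gblup_selection_index,
    solve_blup,
)
from .relationships import RelationshipMatrix

logger = logging.getLogger("clonalgp")

SCENARIOS = {"train90": 0.9, "train50": 0.5}
STRATIFICATIONS = ("within_family", "random")


@dataclass
class CVScheme:
    scenario: str
    stratification: str
    n_replicates: int
    seed: int
    replicates: list  # list of (training ids tuple, validation ids tuple)


@dataclass
class ValidationReport:
    per_replicate: pd.DataFrame
    scheme: CVScheme
    ebv1: BreedingValueSet

    def means(self) -> pd.Series:
        cols = [c for c in self.per_replicate.columns if c.startswith(("r_", "se_"))]
        return self.per_replicate[cols].mean()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_cv_scheme(
    clone_ids,
    families: dict,
    scenario: str = "train90",
    stratification: str = "within_family",
    n_replicates: int = 6,
    seed: int = 0,
) -> CVScheme:
    """Reproducible training/validation partitions.

    ``families`` maps clone_id -> family label.  ``scenario`` is 'train90',
    'train50', or a training fraction in (0, 1).  Within-family sampling
    rounds the training count half-up per family and guarantees at least one
    clone on each side for families of two or more; the replicate r uses seed
    ``seed + r``.
    """
    clone_ids = [str(c) for c in clone_ids]
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        frac = SCENARIOS[scenario]
        name = scenario
    else:
        frac = float(scenario)
        name = f"train{int(round(frac * 100))}"
    if not 0.0 < frac < 1.0:
        raise ValueError("training fraction must lie strictly in (0, 1)")
    if stratification not in STRATIFICATIONS:
        raise ValueError(f"unknown stratification {stratification!r}")
    reps = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        if stratification == "random":
            n_train = min(max(_round_half_up(frac * len(clone_ids)), 1), len(clone_ids) - 1)
            perm = rng.permutation(clone_ids)
            train, val = perm[:n_train], perm[n_train:]
        else:
            by_family: dict = {}
            for c in clone_ids:
                by_family.setdefault(families[c], []).append(c)
            train, val = [], []
            for fam in sorted(by_family):
                members = by_family[fam]
                if len(members) == 1:
                    train.extend(members)
                    continue
                n_train = min(max(_round_half_up(frac * len(members)), 1), len(members) - 1)
                perm = rng.permutation(members)
                train.extend(perm[:n_train])
                val.extend(perm[n_train:])
        if len(val) == 0:
            raise ValueError("validation set is empty for this scenario")
        reps.append((tuple(sorted(train)), tuple(sorted(val))))
    return CVScheme(
        scenario=name,
        stratification=stratification,
        n_replicates=n_replicates,
        seed=seed,
        replicates=reps,
    )


def compute_ebv1(
    pheno: pd.DataFrame,
    vc: VarianceComponents | None = None,
    clone_ids=None,
) -> BreedingValueSet:
    """Phenotype-only clone BLUP (K = I) on all records; the reference
    standard against which cross-validated predictions are correlated."""
    if clone_ids is None:
        clone_ids = sorted(pheno["clone_id"].unique())
    K = RelationshipMatrix.identity(clone_ids)
    spec = MixedModelSpec.from_tables(pheno, K)
    if vc is None:
        vc = fit_reml(spec)
    bvs = solve_blup(spec, vc, method="EBV1")
    bvs.meta["vc"] = vc
    return bvs


def compute_ebv2(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    validation_ids=(),
    vc: VarianceComponents | None = None,
) -> BreedingValueSet:
    """Pedigree BLUP with validation-clone phenotypes removed.

    Predictions are produced for every clone in A; validation clones (no
    data) get relative-driven predictions - full sibs the mid-parent value.
    """
    validation_ids = set(map(str, validation_ids))
    train = pheno[~pheno["clone_id"].astype(str).isin(validation_ids)]
    spec = MixedModelSpec.from_tables(train, A)
    if vc is None:
        vc = fit_reml(spec)
    bvs = solve_blup(spec, vc, method="EBV2")
    bvs.meta["vc"] = vc
    return bvs


def compute_gebv(
    pheno: pd.DataFrame,
    G: RelationshipMatrix,
    validation_ids=(),
    method: str = "selection_index",
    vc: VarianceComponents | None = None,
    tag: str | None = None,
) -> BreedingValueSet:
    """GBLUP with validation phenotypes removed, by either solver form."""
    if method not in ("selection_index", "mme"):
        raise ValueError(f"unknown GBLUP form {method!r}")
    validation_ids = set(map(str, validation_ids))
    train = pheno[~pheno["clone_id"].astype(str).isin(validation_ids)]
    if vc is None:
        vc = fit_reml(MixedModelSpec.from_tables(train, G))
    if method == "selection_index":
        bvs = gblup_selection_index(train, G, vc, method=tag or "GEBVa")
    else:
        bvs = gblup_mme(train, G, vc, method=tag or "GEBVb")
    bvs.meta["vc"] = vc
    return bvs


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def run_cross_validation(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    G_freq: RelationshipMatrix,
    G_reg: RelationshipMatrix,
    scheme: CVScheme,
    reestimate_vc: bool = True,
    ebv1: BreedingValueSet | None = None,
) -> ValidationReport:
    """The cross-validation study: per replicate, fit on training phenotypes,
    predict validation clones, and correlate GEBVa/GEBVb with EBV1 (full-data
    no-pedigree standard) and EBV2 (pedigree, validation phenotypes removed).

    Variance components are re-estimated on every training set unless
    ``reestimate_vc`` is False, in which case full-data fits are reused.
    Replicates with fewer than three validation clones are skipped.
    """
    if ebv1 is None:
        ebv1 = compute_ebv1(pheno)
    fixed = {}
    if not reestimate_vc:
        fixed = {
            "A": fit_reml(MixedModelSpec.from_tables(pheno, A)),
            "Gf": fit_reml(MixedModelSpec.from_tables(pheno, G_freq)),
            "Gr": fit_reml(MixedModelSpec.from_tables(pheno, G_reg)),
        }
    rows = []
    for r, (train_ids, val_ids) in enumerate(scheme.replicates):
        if len(val_ids) < 3:
            logger.warning("replicate %d has < 3 validation clones; skipped", r)
            continue
        val = list(val_ids)
        ebv2 = compute_ebv2(pheno, A, val, vc=fixed.get("A"))
        gebva = compute_gebv(pheno, G_freq, val, "selection_index",
                             vc=fixed.get("Gf"), tag="GEBVa")
        gebvb = compute_gebv(pheno, G_reg, val, "mme",
                             vc=fixed.get("Gr"), tag="GEBVb")
        e1 = ebv1.values_for(val)
        e2 = ebv2.values_for(val)
        ga = gebva.values_for(val)
        gb = gebvb.values_for(val)
        rows.append(
            {
                "replicate": r,
                "n_validation": len(val),
                "r_GEBVa_EBV1": _corr(ga, e1),
                "r_GEBVb_EBV1": _corr(gb, e1),
                "r_GEBVa_EBV2": _corr(ga, e2),
                "r_GEBVb_EBV2": _corr(gb, e2),
                "se_EBV2": float(np.mean(ebv2.se_for(val))),
                "se_GEBVa": float(np.mean(gebva.se_for(val))),
                "se_GEBVb": float(np.mean(gebvb.se_for(val))),
            }
        )
    return ValidationReport(
        per_replicate=pd.DataFrame(rows), scheme=scheme, ebv1=ebv1
    )


def within_family_correlation(
    predictions: pd.Series, reference: pd.Series, families: dict
) -> float:
    """Pooled within-family product-moment correlation.

    Both series are centered within each family (families with at least two
    members) and the centered values correlated jointly.  This is the metric
    that exposes Mendelian-sampling resolution: a predictor constant within
    families (like pedigree BLUP without phenotypes) scores zero.
    """
    ids = [i for i in predictions.index if i in reference.index]
    df = pd.DataFrame(
        {
            "pred": predictions.loc[ids],
            "ref": reference.loc[ids],
            "fam": [families[i] for i in ids],
        }
    )
    df = df.groupby("fam").filter(lambda g: len(g) >= 2)
    if df.empty:
        return float("nan")
    centered = df.groupby("fam")[["pred", "ref"]].transform(lambda g: g - g.mean())
    # a predictor constant within families leaves only float noise: count as 0
    for col in ("pred", "ref"):
        if centered[col].std() <= 1e-9 * (df[col].abs().mean() + 1e-300):
            return 0.0
    return float(np.corrcoef(centered["pred"], centered["ref"])[0, 1])


def scatter_outputs(
    bv_sets: dict, families: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy paired-prediction table plus the correlation matrix between
    breeding-value sets (plot data for external scatter plots)."""
    if len(bv_sets) < 2:
        raise ValueError("need at least two breeding-value sets")
    common = None
    for bvs in bv_sets.values():
        ids = set(bvs.table.index)
        common = ids if common is None else common & ids
    common = sorted(common)
    pairs = pd.DataFrame(index=common)
    pairs.index.name = "clone_id"
    for name, bvs in bv_sets.items():
        pairs[name] = bvs.table.loc[common, "value"]
    if families is not None:
        pairs["family"] = [families.get(c, "") for c in common]
    value_cols = list(bv_sets)
    corr = pairs[value_cols].corr(method="pearson")
    return pairs.reset_index(), corr
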