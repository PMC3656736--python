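"""Readers and writers for the pipeline's delimited-text tables.

All tables are TSV by default; a ``.csv`` extension switches to commas.
Pedigree files are three columns (individual, sire, dam) with "0" or empty
for an unknown parent.  Genotype files are a labeled matrix (header = marker
ids, first column = clone ids) with cells in {0, 1, 2, NA}; a flag accepts
the transposed (markers-by-clones) orientation, since deposited matrices
come both ways.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    PedigreeTable,
    PHENOTYPE_COLUMNS,
    validate_phenotypes,
)
from .mixed_models import BreedingValueSet
from .qc import IMPUTATION_METHODS
from .relationships import RelationshipMatrix

logger = logging.getLogger("clonalgp")

G_METHODS = ("allele_frequency", "regression")
FREQ_SOURCES = ("sample", "supplied")
ORIENTATIONS = ("clones_by_markers", "markers_by_clones")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column pedigree file; returns a topologically sorted table.

    Raises on duplicate ids or cycles (naming the offending individuals).
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"pedigree file {path} needs 3 columns")
    return PedigreeTable.from_records(df.iloc[:, :3].itertuples(index=False))


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_genotypes(
    path, orientation: str = "clones_by_markers", allow_continuous: bool = False
) -> GenotypeMatrix:
    """Read a labeled dosage matrix; NA/empty cells become missing.

    Raw genotype files must contain only {0, 1, 2, NA}; a cell outside that
    set raises with its row/column labels.  ``allow_continuous=True`` admits
    imputed matrices with values anywhere in [0, 2].
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "markers_by_clones":
        df = df.T
    values = df.to_numpy(dtype=float)
    if not allow_continuous:
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype {values[r, c]!r} at clone {df.index[r]!r}, "
                f"marker {df.columns[c]!r} in {path}"
            )
    return GenotypeMatrix(
        np.asarray(df.index.astype(str), dtype=object),
        np.asarray(df.columns.astype(str), dtype=object),
        values,
    )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Optional VCF ingestion: GT fields of biallelic SNPs become ALT-allele
    dosages (recode with :func:`clonalgp.qc.recode_to_minor` if the ALT is
    not the minor allele).  Non-biallelic or non-SNP records are skipped
    with a logged count; missing genotypes become NaN.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # deferred: VCF support is optional

    vcf = VCF(str(path))
    clones = list(vcf.samples)
    marker_ids, columns, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        col = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else np.nan
             for gt in var.genotypes],
            dtype=float,
        )
        columns.append(col)
    if skipped:
        logger.info("VCF %s: skipped %d non-biallelic/non-SNP records", path, skipped)
    if not columns:
        raise ValueError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(
        np.asarray(clones, dtype=object),
        np.asarray(marker_ids, dtype=object),
        np.column_stack(columns),
    )


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    frame = geno.to_frame()
    if np.all(np.isnan(geno.dosage) | (geno.dosage == np.round(geno.dosage))):
        frame = frame.astype("Int64")
    frame.to_csv(path, sep=_sep(path), na_rep="NA", index_label="clone_id")


def read_phenotypes(path, known_clones=None, keep_unknown: bool = False) -> pd.DataFrame:
    """Read the tree-level phenotype table.

    If ``known_clones`` is given, rows whose clone is unknown are logged and
    (by default) dropped; pass ``keep_unknown=True`` to retain them.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype={c: str for c in PHENOTYPE_COLUMNS[:3]})
    validate_phenotypes(df)
    if known_clones is not None:
        unknown = sorted(set(df["clone_id"]) - set(map(str, known_clones)))
        if unknown:
            logger.warning(
                "%d phenotype rows reference clones outside the pedigree/"
                "genotype set (e.g. %s)%s",
                int(df["clone_id"].isin(unknown).sum()), unknown[:5],
                "" if keep_unknown else "; dropping them",
            )
            if not keep_unknown:
                df = df[~df["clone_id"].isin(unknown)].reset_index(drop=True)
                validate_phenotypes(df)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df).to_csv(path, sep=_sep(path), index=False)


def read_relationship_matrix(path, flavor: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if flavor is None:
        flavor = Path(path).stem
    return RelationshipMatrix(
        np.asarray(df.index.astype(str), dtype=object),
        df.to_numpy(dtype=float),
        flavor=flavor,
    )


def write_relationship_matrix(K: RelationshipMatrix, path) -> None:
    K.to_frame().to_csv(path, sep=_sep(path), index_label="id")


def write_breeding_values(bv_sets, path) -> None:
    """Write one or more BreedingValueSets as a long table
    (clone_id, method, value, se, accuracy)."""
    if isinstance(bv_sets, BreedingValueSet):
        bv_sets = [bv_sets]
    frames = []
    for bvs in bv_sets:
        t = bvs.table.reset_index()
        t.insert(1, "method", bvs.method)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep(path), index=False)


def read_breeding_values(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), dtype={"clone_id": str})


@dataclass
class RunConfig:
    """Validated pipeline configuration (JSON on disk).

    Method names come from closed vocabularies; every randomized stage reads
    its seed from here so runs are reproducible end to end.
    """

    pedigree_path: str = ""
    genotype_path: str = ""
    phenotype_path: str = ""
    genotype_orientation: str = "clones_by_markers"
    imputation_method: str = "gene_content_truncated"
    g_method: str = "allele_frequency"
    freq_source: str = "sample"
    cv_scenario: str = "train90"
    cv_stratification: str = "within_family"
    n_replicates: int = 6
    seed: int = 0
    max_missing: float = 0.15
    blend_weight: float = 0.01
    reml_xatol: float = 1e-10

    def __post_init__(self):
        checks = {
            "imputation_method": IMPUTATION_METHODS,
            "g_method": G_METHODS,
            "freq_source": FREQ_SOURCES,
            "genotype_orientation": ORIENTATIONS,
            "cv_stratification": ("within_family", "random"),
            "cv_scenario": ("train90", "train50"),
        }
        for attr, allowed in checks.items():
            if getattr(self, attr) not in allowed:
                raise ValueError(
                    f"{attr} must be one of {allowed}, got {getattr(self, attr)!r}"
                )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
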