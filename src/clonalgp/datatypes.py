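"""Core data containers shared across the pipeline.

The pipeline moves three kinds of tables around: a pedigree (trio records
defining expected additive relationships), a clones-by-markers dosage matrix
with a missingness mask, and a tree-level phenotype table.  The first two get
thin container classes here; phenotypes stay a plain :class:`pandas.DataFrame`
with the columns listed in :data:`PHENOTYPE_COLUMNS`.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for an unknown parent in pedigree files
UNKNOWN_PARENT = "0"

#: required columns of a phenotype table (one row per ramet/tree)
PHENOTYPE_COLUMNS = ("tree_id", "clone_id", "site_id", "volume")


def _normalize_parent(value) -> str:
    if value is None:
        return UNKNOWN_PARENT
    s = str(value).strip()
    if s in ("", "0", "NA", "nan", "None", "."):
        return UNKNOWN_PARENT
    return s


@dataclass(frozen=True)
class PedigreeTable:
    """Topologically sorted pedigree: parents always precede offspring.

    Use :meth:`from_records` to build one from arbitrary-order trio records;
    it validates uniqueness, detects cycles, and adds implicit founder
    records for parents that appear only on the right-hand side.
    """

    individual: tuple
    sire: tuple
    dam: tuple

    @classmethod
    def from_records(cls, records: Iterable[Sequence]) -> "PedigreeTable":
        trios = [(str(i).strip(), _normalize_parent(s), _normalize_parent(d))
                 for i, s, d in records]
        ids = [t[0] for t in trios]
        seen = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate individual id in pedigree: {i!r}")
            seen.add(i)
        by_id = {t[0]: t for t in trios}
        # implicit founders for parents never listed as individuals
        for _, s, d in list(trios):
            for p in (s, d):
                if p != UNKNOWN_PARENT and p not in by_id:
                    by_id[p] = (p, UNKNOWN_PARENT, UNKNOWN_PARENT)
        graph = {
            i: [p for p in (s, d) if p != UNKNOWN_PARENT]
            for i, s, d in by_id.values()
        }
        try:
            order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1] if len(exc.args) > 1 else []
            raise ValueError(
                f"pedigree contains a cycle involving: {', '.join(map(str, cycle))}"
            ) from None
        sorted_trios = [by_id[i] for i in order]
        return cls(
            individual=tuple(t[0] for t in sorted_trios),
            sire=tuple(t[1] for t in sorted_trios),
            dam=tuple(t[2] for t in sorted_trios),
        )

    def __post_init__(self):
        if not (len(self.individual) == len(self.sire) == len(self.dam)):
            raise ValueError("pedigree columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.individual)

    @property
    def ids(self) -> tuple:
        return self.individual

    def position(self, individual_id: str) -> int:
        return self.individual.index(individual_id)

    def parents(self, individual_id: str) -> tuple:
        i = self.position(individual_id)
        return self.sire[i], self.dam[i]

    def is_founder(self, individual_id: str) -> bool:
        s, d = self.parents(individual_id)
        return s == UNKNOWN_PARENT and d == UNKNOWN_PARENT

    def is_selfed(self, individual_id: str) -> bool:
        s, d = self.parents(individual_id)
        return s != UNKNOWN_PARENT and s == d

    def founders(self) -> list:
        return [i for i in self.individual if self.is_founder(i)]

    def offspring(self) -> list:
        return [i for i in self.individual if not self.is_founder(i)]

    def families(self) -> dict:
        """Map (sire, dam) -> list of offspring ids (full-sib families).

        The parent pair is unordered: (a, b) and (b, a) are the same family.
        """
        fams: dict = {}
        for i, s, d in zip(self.individual, self.sire, self.dam):
            if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT:
                continue
            key = tuple(sorted((s, d)))
            fams.setdefault(key, []).append(i)
        return fams

    def family_of(self) -> dict:
        """Map offspring id -> family label 'sire x dam'."""
        out = {}
        for key, members in self.families().items():
            label = "x".join(key)
            for m in members:
                out[m] = label
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual": self.individual, "sire": self.sire, "dam": self.dam}
        )


@dataclass
class GenotypeMatrix:
    """Clones x markers dosage matrix; NaN encodes a missing genotype.

    Observed (pre-imputation) entries are integers in {0, 1, 2} counting
    copies of the counted (minor) allele; imputed entries may be continuous
    in [0, 2].
    """

    clone_ids: np.ndarray
    marker_ids: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        self.clone_ids = np.asarray(self.clone_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.clone_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.clone_ids)} clones x {len(self.marker_ids)} markers"
            )
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("duplicate clone ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage outside [0, 2] at clone {self.clone_ids[r]!r}, "
                f"marker {self.marker_ids[c]!r}: {self.dosage[r, c]}"
            )

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean missingness mask (True = missing)."""
        return np.isnan(self.dosage)

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.dosage))

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele among observed entries.

        Markers with no observed entries get NaN.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.clone_ids.copy(), self.marker_ids.copy(), self.dosage.copy()
        )

    def select_markers(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.clone_ids.copy(), self.marker_ids[idx], self.dosage[:, idx]
        )

    def select_clones(self, clone_ids: Sequence) -> "GenotypeMatrix":
        pos = {c: i for i, c in enumerate(self.clone_ids)}
        idx = np.array([pos[c] for c in clone_ids])
        return GenotypeMatrix(
            np.asarray(list(clone_ids), dtype=object),
            self.marker_ids.copy(),
            self.dosage[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=list(self.clone_ids), columns=list(self.marker_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            np.asarray(df.index, dtype=object),
            np.asarray(df.columns, dtype=object),
            df.to_numpy(dtype=float),
        )


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and basic sanity of a phenotype table."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    if len(df) == 0:
        raise ValueError("phenotype table is empty")
    if df["volume"].isna().any():
        raise ValueError("phenotype table contains missing volumes")
    return df
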