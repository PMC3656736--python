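"""Synthetic study-design generator: pedigree, gene-dropped genotypes, and
clonally replicated phenotypes.

The defaults emulate a small structured conifer breeding trial: 13 parents
crossed into 9 full-sib families (several sharing a parent), 165 cloned
progeny (3-37 per family), each clone replicated as 16-50 ramets across 16
sites (~6250 trees), and 3461 informative biallelic SNP loci with founder
minor-allele frequencies uniform on [0.05, 0.5].  Genotypes descend from the
founders by fair Mendelian gene dropping at unlinked loci, so realized
relationships disperse around their pedigree expectations exactly as
Mendelian sampling dictates.  A raw-marker mode appends monomorphic and
high-missing loci to exercise the QC filters, and a masking step introduces
missing calls completely at random.

Marker loci are conditioned on being polymorphic among the sampled clones
(columns that come out monomorphic are redrawn), mimicking the ascertainment
of a genotyping array, where only loci observed to segregate are reported.

Phenotypes follow the model the analysis fits: tree record = fixed site
effect + clone breeding value + independent residual, with the breeding
value the sum of centered marker dosages times normal marker effects scaled
so its variance among unrelated individuals equals ``sigma2_a``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PedigreeTable, UNKNOWN_PARENT

logger = logging.getLogger("clonalgp")


@dataclass
class SimulationConfig:
    n_parents: int = 13
    n_families: int = 9
    n_progeny: int = 165
    progeny_per_family: tuple = (3, 37)
    n_markers: int = 3461
    maf_range: tuple = (0.05, 0.5)
    n_sites: int = 16
    ramets_per_clone: tuple = (16, 50)
    h2: float = 0.25              # individual-tree heritability
    sigma2_a: float = 1.0
    site_effect_sd: float = 1.0
    missing_rate: float = 0.012
    n_monomorphic: int = 0        # raw-marker mode: planted monomorphic loci
    n_high_missing: int = 0       # raw-marker mode: planted high-missing loci
    high_missing_range: tuple = (0.18, 0.5)
    share_parents: bool = True

    def __post_init__(self):
        for name in ("n_parents", "n_families", "n_progeny", "n_markers", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        lo, hi = self.progeny_per_family
        if not lo * self.n_families <= self.n_progeny <= hi * self.n_families:
            raise ValueError(
                f"{self.n_progeny} progeny infeasible for {self.n_families} "
                f"families of {lo}-{hi}"
            )
        if self.n_monomorphic < 0 or self.n_high_missing < 0:
            raise ValueError("planted locus counts must be non-negative")
        if self.high_missing_range[0] <= 0.15:
            raise ValueError("planted high-missing fraction must exceed 0.15")

    @property
    def sigma2_e(self) -> float:
        """Residual variance implied by the tree-level heritability target."""
        return self.sigma2_a * (1.0 / self.h2 - 1.0)


@dataclass
class TruthSet:
    """Ground truth retained for parameter-recovery and accuracy tests."""

    breeding_values: pd.Series      # clone_id -> true BV
    marker_effects: np.ndarray
    sigma2_a: float
    sigma2_e: float
    site_effects: pd.Series         # site_id -> fixed effect

    def to_frame(self) -> pd.DataFrame:
        return self.breeding_values.rename("true_bv").rename_axis("clone_id").reset_index()


@dataclass
class SimulatedDataset:
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix            # clones x markers, possibly masked/raw
    genotypes_complete: GenotypeMatrix   # clean informative loci, no missing
    phenotypes: pd.DataFrame
    truth: TruthSet
    founder_freqs: np.ndarray            # counted-allele freq of informative loci


def _make_crosses(n_parents: int, n_families: int, share_parents: bool) -> list:
    """Deterministic parent pairs: disjoint pairs first, then chained pairs
    that reuse parents (so at least two crosses share a parent)."""
    pairs = [(2 * i, 2 * i + 1) for i in range(n_parents // 2)]
    if n_families <= len(pairs):
        if not share_parents:
            return pairs[:n_families]
        pairs = pairs[: n_families - 1]
    elif not share_parents:
        raise ValueError(
            f"{n_families} disjoint crosses impossible with {n_parents} parents"
        )
    extra = [((2 * i + 1) % n_parents, (2 * i + 2) % n_parents) for i in range(n_parents)]
    for pair in extra:
        if len(pairs) >= n_families:
            break
        if pair not in pairs and pair[0] != pair[1]:
            pairs.append(pair)
    if len(pairs) < n_families:
        raise ValueError("cannot construct the requested number of crosses")
    return pairs


def simulate_pedigree(cfg: SimulationConfig, seed: int) -> PedigreeTable:
    """Crosses among the parents plus cloned progeny, per-family counts drawn
    to sum to the target while staying within the per-family range."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.progeny_per_family
    crosses = _make_crosses(cfg.n_parents, cfg.n_families, cfg.share_parents)
    counts = np.full(cfg.n_families, lo)
    for _ in range(cfg.n_progeny - lo * cfg.n_families):
        open_fams = np.flatnonzero(counts < hi)
        counts[rng.choice(open_fams)] += 1
    pad = len(str(cfg.n_parents))
    parents = [f"P{i + 1:0{pad}d}" for i in range(cfg.n_parents)]
    records = [(p, UNKNOWN_PARENT, UNKNOWN_PARENT) for p in parents]
    pad_c = len(str(cfg.n_progeny))
    k = 0
    for (si, di), c in zip(crosses, counts):
        for _ in range(c):
            k += 1
            records.append((f"C{k:0{pad_c}d}", parents[si], parents[di]))
    return PedigreeTable.from_records(records)


def _drop_columns(ped: PedigreeTable, freqs: np.ndarray, rng) -> np.ndarray:
    """Gene-drop dosages for all pedigree individuals at independent loci.

    Founders draw genotype ~ Binomial(2, p); each offspring receives one
    allele per parent per locus, transmitted with probability dosage/2."""
    n_loci = len(freqs)
    pos = {ind: i for i, ind in enumerate(ped.individual)}
    dos = np.zeros((len(ped), n_loci))
    for i, (ind, s, d) in enumerate(zip(ped.individual, ped.sire, ped.dam)):
        if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT:
            dos[i] = rng.binomial(2, freqs)
        else:
            gs = dos[pos[s]]
            gd = dos[pos[d]]
            dos[i] = rng.binomial(1, gs / 2.0) + rng.binomial(1, gd / 2.0)
    return dos


def simulate_genotypes(
    ped: PedigreeTable, cfg: SimulationConfig, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Gene-dropped clone genotypes at ``cfg.n_markers`` informative loci.

    Returns the clone genotype matrix and the founder (base-population)
    allele frequencies of the counted allele.  Columns monomorphic among the
    clones are redrawn (array ascertainment), so every returned locus
    segregates in the sample.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    dos = _drop_columns(ped, freqs, rng)
    clone_rows = [i for i, ind in enumerate(ped.individual) if not ped.is_founder(ind)]
    clone_ids = [ped.individual[i] for i in clone_rows]
    for _ in range(1000):
        sub = dos[clone_rows]
        mono = np.flatnonzero(np.all(sub == sub[0], axis=0))
        if mono.size == 0:
            break
        dos[:, mono] = _drop_columns(ped, freqs[mono], rng)
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw polymorphic loci")
    pad = len(str(cfg.n_markers))
    marker_ids = [f"SNP{j + 1:0{pad}d}" for j in range(cfg.n_markers)]
    geno = GenotypeMatrix(
        np.asarray(clone_ids, dtype=object),
        np.asarray(marker_ids, dtype=object),
        dos[clone_rows],
    )
    return geno, freqs


def simulate_phenotypes(
    ped: PedigreeTable,
    geno: GenotypeMatrix,
    founder_freqs: np.ndarray,
    cfg: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, TruthSet]:
    """Clonally replicated tree records under y = site + BV + e.

    True breeding value of clone j is sum_i (dosage_ij - 2 p_i) a_i with
    marker effects a_i ~ N(0, sigma2_a / (2 sum p_i (1 - p_i))), so the BV
    variance among unrelated individuals matches ``cfg.sigma2_a``.  Residual
    variance follows the tree-level heritability target.  Each clone gets a
    ramet count drawn from ``ramets_per_clone`` and its ramets are spread
    over sites as evenly as the count allows (uniform allocation).
    """
    if not geno.is_complete:
        raise ValueError("phenotype simulation needs complete genotypes")
    rng = np.random.default_rng(seed)
    p = np.asarray(founder_freqs, dtype=float)
    sigma2_m = cfg.sigma2_a / (2.0 * float(np.sum(p * (1.0 - p))))
    effects = rng.normal(0.0, np.sqrt(sigma2_m), size=geno.n_markers)
    tbv = (geno.dosage - 2.0 * p) @ effects
    sites = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    site_eff = rng.normal(0.0, cfg.site_effect_sd, size=cfg.n_sites)
    sigma2_e = cfg.sigma2_e
    lo, hi = cfg.ramets_per_clone
    rows = []
    tree = 0
    for ci, clone in enumerate(geno.clone_ids):
        n_ramets = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(cfg.n_sites))
        for r in range(n_ramets):
            s = (start + r) % cfg.n_sites
            tree += 1
            rows.append((f"T{tree:06d}", clone, sites[s], ci, s))
    df = pd.DataFrame(rows, columns=["tree_id", "clone_id", "site_id", "_ci", "_si"])
    noise = rng.normal(0.0, np.sqrt(sigma2_e), size=len(df))
    df["volume"] = site_eff[df["_si"]] + tbv[df["_ci"]] + noise
    df = df.drop(columns=["_ci", "_si"])
    truth = TruthSet(
        breeding_values=pd.Series(tbv, index=list(geno.clone_ids)),
        marker_effects=effects,
        sigma2_a=cfg.sigma2_a,
        sigma2_e=sigma2_e,
        site_effects=pd.Series(site_eff, index=sites),
    )
    return df, truth


def mask_genotypes(geno: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set cells missing independently with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("masking rate must lie in [0, 1)")
    if rate == 0.0:
        return geno.copy()
    rng = np.random.default_rng(seed)
    out = geno.copy()
    hit = rng.random(out.dosage.shape) < rate
    out.dosage[hit] = np.nan
    return out


def _append_raw_markers(
    geno: GenotypeMatrix, cfg: SimulationConfig, rng
) -> GenotypeMatrix:
    """Raw-marker mode: append planted monomorphic and high-missing loci and
    shuffle column order, reproducing the raw-array filter pathway."""
    n = geno.n_clones
    cols = [geno.dosage]
    ids = list(geno.marker_ids)
    if cfg.n_monomorphic:
        mono = np.zeros((n, cfg.n_monomorphic))
        cols.append(mono)
        ids += [f"MONO{j + 1:04d}" for j in range(cfg.n_monomorphic)]
    if cfg.n_high_missing:
        p = rng.uniform(*cfg.maf_range, size=cfg.n_high_missing)
        block = rng.binomial(2, p, size=(n, cfg.n_high_missing)).astype(float)
        # force each column polymorphic (also among the surviving observed
        # entries), then mask strictly more than 15% of its cells
        for j in range(cfg.n_high_missing):
            frac = rng.uniform(*cfg.high_missing_range)
            n_miss = min(max(int(np.floor(0.15 * n)) + 1, int(round(frac * n))), n - 2)
            while True:
                col = rng.binomial(2, p[j], size=n).astype(float)
                col[rng.choice(n, size=n_miss, replace=False)] = np.nan
                obs = col[~np.isnan(col)]
                if obs.size >= 2 and not np.all(obs == obs[0]):
                    block[:, j] = col
                    break
        cols.append(block)
        ids += [f"HIMISS{j + 1:04d}" for j in range(cfg.n_high_missing)]
    dosage = np.hstack(cols)
    order = rng.permutation(dosage.shape[1])
    return GenotypeMatrix(
        geno.clone_ids.copy(),
        np.asarray(ids, dtype=object)[order],
        dosage[:, order],
    )


def _repair_masking(
    raw: GenotypeMatrix, masked: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Redraw the random mask of any informative locus that the masking left
    monomorphic-among-observed or above the 15% missing threshold.

    Like the polymorphism conditioning in :func:`simulate_genotypes`, this is
    array ascertainment: reported informative loci are those that segregate
    among called genotypes.  Planted monomorphic/high-missing loci (raw-marker
    mode) keep their intended status.
    """
    if rate == 0.0:
        return masked
    rng = np.random.default_rng(seed)
    n = masked.n_clones
    out = masked.copy()
    for _ in range(100):
        bad = []
        for j, mid in enumerate(out.marker_ids):
            col = out.dosage[:, j]
            obs = col[~np.isnan(col)]
            if str(mid).startswith("MONO"):
                continue
            if obs.size == 0 or np.all(obs == obs[0]):
                bad.append(j)
            elif str(mid).startswith("SNP") and np.isnan(col).mean() > 0.15:
                bad.append(j)
        if not bad:
            return out
        for j in bad:
            col = raw.dosage[:, j].copy()
            observed = ~np.isnan(col)
            col[observed & (rng.random(n) < rate)] = np.nan
            out.dosage[:, j] = col
    raise RuntimeError("could not draw an admissible missingness pattern")


def simulate_dataset(cfg: SimulationConfig, seed: int) -> SimulatedDataset:
    """Full study draw: pedigree, genotypes, phenotypes, masking, raw mode.

    Sub-seeds are derived from ``seed`` so each stage is independently
    reproducible; the returned dataset keeps the complete informative
    genotypes alongside the masked (and optionally raw-mode) matrix.
    """
    ped = simulate_pedigree(cfg, seed)
    geno, freqs = simulate_genotypes(ped, cfg, seed + 1)
    pheno, truth = simulate_phenotypes(ped, geno, freqs, cfg, seed + 2)
    rng = np.random.default_rng(seed + 3)
    raw = geno
    if cfg.n_monomorphic or cfg.n_high_missing:
        raw = _append_raw_markers(geno, cfg, rng)
    masked = mask_genotypes(raw, cfg.missing_rate, seed + 4)
    masked = _repair_masking(raw, masked, cfg.missing_rate, seed + 5)
    logger.info(
        "simulated %d clones, %d trees, %d markers (seed %d)",
        geno.n_clones, len(pheno), masked.n_markers, seed,
    )
    return SimulatedDataset(
        pedigree=ped,
        genotypes=masked,
        genotypes_complete=geno,
        phenotypes=pheno,
        truth=truth,
        founder_freqs=freqs,
    )
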