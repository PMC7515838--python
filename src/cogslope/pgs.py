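"""Polygenic scoring from GWAS summary statistics: clumping + thresholding.

The engine harmonizes summary statistics to the target genotypes, prunes
linkage disequilibrium by greedy p-value-ordered clumping (default r^2 >
0.25 within +/-250 kb), applies a p-value inclusion threshold, and scores
each person as the dosage-weighted sum of effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .simulate import COMPLEMENT, GenotypeMatrix, SummaryStats

log = logging.getLogger(__name__)

AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonize(sumstats: SummaryStats, genotypes: GenotypeMatrix) -> SummaryStats:
    """Align summary statistics to the genotype allele coding and column order.

    SNPs absent from the genotypes are dropped; where effect/other alleles
    are swapped relative to the genotype coding the beta sign is flipped;
    strand flips are resolved via allele complements; strand-ambiguous
    (A/T, C/G) SNPs are dropped, as are irreconcilable allele pairs (with a
    logged reason — never an error).
    """
    geno = genotypes.snps.set_index("snp")
    rows = []
    dropped: dict[str, int] = {"absent": 0, "ambiguous": 0, "irreconcilable": 0}
    ss = sumstats.table.set_index("snp")
    for snp in geno.index:
        if snp not in ss.index:
            continue
        g = geno.loc[snp]
        s = ss.loc[snp]
        pair = (s["a1"], s["a2"])
        if pair in AMBIGUOUS:
            dropped["ambiguous"] += 1
            continue
        flip = None
        if (s["a1"], s["a2"]) == (g["a1"], g["a2"]):
            flip = 1.0
        elif (s["a1"], s["a2"]) == (g["a2"], g["a1"]):
            flip = -1.0
        else:
            comp = (COMPLEMENT[s["a1"]], COMPLEMENT[s["a2"]])
            if comp == (g["a1"], g["a2"]):
                flip = 1.0
            elif comp == (g["a2"], g["a1"]):
                flip = -1.0
        if flip is None:
            dropped["irreconcilable"] += 1
            continue
        rows.append(
            {
                "snp": snp,
                "chrom": g["chrom"],
                "pos": g["pos"],
                "a1": g["a1"],
                "a2": g["a2"],
                "beta": flip * s["beta"],
                "se": s["se"],
                "p": s["p"],
            }
        )
    n_absent = len(ss.index.difference(geno.index))
    if any(dropped.values()) or n_absent:
        log.info(
            "harmonize: kept %d SNPs; dropped %d ambiguous, %d irreconcilable, %d absent",
            len(rows),
            dropped["ambiguous"],
            dropped["irreconcilable"],
            n_absent,
        )
    cols = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p"]
    return SummaryStats(pd.DataFrame(rows, columns=cols))


@dataclass
class ClumpResult:
    """Retained index SNPs plus the removal map from greedy clumping."""

    index_snps: list[str]
    removed_by: dict[str, str] = field(default_factory=dict)
    r2_max: float = 0.25
    window_kb: float = 250.0


def ld_clump(
    sumstats: SummaryStats,
    genotypes: GenotypeMatrix,
    r2_max: float = 0.25,
    window_kb: float = 250.0,
) -> ClumpResult:
    """Greedy p-value-ordered LD clumping in the target sample.

    SNPs are visited in ascending p (ties broken by chromosome, position,
    then id, so the result is invariant to input order); each unremoved
    visited SNP becomes an index and removes all other unvisited SNPs on
    the same chromosome within +/- ``window_kb`` whose squared dosage
    correlation with it exceeds ``r2_max``.
    """
    if not 0 < r2_max <= 1:
        raise ParameterError("r2_max must lie in (0, 1]")
    if window_kb <= 0:
        raise ParameterError("window_kb must be positive")
    tab = sumstats.table
    if tab.empty:
        return ClumpResult([], {}, r2_max, window_kb)

    geno_index = pd.Index(genotypes.snps["snp"])
    col_of = {s: i for i, s in enumerate(geno_index)}
    unknown = [s for s in tab["snp"] if s not in col_of]
    if unknown:
        raise ConsistencyError(f"summary stats reference SNPs absent from genotypes: {unknown[:3]}")

    order = tab.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    window = window_kb * 1000.0
    removed: dict[str, str] = {}
    index_snps: list[str] = []
    dos = genotypes.dosage
    by_chrom = {c: g for c, g in order.groupby("chrom")}
    visited: set[str] = set()
    for _, row in order.iterrows():
        snp = row["snp"]
        if snp in removed or snp in visited:
            continue
        visited.add(snp)
        index_snps.append(snp)
        near = by_chrom[row["chrom"]]
        cand = near[
            (np.abs(near["pos"] - row["pos"]) <= window)
            & (near["snp"] != snp)
            & ~near["snp"].isin(removed)
            & ~near["snp"].isin(visited)
        ]
        if cand.empty:
            continue
        xi = dos[:, col_of[snp]]
        for other in cand["snp"]:
            xj = dos[:, col_of[other]]
            sx, sy = xi.std(), xj.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if r * r > r2_max:
                removed[other] = snp
    return ClumpResult(index_snps, removed, r2_max, window_kb)


@dataclass
class PGSVector:
    """Per-person polygenic score with its construction provenance."""

    scores: pd.Series
    name: str = "pgs"
    p_threshold: float = 1.0
    r2_max: float = 0.25
    window_kb: float = 250.0
    n_snps_used: int = 0

    def standardized(self) -> pd.Series:
        sd = self.scores.std()
        return (self.scores - self.scores.mean()) / (sd if sd > 0 else 1.0)

    @property
    def provenance(self) -> dict:
        return {
            "name": self.name,
            "p_threshold": self.p_threshold,
            "clump_r2_max": self.r2_max,
            "clump_window_kb": self.window_kb,
            "n_snps_used": self.n_snps_used,
        }


def score(
    genotypes: GenotypeMatrix,
    sumstats: SummaryStats,
    clump: ClumpResult,
    p_threshold: float = 1.0,
    name: str = "pgs",
    person_ids=None,
) -> PGSVector:
    """Dosage-weighted sum of effect sizes over retained, threshold-passing SNPs.

    Missing dosages (NaN) are mean-imputed per SNP before scoring and
    logged.  Raw scores are returned; standardize via
    :meth:`PGSVector.standardized` before association analyses.
    """
    if not 0 < p_threshold <= 1:
        raise ParameterError("p_threshold must lie in (0, 1]")
    tab = sumstats.table.set_index("snp")
    col_of = {s: i for i, s in enumerate(genotypes.snps["snp"])}
    missing = [s for s in clump.index_snps if s not in col_of or s not in tab.index]
    if missing:
        raise ConsistencyError(f"clump references unknown SNPs: {missing[:3]}")
    use = [s for s in clump.index_snps if tab.loc[s, "p"] <= p_threshold]
    cols = np.array([col_of[s] for s in use], dtype=int)
    betas = tab.loc[use, "beta"].to_numpy() if use else np.zeros(0)
    dos = genotypes.dosage[:, cols] if len(cols) else np.zeros((genotypes.n, 0))
    if np.isnan(dos).any():
        n_missing = int(np.isnan(dos).sum())
        log.info("score: mean-imputing %d missing dosage entries", n_missing)
        means = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), means, dos)
    values = dos @ betas if len(cols) else np.zeros(genotypes.n)
    idx = person_ids if person_ids is not None else pd.RangeIndex(genotypes.n)
    return PGSVector(
        scores=pd.Series(values, index=idx, name=name),
        name=name,
        p_threshold=p_threshold,
        r2_max=clump.r2_max,
        window_kb=clump.window_kb,
        n_snps_used=len(use),
    )


def build_pgs(
    genotypes: GenotypeMatrix,
    sumstats: SummaryStats,
    p_threshold: float = 1.0,
    r2_max: float = 0.25,
    window_kb: float = 250.0,
    name: str = "pgs",
    person_ids=None,
) -> PGSVector:
    """Harmonize, clump and score in one call."""
    harm = harmonize(sumstats, genotypes)
    clump = ld_clump(harm, genotypes, r2_max=r2_max, window_kb=window_kb)
    return score(genotypes, harm, clump, p_threshold, name=name, person_ids=person_ids)
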