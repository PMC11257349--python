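"""Genotype QC and candidate sex-autosome-fusion SNP identification.

QC applies, in order: a site-quality floor, a per-genotype depth floor
(failing genotypes become missing), a site missingness cap, a cap on the
across-sample mean depth relative to the genome-wide mean of site-mean depths
(masking collapsed paralogs), and removal of sites with a significant excess
of heterozygotes under a one-sided Hardy-Weinberg exact test (also a paralog
signature).

Candidate fusion sites are SNPs where, in *every* species of the focal clade:
(i) no male is heterozygous, (ii) at least one female is heterozygous and
(iii) at most one female is homozygous, where one additional female with a
half-called genotype (one allele not called) is tolerated.  On a chromosome
carrying a W-autosome fusion these criteria are met by every site private to
the non-recombining female haplotype, because each female carries exactly one
copy of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .io_formats import GenotypeTable, HALF_CALL, HET, HOM_ALT, HOM_REF, MISSING, SampleSheet


@dataclass
class QcThresholds:
    """Thresholds for site/genotype QC (defaults follow common practice for
    joint-genotyped short-read data)."""

    min_site_quality: float = 30.0
    max_site_missingness: float = 0.05
    min_genotype_depth: int = 5
    max_mean_depth_factor: float = 1.5
    excess_het_p: float = 1e-5

    def __post_init__(self) -> None:
        if self.min_site_quality < 0 or self.min_genotype_depth < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not (0.0 <= self.max_site_missingness <= 1.0):
            raise ValueError("max_site_missingness must be in [0, 1]")
        if self.max_mean_depth_factor < 0 or self.excess_het_p < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class QcResult:
    table: GenotypeTable
    removal_counts: dict[str, int]
    n_genotypes_masked: int


@lru_cache(maxsize=100_000)
def _het_excess_tail(n_diploid: int, n_rare: int, n_het: int) -> float:
    """P(het count >= n_het) under the Hardy-Weinberg exact distribution.

    Levene/Haldane conditional distribution of the heterozygote count given
    ``n_diploid`` individuals and ``n_rare`` copies of the rarer allele.
    Only heterozygote counts with the parity of ``n_rare`` are possible.
    """
    if n_diploid == 0 or n_rare == 0:
        return 1.0
    two_n = 2 * n_diploid
    n_common = two_n - n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_rare_hom = (n_rare - hets) // 2
    n_common_hom = n_diploid - hets - n_rare_hom
    logp = (
        hets * math.log(2)
        + gammaln(n_diploid + 1)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(two_n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(p[hets >= n_het].sum())


def hwe_excess_het_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided (heterozygote excess) Hardy-Weinberg exact p-value."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    return _het_excess_tail(n, n_rare, n_het)


def qc_filter(table: GenotypeTable, thresholds: QcThresholds | None = None) -> QcResult:
    """Apply site/genotype QC, returning the filtered table and per-rule counts."""
    if table.n_sites == 0:
        raise ValueError("qc_filter: empty genotype table")
    thr = thresholds or QcThresholds()
    counts: dict[str, int] = {}

    keep = table.qual >= thr.min_site_quality
    counts["site_quality"] = int((~keep).sum())
    table = table.subset_sites(keep)

    # genotypes below the depth floor become missing (depth -1 = no DP data,
    # which does not trigger masking)
    low = (table.depth >= 0) & (table.depth < thr.min_genotype_depth) & (table.gt != MISSING)
    n_masked = int(low.sum())
    if n_masked:
        gt = table.gt.copy()
        gt[low] = MISSING
        table.gt = gt
        if table.haplotypes is not None:
            haps = table.haplotypes.copy()
            haps[low] = MISSING
            table.haplotypes = haps

    miss_frac = (table.gt == MISSING).mean(axis=1)
    keep = miss_frac < thr.max_site_missingness
    counts["missingness"] = int((~keep).sum())
    table = table.subset_sites(keep)

    if np.isfinite(thr.max_mean_depth_factor) and table.n_sites:
        if (table.depth >= 0).all():
            site_mean = table.depth.mean(axis=1)
        else:
            has_dp = table.depth >= 0
            with np.errstate(invalid="ignore"):
                site_mean = np.where(
                    has_dp.any(axis=1),
                    np.where(has_dp, table.depth, 0).sum(axis=1) / np.maximum(has_dp.sum(axis=1), 1),
                    np.nan,
                )
        global_mean = np.nanmean(site_mean) if np.isfinite(site_mean).any() else np.nan
        keep = ~(site_mean > thr.max_mean_depth_factor * global_mean)
        counts["mean_depth_cap"] = int((~keep).sum())
        table = table.subset_sites(keep)
    else:
        counts["mean_depth_cap"] = 0

    if thr.excess_het_p > 0 and table.n_sites:
        n_rr = (table.gt == HOM_REF).sum(axis=1).astype(np.int64)
        n_ra = (table.gt == HET).sum(axis=1).astype(np.int64)
        n_aa = (table.gt == HOM_ALT).sum(axis=1).astype(np.int64)
        n = n_rr + n_ra + n_aa
        # cheap screen: the exact one-sided p can only be small when the het
        # count clearly exceeds its Hardy-Weinberg expectation, so the exact
        # tail is evaluated only where the normal deviate is > 2 (a site with
        # z <= 2 has p orders of magnitude above any sensible cutoff)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = (2 * n_aa + n_ra) / np.maximum(2 * n, 1)
            q = 2.0 * p_hat * (1.0 - p_hat)
            e_het = q * n
            sd = np.sqrt(np.maximum(n * q * (1.0 - q), 1e-12))
            z = (n_ra - e_het) / sd
        suspicious = np.flatnonzero((z > 2.0) & (n > 0))
        remove = np.zeros(table.n_sites, dtype=bool)
        for i in suspicious:
            if hwe_excess_het_p(int(n_rr[i]), int(n_ra[i]), int(n_aa[i])) < thr.excess_het_p:
                remove[i] = True
        keep = ~remove
        counts["excess_heterozygosity"] = int((~keep).sum())
        table = table.subset_sites(keep)
    else:
        counts["excess_heterozygosity"] = 0

    return QcResult(table=table, removal_counts=counts, n_genotypes_masked=n_masked)


# ---------------------------------------------------------------------------
# candidate fusion sites
# ---------------------------------------------------------------------------


@dataclass
class CandidateSiteReport:
    """Sites passing the per-species fusion criteria for one clade."""

    clade: tuple[str, ...]
    site_index: np.ndarray  # indices into the source table, sorted (chrom, pos)
    species_pass: dict[str, np.ndarray]  # species -> bool per table site
    chrom: np.ndarray  # chromosome of each passing site
    pos: np.ndarray  # 1-based position of each passing site
    counts_per_chrom: dict[str, int]
    subsample_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n_passing(self) -> int:
        return int(self.site_index.size)


def candidate_fusion_sites(
    table: GenotypeTable, sheet: SampleSheet, clade_species: list[str] | tuple[str, ...]
) -> CandidateSiteReport:
    """Identify SNPs matching the female-limited-haplotype pattern per clade.

    A site passes for the clade only if it passes the three criteria in every
    clade species (heterogametic females carrying the shared fused haplotype
    are heterozygous in all of them).
    """
    clade_species = tuple(clade_species)
    males = sheet.select(sex="male", species=clade_species)
    females = sheet.select(sex="female", species=clade_species)
    if len(males) < 1 or len(females) < 2:
        raise ValueError("clade must contain at least 1 male and 2 females")

    species_pass: dict[str, np.ndarray] = {}
    overall = np.ones(table.n_sites, dtype=bool)
    for sp in clade_species:
        f = sheet.select(sex="female", species=sp)
        if not f:
            raise ValueError(f"species {sp!r} has no females; fusion unobservable")
        m = sheet.select(sex="male", species=sp)
        gt_m = table.gt[:, table.sample_indices(m)] if m else np.empty((table.n_sites, 0), np.int8)
        gt_f = table.gt[:, table.sample_indices(f)]
        male_het = (gt_m == HET).sum(axis=1)
        fem_het = (gt_f == HET).sum(axis=1)
        fem_hom = ((gt_f == HOM_REF) | (gt_f == HOM_ALT)).sum(axis=1)
        fem_half = (gt_f == HALF_CALL).sum(axis=1)
        ok = (male_het == 0) & (fem_het >= 1) & (fem_hom <= 1) & (fem_half <= 1)
        species_pass[sp] = ok
        overall &= ok

    idx = np.flatnonzero(overall)
    # sort passing sites by (chromosome, position); chromosome order as in table
    chrom_rank = {c: i for i, c in enumerate(table.chromosomes)}
    order = np.lexsort((table.pos[idx], np.array([chrom_rank[c] for c in table.chrom[idx]])))
    idx = idx[order]
    chroms = table.chrom[idx]
    counts = {c: int((chroms == c).sum()) for c in table.chromosomes}
    return CandidateSiteReport(
        clade=clade_species,
        site_index=idx,
        species_pass=species_pass,
        chrom=chroms,
        pos=table.pos[idx],
        counts_per_chrom=counts,
    )


def subsample_every_kth(report: CandidateSiteReport, k: int) -> CandidateSiteReport:
    """Keep every k-th passing site (1-based ranks k, 2k, ...).

    Returns the report with ``subsample_index`` filled; fewer than ``k``
    passing sites yield an empty subsample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = report.site_index[k - 1 :: k]
    report.subsample_index = sub
    return report
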