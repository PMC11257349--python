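"""End-to-end fusion scan: QC -> windowed statistics -> genealogy -> calls.

This is the orchestration layer the CLI and the acceptance checks drive.  It
wires the modules together for the standard analysis: per-sex windowed
heterozygosity and depth for the focal clade, female/male between-group FST,
candidate-site identification with the genealogy clade test, optional Hi-C
enrichment, and the per-chromosome classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierThresholds, FusionCall, FusionEvidence, classify, evaluate_chromosome
from .genealogy import FULL, scan_candidate_sites
from .hic import ContactMatrix, enrichment_frame, interchrom_enrichment
from .io_formats import GenotypeTable, SampleSheet, make_windows
from .site_filter import QcThresholds, candidate_fusion_sites, qc_filter, subsample_every_kth
from .window_stats import (
    DEFAULT_MIN_SITES,
    depth_windows,
    fst_windows,
    het_proportion_windows,
)


@dataclass
class ScanResult:
    calls: list[FusionCall]
    evidence: list[FusionEvidence]
    het_group_means: pd.DataFrame  # window x {female, male}, plus window columns
    fst_female: pd.DataFrame | None
    fst_male: pd.DataFrame | None
    depth_group_means: pd.DataFrame
    clade_fractions: dict[str, float]
    candidate_counts: dict[str, int]
    qc_removals: dict[str, int]
    hic_female: pd.DataFrame | None = None
    hic_male: pd.DataFrame | None = None


def _fused_chroms_from_hic(enr: pd.DataFrame) -> set[str]:
    fused = enr[enr["fused"]]
    return set(fused["chrom_a"]) | set(fused["chrom_b"])


def scan_for_fusions(
    table: GenotypeTable,
    sheet: SampleSheet,
    clade: Sequence[str],
    chrom_lengths: Mapping[str, int],
    autosomes: Sequence[str] | None = None,
    species_pair: tuple[str, str] | None = None,
    window_bp: int = 50_000,
    min_sites_fst: int = DEFAULT_MIN_SITES,
    qc: QcThresholds | None = None,
    thresholds: ClassifierThresholds | None = None,
    hic_female: ContactMatrix | None = None,
    hic_male: ContactMatrix | None = None,
    subsample_k: int = 1000,
    max_genealogy_sites: int = 100,
    genealogy_mode: str = "allele",
) -> ScanResult:
    """Run the full resequencing (+ optional Hi-C) fusion scan for one clade.

    ``autosomes`` restricts the evaluated chromosomes (defaults to every
    chromosome in ``chrom_lengths`` not named like a Z or W scaffold);
    ``species_pair`` names the two clade groups for FST (defaults to the
    first two clade species; with fewer than two species the FST signature
    is skipped and the classifier requires the genealogy flag instead).
    """
    clade = tuple(clade)
    thr = thresholds or ClassifierThresholds()
    if autosomes is None:
        autosomes = [
            c for c in chrom_lengths if not (c in ("chrZ", "Z") or c.startswith("W"))
        ]
    qc_res = qc_filter(table, qc)
    ftable = qc_res.table

    windows = make_windows({c: chrom_lengths[c] for c in autosomes}, window_bp)
    females = sheet.select(sex="female", species=clade)
    males = sheet.select(sex="male", species=clade)
    clade_samples = females + males
    het = het_proportion_windows(
        ftable, windows, clade_samples, groups={"female": females, "male": males}
    )
    depth = depth_windows(ftable, windows, {"female": females, "male": males})

    if species_pair is None:
        clade_sp = [sp for sp in sheet.species_list if sp in clade]
        species_pair = tuple(clade_sp[:2]) if len(clade_sp) >= 2 else None
    fst_f = fst_m = None
    if species_pair is not None:
        fa = sheet.select(sex="female", species=species_pair[0])
        fb = sheet.select(sex="female", species=species_pair[1])
        ma = sheet.select(sex="male", species=species_pair[0])
        mb = sheet.select(sex="male", species=species_pair[1])
        fst_f = fst_windows(ftable, fa, fb, windows, min_sites=min_sites_fst).frame
        fst_m = fst_windows(ftable, ma, mb, windows, min_sites=min_sites_fst).frame

    report = candidate_fusion_sites(ftable, sheet, clade)
    clade_fractions: dict[str, float] = {}
    for c in autosomes:
        n_on = report.counts_per_chrom.get(c, 0)
        if n_on == 0:
            clade_fractions[c] = np.nan
            continue
        # every-k-th subsampling; when that would leave too few sites for a
        # stable fraction, tighten k so ~max_genealogy_sites are evaluated
        k = subsample_k if n_on // subsample_k >= 20 else max(1, n_on // max_genealogy_sites)
        sub = subsample_every_kth(report, k)
        summary = scan_candidate_sites(
            ftable, sub, sheet, clade, mode=genealogy_mode, chrom=c, chrom_length=chrom_lengths[c]
        )
        clade_fractions[c] = summary.fractions[FULL]

    hic_f_frame = hic_m_frame = None
    hic_f_set: set[str] | None = None
    hic_m_set: set[str] | None = None
    if hic_female is not None:
        hic_f_frame = enrichment_frame(
            interchrom_enrichment(hic_female, thr.hic_min_enrichment, thr.hic_min_count)
        )
        hic_f_set = _fused_chroms_from_hic(hic_f_frame)
    if hic_male is not None:
        hic_m_frame = enrichment_frame(
            interchrom_enrichment(hic_male, thr.hic_min_enrichment, thr.hic_min_count)
        )
        hic_m_set = _fused_chroms_from_hic(hic_m_frame)

    win = het.windows
    evidence = []
    het_by_chrom = {}
    for c in autosomes:
        m = ((win["chrom"] == c) & (~win["rejected"])).to_numpy()
        het_by_chrom[c] = het.group_means["female"].to_numpy()[m]
    for c in autosomes:
        m = ((win["chrom"] == c) & (~win["rejected"])).to_numpy()
        f_het = het.group_means["female"].to_numpy()[m]
        m_het = het.group_means["male"].to_numpy()[m]
        dm = (depth["chrom"] == c).to_numpy()
        fst_focal = fst_other = None
        if fst_f is not None:
            keep = (~fst_f["rejected"]).to_numpy()
            on = (fst_f["chrom"] == c).to_numpy()
            fst_focal = fst_f["fst"].to_numpy()[keep & on]
            fst_other = fst_f["fst"].to_numpy()[keep & ~on]
        evidence.append(
            evaluate_chromosome(
                chromosome=c,
                clade=clade,
                het_female=f_het,
                het_male=m_het,
                het_female_by_chrom=het_by_chrom,
                fst_female_focal=fst_focal,
                fst_female_other=fst_other,
                depth_female=depth["female"].to_numpy()[dm],
                depth_male=depth["male"].to_numpy()[dm],
                clade_fraction=clade_fractions[c],
                hic_female_fused=None if hic_f_set is None else (c in hic_f_set),
                hic_male_fused=None if hic_m_set is None else (c in hic_m_set),
                thresholds=thr,
            )
        )
    calls = classify(evidence)

    het_out = pd.concat([win.reset_index(drop=True), het.group_means], axis=1)
    return ScanResult(
        calls=calls,
        evidence=evidence,
        het_group_means=het_out,
        fst_female=fst_f,
        fst_male=fst_m,
        depth_group_means=depth,
        clade_fractions=clade_fractions,
        candidate_counts=report.counts_per_chrom,
        qc_removals=qc_res.removal_counts,
        hic_female=hic_f_frame,
        hic_male=hic_m_frame,
    )
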