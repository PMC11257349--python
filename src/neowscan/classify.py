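"""Integrate resequencing signatures and Hi-C into per-chromosome fusion calls.

Four resequencing signatures are evaluated per chromosome for a focal clade
(each flag carries its p-value or score, thresholded at p < 0.01 with the
required direction):

1. female heterozygosity-proportion excess over males (paired signed-rank
   over shared windows);
2. female heterozygosity excess over the other autosomes (Kruskal-Wallis
   omnibus plus Holm-corrected pairwise focal-vs-other tests, all required
   significant with the focal chromosome greater);
3. reduced female between-group FST relative to the rest of the genome
   (rank-sum of focal vs pooled other-autosome female FST windows, focal
   lower) — this signature needs two groups sharing the fused haplotype;
4. reduced female depth vs males (advisory only: young fusions show no
   mapping dropout, so the depth signature may legitimately be absent);

plus the genealogy clade-test fraction (full-pattern fraction >= a
configurable floor, default 0.2).

Calls: ``no_fusion`` unless (1) AND (2) AND (3 OR clade fraction) hold; then
``sex_linked_undetermined``.  Hi-C evidence disambiguates: a chromosome
flagged in a fused pair in the female (or fused-haplotype) matrix but not in
the male matrix upgrades to ``W_fused``; flagged in the male matrix upgrades
to ``Z_fused``; flagged in both yields a conflict caveat and stays
undetermined.  Resequencing-only runs can therefore never exceed
``sex_linked_undetermined``.  Every call carries the caveat that an
additional fusion of the ancestral Z cannot be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .window_stats import ChromosomeComparison, RankTestResult, compare_chromosomes, compare_sexes

NO_FUSION = "no_fusion"
SEX_LINKED = "sex_linked_undetermined"
W_FUSED = "W_fused"
Z_FUSED = "Z_fused"

Z_CAVEAT = "additional fusion of the ancestral Z to the neo-Z cannot be excluded"


@dataclass
class ClassifierThresholds:
    alpha: float = 0.01
    clade_fraction_min: float = 0.2
    hic_min_enrichment: float = 5.0
    hic_min_count: int = 100


@dataclass
class FusionEvidence:
    chromosome: str
    clade: tuple[str, ...]
    flags: dict[str, bool]
    p_values: dict[str, float]
    clade_fraction: float | None = None
    hic_female_fused: bool | None = None  # None = Hi-C not provided
    hic_male_fused: bool | None = None
    details: dict = field(default_factory=dict)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)


@dataclass
class FusionCall:
    chromosome: str
    verdict: str
    evidence: FusionEvidence
    caveats: list[str] = field(default_factory=list)


def _paired_flag(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float, greater: bool, label: str
) -> tuple[bool, RankTestResult]:
    """Paired signed-rank flag with a required direction on the median diff."""
    res = compare_sexes(values_a, values_b, paired_by_window=True, comparison=label)
    d = np.asarray(values_a, float) - np.asarray(values_b, float)
    d = d[np.isfinite(d)]
    direction = np.median(d) > 0 if greater else np.median(d) < 0
    return bool(res.p_value < alpha and direction), res


def evaluate_chromosome(
    chromosome: str,
    clade: Sequence[str],
    het_female: np.ndarray,
    het_male: np.ndarray,
    het_female_by_chrom: Mapping[str, np.ndarray],
    fst_female_focal: np.ndarray | None,
    fst_female_other: np.ndarray | None,
    depth_female: np.ndarray | None = None,
    depth_male: np.ndarray | None = None,
    clade_fraction: float | None = None,
    hic_female_fused: bool | None = None,
    hic_male_fused: bool | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> FusionEvidence:
    """Evaluate the fusion signatures for one chromosome.

    ``het_female``/``het_male`` are the focal chromosome's per-window group
    means; ``het_female_by_chrom`` covers all autosomes (focal included);
    ``fst_female_focal``/``fst_female_other`` are female FST windows on the
    focal chromosome and pooled over the rest of the genome (None when the
    clade has a single group and FST is unavailable).
    """
    thr = thresholds or ClassifierThresholds()
    flags: dict[str, bool] = {}
    pvals: dict[str, float] = {}
    details: dict = {}

    if het_female.size == 0 or het_male.size == 0:
        raise ValueError("window statistics missing for one sex")

    flags["het_excess_vs_males"], res = _paired_flag(
        het_female, het_male, thr.alpha, greater=True, label=f"{chromosome}:het F>M"
    )
    pvals["het_excess_vs_males"] = res.p_value

    comp: ChromosomeComparison = compare_chromosomes(het_female_by_chrom, focal=chromosome)
    pw = comp.pairwise
    all_sig = bool(
        len(pw)
        and (pw["p_holm"] < thr.alpha).all()
        and (pw["focal_median"] > pw["other_median"]).all()
    )
    flags["het_excess_vs_autosomes"] = bool(comp.omnibus.p_value < thr.alpha and all_sig)
    pvals["het_excess_vs_autosomes"] = comp.omnibus.p_value
    details["het_posthoc"] = pw

    if fst_female_focal is not None and fst_female_other is not None:
        from scipy import stats

        f = np.asarray(fst_female_focal, float)
        o = np.asarray(fst_female_other, float)
        f, o = f[np.isfinite(f)], o[np.isfinite(o)]
        if f.size >= 6 and o.size >= 6:
            r = stats.mannwhitneyu(f, o, alternative="two-sided")
            flags["fst_reduction_female"] = bool(
                r.pvalue < thr.alpha and np.median(f) < np.median(o)
            )
            pvals["fst_reduction_female"] = float(r.pvalue)
        else:
            flags["fst_reduction_female"] = False
            pvals["fst_reduction_female"] = np.nan
    else:
        flags["fst_reduction_female"] = False
        pvals["fst_reduction_female"] = np.nan
        details["fst_skipped"] = "single-group clade: FST signature unavailable"

    if depth_female is not None and depth_male is not None and depth_female.size:
        flags["depth_reduction_female"], res = _paired_flag(
            depth_female, depth_male, thr.alpha, greater=False, label=f"{chromosome}:depth F<M"
        )
        pvals["depth_reduction_female"] = res.p_value
    else:
        flags["depth_reduction_female"] = False
        pvals["depth_reduction_female"] = np.nan

    flags["clade_fraction"] = bool(
        clade_fraction is not None
        and np.isfinite(clade_fraction)
        and clade_fraction >= thr.clade_fraction_min
    )

    return FusionEvidence(
        chromosome=chromosome,
        clade=tuple(clade),
        flags=flags,
        p_values=pvals,
        clade_fraction=clade_fraction,
        hic_female_fused=hic_female_fused,
        hic_male_fused=hic_male_fused,
        details=details,
        thresholds=thr,
    )


def classify(evidence: Sequence[FusionEvidence]) -> list[FusionCall]:
    """Turn per-chromosome evidence into fusion calls with W/Z disambiguation."""
    calls = []
    for ev in evidence:
        f = ev.flags
        fst_skipped = "fst_skipped" in ev.details
        supported = f["het_excess_vs_males"] and f["het_excess_vs_autosomes"]
        if fst_skipped:
            # single-group runs cannot show the shared-haplotype FST
            # signature; require the clade-fraction flag instead
            supported = supported and f["clade_fraction"]
        else:
            supported = supported and (f["fst_reduction_female"] or f["clade_fraction"])
        caveats = [Z_CAVEAT]
        if not supported:
            calls.append(FusionCall(ev.chromosome, NO_FUSION, ev, caveats))
            continue
        verdict = SEX_LINKED
        if ev.hic_female_fused and ev.hic_male_fused:
            caveats.append("conflicting Hi-C: fused pair flagged in both sexes")
        elif ev.hic_female_fused and not ev.hic_male_fused:
            verdict = W_FUSED
        elif ev.hic_male_fused:
            verdict = Z_FUSED
        if not f["depth_reduction_female"]:
            caveats.append("no female depth reduction: consistent with a young fusion")
        calls.append(FusionCall(ev.chromosome, verdict, ev, caveats))
    return calls


def calls_frame(calls: Sequence[FusionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"chromosome": c.chromosome, "verdict": c.verdict}
        row.update({f"flag_{k}": v for k, v in c.evidence.flags.items()})
        row.update({f"p_{k}": v for k, v in c.evidence.p_values.items()})
        row["clade_fraction"] = c.evidence.clade_fraction
        row["caveats"] = "; ".join(c.caveats)
        rows.append(row)
    return pd.DataFrame(rows)
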