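"""Windowed and per-chromosome population statistics, stratified by group.

Implements the signature statistics of a sex-autosome fusion scan:

* per-individual heterozygosity proportion (#het / #called genotypes) in
  windows, averaged over a group's individuals — on a chromosome fused to the
  W this is elevated in females only;
* Hudson-style windowed FST with dxy and within-group pi, as a ratio of
  window averages — a shared female-limited haplotype depresses female FST
  between species while leaving male FST untouched;
* windowed group mean depth (mean over sites of the per-site group mean) —
  mapping dropout of a diverged fused haplotype halves female depth;
* Wilcoxon signed-rank sex comparisons (paired by window) and Kruskal-Wallis
  across chromosomes with Holm-corrected pairwise post-hoc tests.

Per-site estimators, for a group with ``n`` called allele copies of which
``n_alt`` are alternate:

    pi_site  = 2 * n_alt * (n - n_alt) / (n * (n - 1))
    dxy_site = p_A (1 - p_B) + p_B (1 - p_A)
    FST_win  = 1 - mean(pi_A, pi_B) / dxy        (ratio of window means)

Negative FST estimates are reported as computed; clamping is left to plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    SampleSheet,
    WindowSet,
    window_site_ranges,
    windowed_sums,
)

#: the variable-site floor below which an FST/dxy/pi window is rejected
DEFAULT_MIN_SITES = 2500
#: lighter floor for heterozygosity/depth windows (no floor is standard for
#: these; 50 called sites keeps per-individual proportions stable)
DEFAULT_MIN_SITES_HET = 50


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    n: int
    comparison: str
    note: str = ""


def _allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Called allele copies and alt copies per site for a genotype submatrix.

    Half-calls are treated as missing (their allele identity is not stored).
    """
    called = (gt == HOM_REF) | (gt == HET) | (gt == HOM_ALT)
    n_called = 2 * called.sum(axis=1)
    n_alt = (gt == HET).sum(axis=1) + 2 * (gt == HOM_ALT).sum(axis=1)
    return n_called.astype(np.int64), n_alt.astype(np.int64)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


@dataclass
class HetWindowResult:
    windows: pd.DataFrame  # chrom, start, end, n_sites, rejected
    per_individual: pd.DataFrame  # window x sample heterozygosity proportion
    group_means: pd.DataFrame  # window x group (unweighted mean over individuals)


def het_proportion_windows(
    table: GenotypeTable,
    windows: WindowSet,
    samples: Sequence[str],
    groups: Mapping[str, Sequence[str]] | None = None,
    min_sites: int = DEFAULT_MIN_SITES_HET,
) -> HetWindowResult:
    """Per-individual windowed heterozygosity proportion and group means.

    The proportion is #heterozygous / #called genotypes per individual per
    window (pi with each individual as its own population).  An individual
    with zero called genotypes in a window gets NaN and is excluded from the
    group mean.
    """
    if not samples:
        raise ValueError("no samples given")
    cols = table.sample_indices(samples)
    gt = table.gt[:, cols]
    lo, hi = window_site_ranges(table, windows)
    het_w = windowed_sums(gt == HET, lo, hi)
    called_w = windowed_sums((gt == HOM_REF) | (gt == HET) | (gt == HOM_ALT), lo, hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(called_w > 0, het_w / called_w, np.nan)
    n_sites = hi - lo
    rejected = n_sites < min_sites
    win = windows.frame.copy()
    win["n_sites"] = n_sites
    win["rejected"] = rejected
    per_ind = pd.DataFrame(prop, columns=list(samples))
    if groups is None:
        groups = {"all": list(samples)}
    gm = {}
    for name, members in groups.items():
        j = [list(samples).index(s) for s in members]
        with np.errstate(invalid="ignore"):
            gm[name] = np.nanmean(prop[:, j], axis=1) if j else np.full(windows.n, np.nan)
    return HetWindowResult(windows=win, per_individual=per_ind, group_means=pd.DataFrame(gm))


# ---------------------------------------------------------------------------
# FST / dxy / pi
# ---------------------------------------------------------------------------


@dataclass
class FstWindowResult:
    frame: pd.DataFrame  # chrom, start, end, fst, dxy, pi_a, pi_b, n_sites, rejected
    estimator: str = "hudson_ratio_of_window_means"


def fst_windows(
    table: GenotypeTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    windows: WindowSet,
    min_sites: int = DEFAULT_MIN_SITES,
) -> FstWindowResult:
    """Hudson-style windowed FST between two groups, with dxy and pi.

    A site is used when both groups have >=2 called allele copies and the
    pooled sample is variable.  Window values are means over used sites;
    ``fst = 1 - mean(pi_a, pi_b) / dxy`` with dxy the window mean, reported
    NaN when the window dxy is 0.  Windows with fewer than ``min_sites`` used
    sites are flagged rejected.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    gt_a = table.gt[:, table.sample_indices(group_a)]
    gt_b = table.gt[:, table.sample_indices(group_b)]
    na, xa = _allele_counts(gt_a)
    nb, xb = _allele_counts(gt_b)
    usable = (na >= 2) & (nb >= 2)
    variable = ((xa + xb) > 0) & ((xa + xb) < (na + nb))
    use = usable & variable

    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(na > 0, xa / np.maximum(na, 1), np.nan)
        pb = np.where(nb > 0, xb / np.maximum(nb, 1), np.nan)
        pi_a = 2.0 * xa * (na - xa) / (na * np.maximum(na - 1, 1))
        pi_b = 2.0 * xb * (nb - xb) / (nb * np.maximum(nb - 1, 1))
        dxy = pa * (1.0 - pb) + pb * (1.0 - pa)

    w = use.astype(np.float64)
    lo, hi = window_site_ranges(table, windows)
    n_used = windowed_sums(w, lo, hi)
    # zero out unused sites before summing: pi/dxy may be NaN where a group
    # has no called alleles, and NaN * 0 would still poison the window sum
    stacked = np.stack(
        [np.where(use, pi_a, 0.0), np.where(use, pi_b, 0.0), np.where(use, dxy, 0.0)], axis=1
    )
    sums = windowed_sums(stacked, lo, hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pi_a = np.where(n_used > 0, sums[:, 0] / n_used, np.nan)
        mean_pi_b = np.where(n_used > 0, sums[:, 1] / n_used, np.nan)
        mean_dxy = np.where(n_used > 0, sums[:, 2] / n_used, np.nan)
        fst = np.where(mean_dxy > 0, 1.0 - 0.5 * (mean_pi_a + mean_pi_b) / mean_dxy, np.nan)

    frame = windows.frame.copy()
    frame["fst"] = fst
    frame["dxy"] = mean_dxy
    frame["pi_a"] = mean_pi_a
    frame["pi_b"] = mean_pi_b
    frame["n_sites"] = n_used.astype(np.int64)
    frame["rejected"] = frame["n_sites"] < min_sites
    return FstWindowResult(frame=frame)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def depth_windows(
    table: GenotypeTable,
    windows: WindowSet,
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-window per-group mean depth (mean over sites of per-site group means)."""
    if not (table.depth >= 0).any():
        raise ValueError("no DP data present; disable depth analyses")
    lo, hi = window_site_ranges(table, windows)
    out = windows.frame.copy()
    out["n_sites"] = hi - lo
    for name, members in groups.items():
        d = table.depth[:, table.sample_indices(members)]
        if (d >= 0).all():
            site_mean = d.mean(axis=1)
        else:
            has = d >= 0
            with np.errstate(invalid="ignore", divide="ignore"):
                site_mean = np.where(
                    has.any(axis=1),
                    np.where(has, d, 0).sum(axis=1) / np.maximum(has.sum(axis=1), 1),
                    np.nan,
                )
        ok = np.isfinite(site_mean)
        s = windowed_sums(np.where(ok, site_mean, 0.0), lo, hi)
        n = windowed_sums(ok.astype(np.float64), lo, hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(n > 0, s / n, np.nan)
    return out


# ---------------------------------------------------------------------------
# summaries and rank tests
# ---------------------------------------------------------------------------


def chromosome_summaries(
    window_values: pd.DataFrame, value_columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Unweighted per-chromosome means over non-rejected windows.

    ``window_values`` needs a ``chrom`` column and, optionally, a ``rejected``
    flag.  A chromosome whose windows are all rejected gets NaN summaries.
    """
    df = window_values
    if "rejected" in df.columns:
        kept = df[~df["rejected"].astype(bool)]
    else:
        kept = df
    if value_columns is None:
        value_columns = [
            c
            for c in df.columns
            if c not in ("chrom", "start", "end", "n_sites", "rejected")
            and np.issubdtype(df[c].dtype, np.number)
        ]
    order = list(dict.fromkeys(df["chrom"]))
    out = kept.groupby("chrom", sort=False)[list(value_columns)].mean()
    out = out.reindex(order)
    return out


def compare_sexes(
    values_female: np.ndarray,
    values_male: np.ndarray,
    paired_by_window: bool = True,
    comparison: str = "female_vs_male",
) -> RankTestResult:
    """Two-sided rank test of female vs male window values.

    Paired mode (default) is the Wilcoxon signed-rank test over windows shared
    by both sexes; unpaired mode is a two-sample rank-sum test.
    """
    f = np.asarray(values_female, dtype=float)
    m = np.asarray(values_male, dtype=float)
    if paired_by_window:
        if f.shape != m.shape:
            raise ValueError("paired comparison requires equal-length window vectors")
        ok = np.isfinite(f) & np.isfinite(m)
        f, m = f[ok], m[ok]
        if f.size < 6:
            raise ValueError("need >=6 shared non-rejected windows for the paired test")
        d = f - m
        if np.all(d == 0):
            return RankTestResult(0.0, 1.0, int(f.size), comparison, note="all differences zero")
        res = stats.wilcoxon(f, m, alternative="two-sided", zero_method="wilcox")
        return RankTestResult(float(res.statistic), float(res.pvalue), int(f.size), comparison)
    f = f[np.isfinite(f)]
    m = m[np.isfinite(m)]
    res = stats.mannwhitneyu(f, m, alternative="two-sided")
    return RankTestResult(float(res.statistic), float(res.pvalue), int(f.size + m.size), comparison)


@dataclass
class ChromosomeComparison:
    omnibus: RankTestResult
    pairwise: pd.DataFrame  # other chrom, statistic, p_raw, p_holm, focal_median, other_median


def compare_chromosomes(
    values_by_chrom: Mapping[str, np.ndarray], focal: str
) -> ChromosomeComparison:
    """Kruskal-Wallis across chromosomes plus focal-vs-each pairwise tests.

    Pairwise two-sample rank-sum tests of the focal chromosome against every
    other one, Holm-corrected.
    """
    if focal not in values_by_chrom:
        raise ValueError(f"focal chromosome {focal!r} absent from values")
    clean = {
        c: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
        for c, v in values_by_chrom.items()
    }
    if len(clean) < 2:
        raise ValueError("need >=2 chromosomes")
    for c, v in clean.items():
        if v.size < 6:
            raise ValueError(f"chromosome {c} has fewer than 6 usable windows")
    kw = stats.kruskal(*clean.values())
    omnibus = RankTestResult(float(kw.statistic), float(kw.pvalue), sum(v.size for v in clean.values()), "kruskal_wallis")

    others = [c for c in clean if c != focal]
    rows = []
    for c in others:
        if np.array_equal(clean[focal], clean[c]):
            rows.append((c, np.nan, 1.0, np.median(clean[focal]), np.median(clean[c])))
            continue
        r = stats.mannwhitneyu(clean[focal], clean[c], alternative="two-sided")
        rows.append((c, float(r.statistic), float(r.pvalue), np.median(clean[focal]), np.median(clean[c])))
    pairwise = pd.DataFrame(rows, columns=["chrom", "statistic", "p_raw", "focal_median", "other_median"])
    if len(pairwise):
        from statsmodels.stats.multitest import multipletests

        pairwise["p_holm"] = multipletests(pairwise["p_raw"].to_numpy(), method="holm")[1]
    else:
        pairwise["p_holm"] = []
    return ChromosomeComparison(omnibus=omnibus, pairwise=pairwise)
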