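"""Assign scaffolds to the W chromosome from sex-stratified depth.

A W-linked scaffold is present in one copy in females and absent in males,
so at depth lambda per diploid copy pair the expected female depth is
lambda/2 and the male depth ~0 (only mismapping).  Per scaffold and sex we
take the *median* of 500-bp-window mean depths (robust to repeat-driven
depth spikes) and compare it with the same sex's autosomal median:

* W-linked: male median <= m_max * male autosomal median AND
  female median >= f_min * female autosomal median (defaults 0.1 / 0.25,
  passing the hemizygous dosage with margin);
* autosomal-like: both sexes within [0.5, 1.5]x their autosomal medians;
* otherwise ambiguous (e.g. no coverage in either sex).

Classification is invariant to global depth rescaling because every rule is
a ratio to the autosomal reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, SampleSheet, make_windows, window_site_ranges, windowed_sums

W_LINKED = "W-linked"
AUTOSOMAL_LIKE = "autosomal-like"
AMBIGUOUS = "ambiguous"


@dataclass
class WThresholds:
    m_max: float = 0.1
    f_min: float = 0.25
    auto_low: float = 0.5
    auto_high: float = 1.5


def _window_mean_depths(
    table: GenotypeTable, chroms: Sequence[str], samples: Sequence[str], window_bp: int
) -> dict[str, np.ndarray]:
    """Per chromosome: window means of per-site group mean depth."""
    cols = table.sample_indices(samples)
    d = table.depth[:, cols].astype(np.float64)
    has = d >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        site_mean = np.where(has.any(axis=1), np.where(has, d, 0.0).sum(axis=1) / np.maximum(has.sum(axis=1), 1), np.nan)
    out = {}
    for c in chroms:
        mask = table.chrom == c
        if not mask.any():
            out[c] = np.array([])
            continue
        pos = table.pos[mask]
        vals = site_mean[mask]
        length = int(pos.max())
        windows = make_windows({c: length}, window_bp)
        sub = table.subset_sites(mask)
        lo, hi = window_site_ranges(sub, windows)
        ok = np.isfinite(vals)
        s = windowed_sums(np.where(ok, vals, 0.0), lo, hi)
        n = windowed_sums(ok.astype(np.float64), lo, hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            wm = np.where(n > 0, s / n, np.nan)
        out[c] = wm[np.isfinite(wm)]
    return out


def scaffold_depth_summary(
    table: GenotypeTable,
    sheet: SampleSheet,
    scaffolds: Sequence[str],
    autosomal: Sequence[str],
    window_bp: int = 500,
) -> pd.DataFrame:
    """Median of window mean depths per scaffold per sex, plus autosomal refs."""
    if not autosomal:
        raise ValueError("no autosomal scaffolds designated for normalization")
    females = sheet.select(sex="female")
    males = sheet.select(sex="male")
    if not females or not males:
        raise ValueError("both sexes required for W assignment")
    rows = []
    refs = {}
    for sex, samp in (("female", females), ("male", males)):
        by_chrom = _window_mean_depths(table, list(scaffolds) + list(autosomal), samp, window_bp)
        auto_vals = np.concatenate([by_chrom[c] for c in autosomal if by_chrom[c].size])
        refs[sex] = float(np.median(auto_vals)) if auto_vals.size else np.nan
        for sc in scaffolds:
            v = by_chrom[sc]
            rows.append((sc, sex, float(np.median(v)) if v.size else np.nan, v.size))
    df = pd.DataFrame(rows, columns=["scaffold", "sex", "median_depth", "n_windows"])
    wide = df.pivot(index="scaffold", columns="sex", values="median_depth").reindex(scaffolds)
    nwin = df.pivot(index="scaffold", columns="sex", values="n_windows").reindex(scaffolds)
    out = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "female_median": wide["female"].to_numpy(),
            "male_median": wide["male"].to_numpy(),
            "n_windows": nwin["female"].to_numpy(),
            "female_autosomal_median": refs["female"],
            "male_autosomal_median": refs["male"],
        }
    )
    # female:male ratio with a pseudo-floor on the male median so a zero male
    # depth yields a large finite ratio
    floor = 0.01 * max(refs["male"], 1e-9)
    out["fm_ratio"] = out["female_median"] / np.maximum(out["male_median"], floor)
    return out


def assign_w_scaffolds(
    table: GenotypeTable,
    sheet: SampleSheet,
    scaffolds: Sequence[str],
    autosomal: Sequence[str],
    window_bp: int = 500,
    thresholds: WThresholds | None = None,
) -> pd.DataFrame:
    """Classify each scaffold as W-linked / autosomal-like / ambiguous."""
    thr = thresholds or WThresholds()
    summary = scaffold_depth_summary(table, sheet, scaffolds, autosomal, window_bp)
    f_ref = summary["female_autosomal_median"].to_numpy()
    m_ref = summary["male_autosomal_median"].to_numpy()
    f = summary["female_median"].to_numpy()
    m = summary["male_median"].to_numpy()
    w_linked = (m <= thr.m_max * m_ref) & (f >= thr.f_min * f_ref)
    auto_like = (
        (f >= thr.auto_low * f_ref)
        & (f <= thr.auto_high * f_ref)
        & (m >= thr.auto_low * m_ref)
        & (m <= thr.auto_high * m_ref)
    )
    cls = np.where(w_linked, W_LINKED, np.where(auto_like, AUTOSOMAL_LIKE, AMBIGUOUS))
    cls[~np.isfinite(f) | ~np.isfinite(m)] = AMBIGUOUS
    summary["classification"] = cls
    summary.attrs["thresholds"] = thr
    return summary
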