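"""Hi-C contact evidence for chromosome fusions.

A fusion joins two chromosomes into one molecule, so the fused pair shows an
excess of inter-chromosomal (trans) contacts concentrated near the junction.
Each chromosome pair's observed trans contacts are compared with a robust
expectation built from trans contacts only (cis counts are excluded because
distance decay makes them uninformative for fusion calling):

    rate(a, b)     = O_ab / (n_bins_a * n_bins_b)
    expected(a, b) = median over all pairs of rate * n_bins_a * n_bins_b
    enrichment     = O_ab / expected(a, b)

The median per-bin-pair trans rate is insensitive to the fused pair itself:
a junction can carry orders of magnitude more contacts than the background
without dragging up the expectation of any pair, including its own.  (A
marginal-product expectation ``T_a * T_b / (2 * T_trans)`` does not have
this property — a dominant junction inflates its own two marginals and the
global total, capping its own score near 2 while pushing every unrelated
pair's score above 1 — so it cannot isolate the fused pair.)  The score is
1 under uniform trans noise, invariant to uniform count scaling, and the
fused pair's score grows linearly with the junction signal.

In a ZW female the pooled matrix mixes the fused (W-linked) and unfused
haplotypes; when per-read-pair haplotype tags are available the matrix can be
split, isolating the junction signal to one haplotype.  A ZZ male carries no
fused haplotype, so his matrix shows no enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with a bin -> interval map.

    ``tags`` is an optional aggregated read-pair stream with columns
    ``bin_i, bin_j, hap, count`` where hap 0 means unassigned; it sums to the
    matrix when present.
    """

    matrix: np.ndarray
    bins: pd.DataFrame  # columns: chrom, start, end
    tags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if len(self.bins) != n:
            raise ValueError("bin map does not cover matrix indices")
        if (self.matrix < 0).any():
            raise ValueError("contact counts must be non-negative")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def total(self) -> int:
        iu = np.triu_indices(self.matrix.shape[0])
        return int(self.matrix[iu].sum())

    def write(self, prefix) -> None:
        """Write counts as 3-column TSV (upper triangle) and the bin map as BED."""
        prefix = Path(prefix)
        iu = np.triu_indices(self.matrix.shape[0])
        c = self.matrix[iu]
        nz = c > 0
        pd.DataFrame({"bin_i": iu[0][nz], "bin_j": iu[1][nz], "count": c[nz]}).to_csv(
            f"{prefix}.contacts.tsv", sep="\t", index=False
        )
        self.bins.to_csv(f"{prefix}.bins.bed", sep="\t", header=False, index=False)
        if self.tags is not None:
            self.tags.to_csv(f"{prefix}.tags.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, contacts_path, bins_path, tags_path=None) -> "ContactMatrix":
        bins = pd.read_csv(bins_path, sep="\t", header=None, names=["chrom", "start", "end"])
        df = pd.read_csv(contacts_path, sep="\t")
        n = len(bins)
        mat = np.zeros((n, n), dtype=np.int64)
        mat[df["bin_i"], df["bin_j"]] = df["count"]
        mat = np.triu(mat) + np.triu(mat, 1).T
        tags = pd.read_csv(tags_path, sep="\t") if tags_path is not None else None
        return cls(matrix=mat, bins=bins, tags=tags)


@dataclass
class PairEnrichment:
    chrom_a: str
    chrom_b: str
    observed: float
    expected: float
    enrichment: float
    fused: bool


def interchrom_enrichment(
    cm: ContactMatrix,
    min_enrichment: float = 5.0,
    min_count: int = 100,
) -> list[PairEnrichment]:
    """Observed/expected trans contacts per chromosome pair, with fused flags.

    The expectation is the median per-bin-pair trans rate scaled by each
    pair's bin-count product (see module docstring).  A pair is flagged
    fused when enrichment >= ``min_enrichment`` and the observed trans count
    >= ``min_count``.  With no trans contacts at all, every pair is
    unflagged (with a warning).
    """
    chroms = cm.chromosomes
    if len(chroms) < 2:
        raise ValueError("need >=2 chromosomes in the bin map")
    chrom_arr = cm.bins["chrom"].to_numpy()
    masks = {c: chrom_arr == c for c in chroms}
    nbins = {c: int(masks[c].sum()) for c in chroms}
    obs = {}
    for ai, a in enumerate(chroms):
        for b in chroms[ai + 1 :]:
            obs[(a, b)] = float(cm.matrix[np.ix_(masks[a], masks[b])].sum())
    t_trans = sum(obs.values())
    out = []
    if t_trans == 0:
        log.warning("no trans contacts at all; no pair can be evaluated")
        return [PairEnrichment(a, b, o, 0.0, 0.0, False) for (a, b), o in obs.items()]
    rates = np.array([o / (nbins[a] * nbins[b]) for (a, b), o in obs.items()])
    median_rate = float(np.median(rates))
    for (a, b), o in obs.items():
        e = median_rate * nbins[a] * nbins[b]
        enr = o / e if e > 0 else 0.0
        fused = bool(e > 0 and enr >= min_enrichment and o >= min_count)
        out.append(PairEnrichment(a, b, o, e, enr, fused))
    return out


def enrichment_frame(pairs: list[PairEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom_a": p.chrom_a,
                "chrom_b": p.chrom_b,
                "observed": p.observed,
                "expected": p.expected,
                "enrichment": p.enrichment,
                "fused": p.fused,
            }
            for p in pairs
        ]
    )


def split_by_haplotype(cm: ContactMatrix) -> tuple[ContactMatrix, ContactMatrix, float]:
    """Route tagged read pairs into per-haplotype matrices.

    Untagged pairs (hap 0) are dropped and counted; returns
    ``(hap1_matrix, hap2_matrix, assignment_rate)``.  Requires >=50% of read
    pairs tagged.
    """
    if cm.tags is None:
        raise ValueError("no haplotype tag stream; run the pooled-only analysis instead")
    tags = cm.tags
    total = float(tags["count"].sum())
    tagged = float(tags.loc[tags["hap"] != 0, "count"].sum())
    rate = tagged / total if total else 0.0
    if rate < 0.5:
        raise ValueError(f"only {rate:.1%} of read pairs are haplotype-tagged (need >=50%)")
    n = cm.matrix.shape[0]
    mats = {}
    for hap in (1, 2):
        sub = tags[tags["hap"] == hap]
        m = np.zeros((n, n), dtype=np.int64)
        np.add.at(m, (sub["bin_i"].to_numpy(), sub["bin_j"].to_numpy()), sub["count"].to_numpy())
        m = np.triu(m) + np.triu(m, 1).T
        mats[hap] = ContactMatrix(matrix=m, bins=cm.bins)
    return mats[1], mats[2], rate
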