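"""Local-genealogy test for a female-specific haplotype clade.

On a chromosome fused to the W, every clade female carries one haplotype
that descends from the shared non-recombining fused W copy.  In the local
genealogy at a candidate site this predicts a clade containing exactly one
haplotype from every clade female and no male haplotype (the female-specific
haplotype clade).  Two interchangeable modes test this prediction:

* ``tree`` mode: neighbor-joining on pairwise Hamming distances over a
  window of SNPs around the focal site (a self-contained local-genealogy
  construction; phasing switch errors degrade it, which is exactly how the
  mixed category arises in practice);
* ``allele`` mode: the derived-allele carrier set at the focal site itself,
  which needs no phasing and is the default when the switch-error rate is
  unknown.

Verdicts: ``full_pattern`` (one haplotype per clade female, nothing else),
``partial_pattern`` (the complete pattern holds within a proper, non-empty
subset of the clade's species — recorded per species) or ``mixed``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, HET, HOM_ALT, HOM_REF, MISSING, SampleSheet
from .site_filter import CandidateSiteReport

FULL = "full_pattern"
PARTIAL = "partial_pattern"
MIXED = "mixed"


@dataclass
class LocalTree:
    """Unrooted NJ tree over haplotype labels ``<sample>_h0`` / ``<sample>_h1``."""

    tree: object  # skbio.TreeNode
    labels: list[str]
    n_sites_used: int

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets of all internal edges (one side of each split)."""
        out = []
        for node in self.tree.non_tips(include_self=False):
            out.append(frozenset(t.name for t in node.tips()))
        return out

    def newick(self) -> str:
        return str(self.tree)


@dataclass
class CladeVerdict:
    verdict: str  # FULL / PARTIAL / MIXED
    species_with_pattern: tuple[str, ...] = ()
    supporting_set: frozenset[str] | None = None


def hamming_distance_matrix(haps: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances normalized by non-missing comparisons.

    ``haps``: (n_sites, n_haplotypes) alleles in {0, 1, -1 missing}.
    """
    h = haps.T.astype(np.float64)  # (n_haps, n_sites)
    ok = h >= 0
    hm = np.where(ok, h, 0.0)
    okf = ok.astype(np.float64)
    both = okf @ okf.T
    # for 0/1 alleles, mismatches over co-called sites expand to two products
    d = (hm * okf) @ ((1.0 - hm) * okf).T + ((1.0 - hm) * okf) @ (hm * okf).T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(both > 0, d / both, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def nj_from_distances(d: np.ndarray, ids: Sequence[str]):
    """Neighbor-joining on a distance matrix; negative branch lengths clamped."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(d, ids=list(ids)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_local_tree(
    haplotypes: np.ndarray,
    labels: Sequence[str],
    focal_index: int,
    flank_snps: int = 50,
) -> LocalTree:
    """Neighbor-joining tree around a focal site.

    Uses the focal site +- ``flank_snps`` SNPs; distances are Hamming
    proportions over non-missing comparisons.  Leaves are ordered
    lexicographically before NJ so ties break deterministically.
    """
    if flank_snps < 10:
        raise ValueError("flank_snps must be >= 10")
    n_sites, n_haps = haplotypes.shape
    if n_haps < 4:
        raise ValueError("need at least 4 haplotypes for a tree")
    lo = max(0, focal_index - flank_snps)
    hi = min(n_sites, focal_index + flank_snps + 1)
    window = haplotypes[lo:hi]
    order = np.argsort(np.asarray(labels, dtype=object))
    ordered_labels = [labels[i] for i in order]
    d = hamming_distance_matrix(window[:, order])
    tree = nj_from_distances(d, ordered_labels)
    return LocalTree(tree=tree, labels=ordered_labels, n_sites_used=hi - lo)


def _pattern_of_set(
    members: frozenset[str],
    female_hap_labels: dict[str, list[str]],  # clade female sample -> its 2 labels
    male_labels: set[str],
    other_labels: set[str],
    species_of_female: dict[str, str],
    clade_species: Sequence[str],
) -> tuple[str, tuple[str, ...]]:
    """Classify one candidate haplotype set against the fusion prediction."""
    if members & male_labels or members & other_labels:
        return MIXED, ()
    per_female = {f: len(members & set(labs)) for f, labs in female_hap_labels.items()}
    covered = [f for f, k in per_female.items() if k == 1]
    if any(k > 1 for k in per_female.values()):
        return MIXED, ()
    if len(members) != len(covered):
        return MIXED, ()
    species_counts = Counter(species_of_female[f] for f in covered)
    complete = tuple(
        sp
        for sp in clade_species
        if species_counts.get(sp, 0) == sum(1 for f in species_of_female if species_of_female[f] == sp)
    )
    if not complete or set(covered) - {
        f for f in species_of_female if species_of_female[f] in complete
    }:
        return MIXED, ()
    if set(complete) == set(clade_species):
        return FULL, complete
    return PARTIAL, complete


def female_clade_verdict(
    table: GenotypeTable,
    sheet: SampleSheet,
    clade: Sequence[str],
    focal_index: int,
    mode: Literal["tree", "allele"] = "allele",
    flank_snps: int = 50,
    outgroup_species: Sequence[str] | None = None,
) -> CladeVerdict:
    """Test the female-specific-clade prediction at one site.

    ``tree`` mode searches the bipartitions of the local NJ tree; ``allele``
    mode uses the derived-allele carrier set at the focal site (derived =
    allele rarer in the outgroup when given, else the minor allele).
    """
    clade = tuple(clade)
    females = sheet.select(sex="female", species=clade)
    if len(females) < 2:
        raise ValueError("clade needs >=2 females across >=1 species")
    males = sheet.select(sex="male")
    species_map = dict(zip(sheet.frame["sample"], sheet.frame["species"]))
    species_of_female = {f: species_map[f] for f in females}
    female_hap_labels = {f: [f"{f}_h0", f"{f}_h1"] for f in females}
    male_labels = {f"{m}_h{k}" for m in males for k in (0, 1)}
    clade_samples = set(females) | set(sheet.select(sex="male", species=clade))
    other_labels = {
        f"{s}_h{k}" for s in table.samples if s not in clade_samples and s not in males for k in (0, 1)
    }

    if mode == "tree":
        if table.haplotypes is None:
            raise ValueError("tree mode needs phased haplotypes; use allele mode instead")
        chrom = table.chrom[focal_index]
        on = np.flatnonzero(table.chrom == chrom)
        local_focal = int(np.searchsorted(on, focal_index))
        haps = table.haplotypes[on].reshape(on.size, -1)
        labels = [f"{s}_h{k}" for s in table.samples for k in (0, 1)]
        tree = build_local_tree(haps, labels, local_focal, flank_snps)
        best = CladeVerdict(MIXED)
        for side in tree.bipartitions():
            for members in (side, frozenset(tree.labels) - side):
                verdict, species = _pattern_of_set(
                    members, female_hap_labels, male_labels, other_labels, species_of_female, clade
                )
                if verdict == FULL:
                    return CladeVerdict(FULL, species, members)
                if verdict == PARTIAL and best.verdict != PARTIAL:
                    best = CladeVerdict(PARTIAL, species, members)
        return best

    # allele mode: carrier set at the focal site, from haplotypes if
    # available, else from genotypes (het female = one carried copy)
    if table.haplotypes is not None:
        derived = _derived_allele(table, focal_index, outgroup_species, sheet)
        carriers = []
        for j, s in enumerate(table.samples):
            for k in (0, 1):
                if table.haplotypes[focal_index, j, k] == derived:
                    carriers.append(f"{s}_h{k}")
        members = frozenset(carriers)
        verdict, species = _pattern_of_set(
            members, female_hap_labels, male_labels, other_labels, species_of_female, clade
        )
        return CladeVerdict(verdict, species, members if verdict != MIXED else None)

    derived = _derived_allele(table, focal_index, outgroup_species, sheet)
    gt = table.gt[focal_index]
    hom_derived = HOM_ALT if derived == 1 else HOM_REF
    carriers_n = {
        s: (2 if gt[j] == hom_derived else 1 if gt[j] == HET else 0)
        for j, s in enumerate(table.samples)
    }
    members = frozenset(
        f"{s}_h0" for s, k in carriers_n.items() if k == 1
    )  # phase-free stand-in: one carried copy -> one haplotype
    if any(k == 2 for k in carriers_n.values()):
        return CladeVerdict(MIXED)
    fem_lab = {f: [f"{f}_h0"] for f in females}
    verdict, species = _pattern_of_set(
        members,
        {f: labs for f, labs in fem_lab.items()},
        {f"{m}_h0" for m in males},
        {f"{s}_h0" for s in table.samples if s not in clade_samples and s not in males},
        species_of_female,
        clade,
    )
    return CladeVerdict(verdict, species, members if verdict != MIXED else None)


def _derived_allele(
    table: GenotypeTable,
    focal_index: int,
    outgroup_species: Sequence[str] | None,
    sheet: SampleSheet,
) -> int:
    """Derived allele orientation: rarer in the outgroup if given, else minor."""
    gt = table.gt[focal_index]
    if outgroup_species:
        cols = table.sample_indices(sheet.select(species=tuple(outgroup_species)))
        g = gt[cols]
    else:
        g = gt
    called = (g == HOM_REF) | (g == HET) | (g == HOM_ALT)
    n = 2 * called.sum()
    n_alt = (g == HET).sum() + 2 * (g == HOM_ALT).sum()
    if n == 0:
        return 1
    return 1 if n_alt * 2 <= n else 0


@dataclass
class ScanSummary:
    fractions: dict[str, float]
    verdicts: pd.DataFrame  # chrom, pos, verdict, n_species_with_pattern
    dispersion: float  # fraction of chromosome deciles holding >=1 full site


def scan_candidate_sites(
    table: GenotypeTable,
    report: CandidateSiteReport,
    sheet: SampleSheet,
    clade: Sequence[str],
    mode: Literal["tree", "allele"] = "allele",
    flank_snps: int = 50,
    chrom: str | None = None,
    chrom_length: int | None = None,
    outgroup_species: Sequence[str] | None = None,
) -> ScanSummary:
    """Verdicts over the report's subsampled sites (optionally one chromosome).

    Returns summary fractions per verdict plus a positional dispersion
    statistic: the fraction of chromosome-length deciles containing at least
    one full-pattern site (requires ``chrom`` and ``chrom_length``).
    """
    idx = report.subsample_index
    if chrom is not None:
        idx = idx[table.chrom[idx] == chrom]
    if idx.size == 0:
        import logging

        logging.getLogger(__name__).warning("empty subsample; nothing to scan")
        return ScanSummary(
            fractions={FULL: np.nan, PARTIAL: np.nan, MIXED: np.nan},
            verdicts=pd.DataFrame(columns=["chrom", "pos", "verdict", "n_species_with_pattern"]),
            dispersion=np.nan,
        )
    rows = []
    for i in idx:
        v = female_clade_verdict(
            table, sheet, clade, int(i), mode=mode, flank_snps=flank_snps, outgroup_species=outgroup_species
        )
        rows.append((table.chrom[i], int(table.pos[i]), v.verdict, len(v.species_with_pattern)))
    verdicts = pd.DataFrame(rows, columns=["chrom", "pos", "verdict", "n_species_with_pattern"])
    n = len(verdicts)
    fractions = {k: float((verdicts["verdict"] == k).mean()) for k in (FULL, PARTIAL, MIXED)}
    dispersion = np.nan
    if chrom is not None and chrom_length:
        full_pos = verdicts.loc[verdicts["verdict"] == FULL, "pos"].to_numpy()
        deciles = np.minimum(((full_pos - 1) * 10) // chrom_length, 9)
        dispersion = float(np.unique(deciles).size / 10.0)
    return ScanSummary(fractions=fractions, verdicts=verdicts, dispersion=dispersion)
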